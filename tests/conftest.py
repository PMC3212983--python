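import numpy as np
import pytest

from discon.features import build_default_catalog
from discon.records import AA_ALPHABET, DisorderAnnotation, assemble_record
from discon.simulate import SimulationConfig, generate_records


@pytest.fixture(scope="session")
def catalog():
    return build_default_catalog()


@pytest.fixture(scope="session")
def small_dataset():
    """60 synthetic chains with full tracks, fixed seed."""
    return generate_records(SimulationConfig(n_proteins=60, seed=11))


def make_record(
    sequence="ACDEFGHIKL",
    ss=None,
    rsa=None,
    bfactor=None,
    domain=None,
    flex_strict=None,
    flex_nonstrict=None,
    signal=None,
    wop=None,
    pssm=None,
    labels=None,
    record_id="toy",
):
    """Small hand-built record; tracks default to None (absent)."""
    disorder = None
    if labels is not None:
        disorder = DisorderAnnotation(record_id, labels=np.asarray(labels, dtype=np.int8))
    return assemble_record(
        record_id,
        sequence,
        pssm=pssm,
        wop=wop,
        ss=ss,
        rsa=None if rsa is None else np.asarray(rsa, dtype=float),
        bfactor=None if bfactor is None else np.asarray(bfactor, dtype=float),
        flex_strict=flex_strict,
        flex_nonstrict=flex_nonstrict,
        domain=domain,
        signal=signal,
        disorder=disorder,
    )


def random_full_record(rng, length=30, record_id="rnd"):
    """Record with every track populated, for round-trip style tests."""
    seq = "".join(rng.choice(list(AA_ALPHABET), size=length))
    wop = rng.dirichlet(np.ones(20), size=length) * 100
    pssm = rng.integers(-8, 9, size=(length, 20))
    ss = "".join(rng.choice(list("HEC"), size=length))
    return make_record(
        sequence=seq,
        ss=ss,
        rsa=rng.random(length),
        bfactor=rng.normal(0, 1, length),
        domain=rng.integers(0, 2, length),
        flex_strict=rng.integers(0, 2, length),
        flex_nonstrict=rng.integers(0, 2, length),
        signal=rng.integers(0, 2, length),
        wop=wop,
        pssm=pssm,
        labels=rng.integers(0, 2, length),
        record_id=record_id,
    )
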