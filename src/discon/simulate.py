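"""Synthetic protein-record generator with disorder-coupled tracks.

The generator produces chains with segmental disorder and per-residue tracks
whose conditional distributions reproduce the couplings the content model
relies on:

* disordered residues are coil-biased, solvent exposed, flexible (high
  normalized B-factor) and mostly outside globular domains;
* disordered positions are less conserved: their profile rows are drawn from
  a high-temperature Dirichlet biased toward the disorder-promoting residues
  (A, R, G, Q, S, E, P, K), while ordered positions conserve a single
  preferred residue;
* the sequence itself is sampled from the profile row, so amino-acid
  composition is disorder-biased as in real chains;
* PSSM rows are the integer logit of the profile probabilities, the inverse
  of the squashing used by the entropy features, keeping the two profile
  encodings consistent.

B-factors are normalized at the corpus level (the state-conditional means
are chosen so a chain of typical content averages about 0) rather than
recentred per chain, since exact per-chain centring would erase the
chain-level signal the content model aggregates.

A separate propensity simulator produces per-chain biased, noisy monotone
transforms of the smoothed disorder labels, mimicking residue-level disorder
predictors whose propensity scale shifts from chain to chain — the failure
mode that content-guided thresholding corrects.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from discon.records import AA_ALPHABET, DISORDER_PROMOTING, ProteinRecord, DisorderAnnotation, assemble_record
from discon import io_formats

_DIS_IDX = np.array([i for i, a in enumerate(AA_ALPHABET) if a in DISORDER_PROMOTING])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study conditions.

    Defaults emulate a mixed structured/disordered benchmark: ~15% fully
    ordered chains and otherwise beta-distributed content with mean ~0.35,
    arranged in alternating geometric-length ordered/disordered segments.
    """

    n_proteins: int = 300
    length_min: int = 60
    length_max: int = 300
    # per-chain target content: point mass at 0 with prob p_fully_ordered,
    # else Beta(content_a, content_b)
    p_fully_ordered: float = 0.15
    content_a: float = 1.2
    content_b: float = 2.2
    mean_disordered_seglen: float = 25.0
    content_tolerance: float = 0.08
    max_resample: int = 60
    # state-conditional emissions (disordered, ordered)
    rsa_beta_dis: tuple = (5.0, 2.5)
    rsa_beta_ord: tuple = (2.5, 5.0)
    bfactor_mean_dis: float = 0.7
    bfactor_mean_ord: float = -0.35
    bfactor_sd: float = 0.45
    p_flex_strict: tuple = (0.6, 0.1)  # (disordered, ordered)
    p_flex_nonstrict: tuple = (0.85, 0.25)
    p_domain: tuple = (0.12, 0.92)
    p_signal_chain: float = 0.1
    # profile emissions: Dirichlet concentration parameters
    conservation_strength: float = 8.0  # ordered preferred-residue weight
    dirichlet_floor: float = 0.3
    disorder_bias: float = 2.0  # weight on disorder-promoting residues
    dirichlet_floor_dis: float = 0.25
    # propensity simulator
    propensity_bias_sd: float = 0.25
    propensity_noise_sd: float = 0.08
    propensity_smooth_window: int = 9
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _geometric_len(rng, mean: float) -> int:
    return 1 + int(rng.geometric(1.0 / max(mean, 1.0)))


def _draw_state_sequence(config: SimulationConfig, rng, length: int, target: float) -> np.ndarray:
    """Alternating geometric ordered/disordered runs calibrated to the target
    content by acceptance-resampling (closest realization kept)."""
    if target <= 0.0:
        return np.zeros(length, dtype=np.int8)
    if target >= 1.0:
        return np.ones(length, dtype=np.int8)
    mu_d = max(3.0, min(config.mean_disordered_seglen, target * length))
    mu_o = max(3.0, mu_d * (1.0 - target) / target)
    best, best_err = None, np.inf
    for _ in range(config.max_resample):
        states = np.empty(length, dtype=np.int8)
        pos = 0
        state = 1 if rng.random() < target else 0
        while pos < length:
            run = _geometric_len(rng, mu_d if state else mu_o)
            states[pos : pos + run] = state
            pos += run
            state = 1 - state
        realized = states.mean()
        err = abs(realized - target)
        if err < best_err:
            best, best_err = states, err
        if err <= config.content_tolerance:
            break
    return best


def _generate_ss(rng, states: np.ndarray) -> str:
    """Segmental 3-state secondary structure conditioned on disorder state."""
    L = len(states)
    ss = []
    i = 0
    while i < L:
        disordered = bool(states[i])
        if disordered:
            # mostly long coil, occasional short helix
            if rng.random() < 0.15:
                kind, mean = "H", 4.0
            else:
                kind, mean = "C", 12.0
        else:
            u = rng.random()
            if u < 0.35:
                kind, mean = "H", 9.0
            elif u < 0.65:
                kind, mean = "E", 5.0
            else:
                kind, mean = "C", 4.0
        run = _geometric_len(rng, mean)
        # stay within the current disorder segment
        j = i
        while j < L and j - i < run and bool(states[j]) == disordered:
            ss.append(kind)
            j += 1
        i = j
    return "".join(ss)


def _profile_rows(config: SimulationConfig, rng, states: np.ndarray) -> np.ndarray:
    """Per-residue 20-dim probability rows, conservation coupled to order."""
    L = len(states)
    probs = np.empty((L, 20))
    for i in range(L):
        alpha = np.full(20, config.dirichlet_floor_dis if states[i] else config.dirichlet_floor)
        if states[i]:
            alpha[_DIS_IDX] += config.disorder_bias
        else:
            preferred = rng.integers(0, 20)
            alpha[preferred] += config.conservation_strength
        probs[i] = rng.dirichlet(alpha)
    return probs


def generate_protein(config: SimulationConfig, rng, protein_id: str = "syn") -> ProteinRecord:
    """Draw one complete protein record with disorder labels and content."""
    L = int(rng.integers(config.length_min, config.length_max + 1))
    if rng.random() < config.p_fully_ordered:
        target = 0.0
    else:
        target = float(rng.beta(config.content_a, config.content_b))
    states = _draw_state_sequence(config, rng, L, target)
    dis = states.astype(bool)

    probs = _profile_rows(config, rng, states)
    seq_idx = np.array([rng.choice(20, p=probs[i]) for i in range(L)])
    sequence = "".join(AA_ALPHABET[j] for j in seq_idx)

    wop = np.round(probs * 100.0)
    clipped = np.clip(probs, 1e-4, 1 - 1e-4)
    pssm = np.clip(np.round(np.log(clipped / (1 - clipped))), -9, 12).astype(int)

    ss = _generate_ss(rng, states)
    rsa = np.where(
        dis,
        rng.beta(*config.rsa_beta_dis, size=L),
        rng.beta(*config.rsa_beta_ord, size=L),
    )
    bf = rng.normal(
        np.where(dis, config.bfactor_mean_dis, config.bfactor_mean_ord),
        config.bfactor_sd,
    )
    flex_s = (rng.random(L) < np.where(dis, *config.p_flex_strict)).astype(np.int8)
    flex_ns = (rng.random(L) < np.where(dis, *config.p_flex_nonstrict)).astype(np.int8)
    domain = (rng.random(L) < np.where(dis, *config.p_domain)).astype(np.int8)
    signal = np.zeros(L, dtype=np.int8)
    if rng.random() < config.p_signal_chain:
        signal[: int(rng.integers(15, 26))] = 1

    return assemble_record(
        protein_id,
        sequence,
        pssm=pssm,
        wop=wop,
        ss=ss,
        rsa=rsa,
        rsa_is_relative=True,
        bfactor=bf,
        flex_strict=flex_s,
        flex_nonstrict=flex_ns,
        domain=domain,
        signal=signal,
        disorder=DisorderAnnotation(protein_id, labels=states),
    )


def generate_records(config: SimulationConfig) -> list[ProteinRecord]:
    """Generate ``config.n_proteins`` records, deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    return [generate_protein(config, rng, f"syn{i:04d}") for i in range(config.n_proteins)]


def generate_dataset(config: SimulationConfig, outdir=None) -> tuple[list[ProteinRecord], dict]:
    """Generate records and optionally write them in the package's formats.

    When ``outdir`` is given, writes ``sequences.fasta``, one PSI-BLAST-style
    profile per chain under ``profiles/``, one track table per chain under
    ``tracks/``, ``labels.tsv`` and a ``manifest.json`` recording the seed
    and config hash.  Byte-identical across runs with the same config.
    """
    records = generate_records(config)
    manifest = {
        "n_proteins": config.n_proteins,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "config": config.to_dict(),
        "ids": [r.id for r in records],
    }
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "profiles").mkdir(parents=True, exist_ok=True)
        (outdir / "tracks").mkdir(parents=True, exist_ok=True)
        if records:
            io_formats.write_fasta(outdir / "sequences.fasta",
                                   [(r.id, r.sequence) for r in records])
            anns = [DisorderAnnotation(r.id, labels=r.disorder_labels) for r in records]
            io_formats.write_disorder_labels(outdir / "labels.tsv", anns)
        for r in records:
            io_formats.write_pssm_ascii(outdir / "profiles" / f"{r.id}.pssm",
                                        r.pssm, r.wop, r.sequence)
            io_formats.write_track_table(
                outdir / "tracks" / f"{r.id}.tsv", r.sequence,
                {"ss": r.ss, "rsa": r.rsa, "bf": r.bfactor,
                 "flex_strict": r.flex_strict, "flex_nonstrict": r.flex_nonstrict,
                 "domain": r.domain, "signal": r.signal})
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return records, manifest


def load_dataset(directory) -> list[ProteinRecord]:
    """Re-assemble records from a directory written by :func:`generate_dataset`."""
    directory = Path(directory)
    seqs, _ = io_formats.read_fasta(directory / "sequences.fasta")
    anns = {a.chain_id: a for a in io_formats.read_disorder_labels(directory / "labels.tsv")}
    records = []
    for rec_id, seq in seqs:
        pssm, wop, _ = io_formats.read_pssm_ascii(directory / "profiles" / f"{rec_id}.pssm")
        tracks = io_formats.read_track_table(directory / "tracks" / f"{rec_id}.tsv")
        records.append(assemble_record(
            rec_id, seq, pssm=pssm, wop=wop,
            ss=tracks.get("ss"), rsa=tracks.get("rsa"), rsa_is_relative=True,
            bfactor=tracks.get("bf"),
            flex_strict=tracks.get("flex_strict"),
            flex_nonstrict=tracks.get("flex_nonstrict"),
            domain=tracks.get("domain"), signal=tracks.get("signal"),
            disorder=anns.get(rec_id)))
    return records


def simulate_propensities(records, config: SimulationConfig, rng=None):
    """Simulated residue-level predictor outputs with per-chain scale bias.

    For each chain the true binary labels are smoothed with a moving average,
    shifted by a per-chain bias ~ N(0, bias_sd), perturbed with Gaussian
    noise, and squashed through a monotone logistic link.  Returns a list of
    :class:`discon.thresholding.PropensityTrack`-compatible arrays paired
    with the chain ids.
    """
    from discon.thresholding import PropensityTrack

    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    w = config.propensity_smooth_window
    kernel = np.ones(w) / w
    out = []
    for rec in records:
        labels = rec.disorder_labels.astype(float)
        base = np.convolve(labels, kernel, mode="same")
        bias = rng.normal(0.0, config.propensity_bias_sd)
        raw = base + bias + rng.normal(0.0, config.propensity_noise_sd, len(labels))
        prop = 1.0 / (1.0 + np.exp(-4.0 * (raw - 0.5)))
        out.append(PropensityTrack(rec.id, prop, source="simulated", default_cutoff=0.5))
    return out
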