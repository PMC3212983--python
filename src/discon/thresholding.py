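"""Content-guided thresholding of real-valued disorder propensities.

Per-residue disorder predictors emit a real-valued propensity per residue and
binarize it with one fixed cutoff for every chain.  When a chain-level
disorder-content estimate is available, the cutoff can instead be adjusted
per chain so that the number of residues called disordered matches the
estimated content — this removes the per-chain over-/under-prediction bias
of the fixed cutoff.  The module also provides the hybrid content rule
(use the residue-level predictor's own content when it is extreme, i.e.
> 0.65 or < 0.1, otherwise the regression estimate), the best fixed cutoff
on a reference set, and the chain-level content-cutoff classification sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from discon.evaluation import confusion_counts, mcc_from_counts

HYBRID_HIGH = 0.65
HYBRID_LOW = 0.1


@dataclass
class PropensityTrack:
    """Per-residue real-valued disorder propensities for one chain."""

    chain_id: str
    propensities: np.ndarray
    source: str = ""
    default_cutoff: Optional[float] = None

    def __post_init__(self):
        self.propensities = np.asarray(self.propensities, dtype=float)
        if not np.isfinite(self.propensities).all():
            raise ValueError(f"{self.chain_id}: non-finite propensity values")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def content_guided_binarize(track, content: float) -> tuple[np.ndarray, float]:
    """Label exactly ``round(content * L)`` top-propensity residues disordered.

    Rounding is half-up; ties in propensity are broken toward the N-terminus
    (stable).  Returns the binary labels and the implied threshold (the m-th
    highest propensity; ``+inf`` when m = 0).
    """
    if not (0.0 <= content <= 1.0):
        raise ValueError(f"content {content} outside [0, 1]")
    p = track.propensities if isinstance(track, PropensityTrack) else np.asarray(track, dtype=float)
    L = len(p)
    m = _round_half_up(content * L)
    m = min(m, L)
    labels = np.zeros(L, dtype=np.int8)
    if m > 0:
        order = np.argsort(-p, kind="stable")  # stable: earlier position wins ties
        chosen = order[:m]
        labels[chosen] = 1
        threshold = float(p[order[m - 1]])
    else:
        threshold = math.inf
    return labels, threshold


def hybrid_content(md_content: float, discon_content: float) -> float:
    """Combine a residue-level predictor's own content with the regression one.

    The residue-level estimate is kept when it is extreme (> 0.65 or < 0.1),
    where such predictors are the more reliable; otherwise the regression
    content is used.
    """
    for name, v in (("md_content", md_content), ("discon_content", discon_content)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} {v} outside [0, 1]")
    if md_content > HYBRID_HIGH or md_content < HYBRID_LOW:
        return md_content
    return discon_content


def optimal_fixed_cutoff(
    tracks: Sequence,
    references: Sequence,
) -> tuple[float, float]:
    """Single cutoff maximizing the pooled residue-level MCC.

    Residues from all chains are pooled; candidate cutoffs are the midpoints
    between consecutive distinct propensity values plus sentinels below the
    minimum and above the maximum.  A residue is called disordered when its
    propensity >= cutoff.  Ties in MCC go to the lower cutoff.  Returns
    (cutoff, MCC at the cutoff).
    """
    props = np.concatenate([
        t.propensities if isinstance(t, PropensityTrack) else np.asarray(t, dtype=float)
        for t in tracks
    ])
    refs = np.concatenate([np.asarray(r).astype(int) for r in references])
    if props.shape != refs.shape:
        raise ValueError("pooled propensities and references differ in length")
    if refs.min() == refs.max():
        raise ValueError("reference contains a single class; MCC cutoff undefined")
    distinct = np.unique(props)
    candidates = [distinct[0] - 1.0]
    candidates.extend(((distinct[:-1] + distinct[1:]) / 2.0).tolist())
    candidates.append(distinct[-1] + 1.0)
    best_cut, best_mcc = candidates[0], -2.0
    for cut in candidates:
        mcc = mcc_from_counts(*confusion_counts(props >= cut, refs))
        if mcc > best_mcc:
            best_cut, best_mcc = cut, mcc
    return float(best_cut), float(best_mcc)


def content_class_sweep(
    predicted_contents,
    native_contents,
    step: float = 0.05,
) -> list[dict]:
    """Chain-level binary classification MCC across content cutoffs.

    For each cutoff t in {0, step, ..., 1}, chains are labeled positive when
    their content exceeds t, by the native and by the predicted content, and
    the MCC of that binary problem is reported.  Cutoffs where the native
    labeling is single-class are flagged with MCC ``None`` rather than a
    fabricated 0.
    """
    x = np.asarray(predicted_contents, dtype=float)
    y = np.asarray(native_contents, dtype=float)
    n_steps = int(round(1.0 / step))
    out = []
    for i in range(n_steps + 1):
        t = i * step
        ref = y > t
        pred = x > t
        if ref.all() or not ref.any():
            out.append({"cutoff": t, "mcc": None, "flag": "single-class reference"})
        else:
            out.append({"cutoff": t,
                        "mcc": mcc_from_counts(*confusion_counts(pred, ref))})
    return out


def read_propensity_tsv(path) -> list[PropensityTrack]:
    """Read propensity tracks from TSV columns ``id  pos  propensity``."""
    chains: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if header[:3] != ["id", "pos", "propensity"]:
            raise ValueError(f"{path}: expected header 'id pos propensity'")
        for line in fh:
            toks = line.split()
            if not toks:
                continue
            chains.setdefault(toks[0], []).append((int(toks[1]), float(toks[2])))
    out = []
    for cid, rows in chains.items():
        rows.sort()
        out.append(PropensityTrack(cid, np.array([v for _, v in rows])))
    return out


def write_binarized_tsv(path, track: PropensityTrack, labels: np.ndarray,
                        threshold: float, content: float, content_source: str) -> None:
    """Write a binarized track mirroring the input plus a 0/1 column."""
    with open(path, "w") as fh:
        fh.write(f"# threshold={threshold:.6g} content={content:.6g} "
                 f"content_source={content_source}\n")
        fh.write("id\tpos\tpropensity\tdisordered\n")
        for i, (p, lab) in enumerate(zip(track.propensities, labels)):
            fh.write(f"{track.chain_id}\t{i + 1}\t{p:.6g}\t{int(lab)}\n")
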