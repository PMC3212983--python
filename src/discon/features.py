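"""Chain-level aggregation features for disorder-content prediction.

A protein record is turned into one fixed-length numeric vector whose entries
aggregate the whole chain: amino-acid composition, secondary-structure /
flexibility / domain / exposure segment statistics, conjunctions ("fusions")
of predicted per-residue states, and Shannon / relative entropies of the
PSI-BLAST PSSM and WOP profile rows and columns, optionally restricted to
residues in a given state.

The feature universe is an enumerable :class:`FeatureCatalog`; the default
catalog spans nine feature families and includes five named features that are
useful markers of order/disorder:

``SS_HE_DOM_in_BFNS_low_RSA_B``
    fraction of helix/strand residues inside globular domains that are rigid
    (low B-factor) and buried — a hallmark of well-structured chains.
``BFNS_low_Seg_10``
    fraction of residues in rigid segments of length >= 10.
``SS_CH_BFNS_high_DOM_notin``
    fraction of coil/helix residues with high B-factor outside domains.
``CHC...CHSeg``
    number of residues in the longest secondary-structure stretch free of
    strands (coil or alternating coil/helix).
``EntAvePSSM``
    entropy of the column-mean profile distribution along the chain.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from discon.records import (
    AA_ALPHABET,
    DISORDER_PROMOTING,
    ORDER_PROMOTING,
    FormatError,
    ProteinRecord,
)

FAMILIES = (
    "aa_comp",
    "ss_segment",
    "exposure",
    "flexibility",
    "domain",
    "signal",
    "fusion",
    "profile_entropy",
    "conditioned_entropy",
)

#: Maximal accessible surface areas (A^2) per residue type, used to convert
#: raw predicted ASA into relative solvent accessibility.
MAX_ASA = {
    "A": 115.0, "C": 149.0, "D": 170.0, "E": 207.0, "F": 230.0,
    "G": 86.0, "H": 206.0, "I": 187.0, "K": 222.0, "L": 192.0,
    "M": 210.0, "N": 184.0, "P": 140.0, "Q": 208.0, "R": 263.0,
    "S": 140.0, "T": 164.0, "V": 161.0, "W": 269.0, "Y": 257.0,
    "X": 190.0,
}

RSA_EXPOSED_CUTOFF = 0.25  # exposed iff RSA > 0.25
MIN_HELIX_RUN = 3  # helices shorter than this are rewritten to coil
SEGMENT_LADDER = (2, 4, 6, 8, 10, 15, 20)

_SEGMENT_STATS = (
    "SegCount", "SegFrac", "SegLongest", "SegMeanLen", "SegFirst", "SegLast", "SegMid",
)

_LOG2_20 = float(np.log2(20.0))


# ---------------------------------------------------------------------------
# numeric helpers
# ---------------------------------------------------------------------------

def shannon_entropy(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy in bits; rows are assumed normalized, 0 log 0 := 0."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=axis)


def relative_entropy(p: np.ndarray, q: Optional[np.ndarray] = None, axis: int = -1) -> np.ndarray:
    """KL divergence in bits of p from the background q (uniform by default)."""
    p = np.asarray(p, dtype=float)
    if q is None:
        q = np.full(p.shape[-1], 1.0 / p.shape[-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / q), 0.0)
    return terms.sum(axis=axis)


def runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (0-based start, length) pairs."""
    mask = np.asarray(mask, dtype=bool)
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i - start))
            start = None
    if start is not None:
        out.append((start, len(mask) - start))
    return out


def pssm_to_probs(pssm: np.ndarray) -> np.ndarray:
    """Map integer log-odds to per-row probabilities: logistic then renormalize."""
    squashed = 1.0 / (1.0 + np.exp(-np.asarray(pssm, dtype=float)))
    return squashed / squashed.sum(axis=1, keepdims=True)


def wop_to_probs(wop: np.ndarray) -> np.ndarray:
    """WOP percentages to probabilities; all-zero rows become uniform."""
    p = np.asarray(wop, dtype=float) / 100.0
    sums = p.sum(axis=1, keepdims=True)
    zero = sums[:, 0] <= 0
    p[zero] = 1.0 / p.shape[1]
    sums[zero] = 1.0
    return p / np.maximum(p.sum(axis=1, keepdims=True), 1e-300)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_tracks(record: ProteinRecord) -> ProteinRecord:
    """Normalize tracks and derive binary exposure / rigidity tracks.

    * every maximal helix run shorter than 3 residues is rewritten to coil
      (strand runs untouched);
    * raw ASA is divided by the residue-type maximal ASA and clipped to [0,1];
    * ``exposed`` := RSA > 0.25;
    * ``rigid`` := normalized B-factor <= 0 (low-B / structurally rigid).

    Absent tracks are skipped.  Idempotent.
    """
    rec = record.copy()
    if rec.ss is not None:
        ss = list(rec.ss)
        for start, length in runs_of(np.array([c == "H" for c in ss])):
            if length < MIN_HELIX_RUN:
                for i in range(start, start + length):
                    ss[i] = "C"
        rec.ss = "".join(ss)
    if rec.rsa is not None:
        rsa = np.asarray(rec.rsa, dtype=float)
        if not rec.rsa_is_relative:
            denom = np.array([MAX_ASA.get(a, MAX_ASA["X"]) for a in rec.sequence])
            rsa = np.clip(rsa / denom, 0.0, 1.0)
            rec.rsa_is_relative = True
        rec.rsa = rsa
        rec.derived["exposed"] = (rsa > RSA_EXPOSED_CUTOFF).astype(np.int8)
    if rec.bfactor is not None:
        rec.derived["rigid"] = (np.asarray(rec.bfactor, dtype=float) <= 0.0).astype(np.int8)
    rec.derived["preprocessed"] = True
    return rec


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDef:
    """One feature: unique id, family, and family-specific parameters."""

    id: str
    family: str
    params: dict

    def key(self):
        return (self.id, self.family, json.dumps(self.params, sort_keys=True))


class FeatureCatalog:
    """Ordered, fingerprinted collection of feature definitions."""

    def __init__(self, defs: list[FeatureDef]):
        ids = [d.id for d in defs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids in catalog: {dupes[:5]}")
        for d in defs:
            if d.family not in FAMILIES:
                raise ValueError(f"unknown feature family '{d.family}'")
        self.defs = list(defs)
        self.ids = ids

    def __len__(self):
        return len(self.defs)

    def __iter__(self):
        return iter(self.defs)

    @property
    def fingerprint(self) -> str:
        blob = json.dumps([d.key() for d in self.defs]).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        doc = [{"id": d.id, "family": d.family, "params": d.params} for d in self.defs]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureCatalog":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls([FeatureDef(e["id"], e["family"], e["params"]) for e in doc])


# component tokens used in fusion / conditioned-entropy ids
_FUSION_SOURCES = {
    "ss": ["H", "E", "C", "HE", "CH", "CE"],
    "exposure": ["exposed", "buried"],
    "bfactor": ["low", "high"],
    "domain": ["in", "notin"],
}
_FUSION_TOKEN = {
    ("exposure", "exposed"): "RSA_E",
    ("exposure", "buried"): "RSA_B",
    ("bfactor", "low"): "BFNS_low",
    ("bfactor", "high"): "BFNS_high",
    ("domain", "in"): "DOM_in",
    ("domain", "notin"): "DOM_notin",
}
# canonical ids for the named features whose historical names deviate from
# the systematic scheme
_NAMED_FUSION_IDS = {
    (("bfactor", "low"), ("domain", "in"), ("exposure", "buried"), ("ss", "HE")):
        "SS_HE_DOM_in_BFNS_low_RSA_B",
    (("bfactor", "high"), ("domain", "notin"), ("ss", "CH")):
        "SS_CH_BFNS_high_DOM_notin",
}


def _fusion_id(combo: dict) -> str:
    key = tuple(sorted(combo.items()))
    if key in _NAMED_FUSION_IDS:
        return _NAMED_FUSION_IDS[key]
    parts = []
    for source in ("ss", "exposure", "bfactor", "domain"):
        if source in combo:
            if source == "ss":
                parts.append(f"SS_{combo['ss']}")
            else:
                parts.append(_FUSION_TOKEN[(source, combo[source])])
    return "FUS_" + "_".join(parts)


def build_default_catalog(ladder: tuple[int, ...] = SEGMENT_LADDER) -> FeatureCatalog:
    """Enumerate the default feature universe over the nine families."""
    defs: list[FeatureDef] = []

    # --- amino-acid composition ------------------------------------------
    for aa in AA_ALPHABET:
        defs.append(FeatureDef(f"AAcomp_{aa}", "aa_comp", {"kind": "residue", "aa": aa}))
    defs.append(FeatureDef("AAcomp_order_promoting", "aa_comp",
                           {"kind": "group", "group": "order_promoting"}))
    defs.append(FeatureDef("AAcomp_disorder_promoting", "aa_comp",
                           {"kind": "group", "group": "disorder_promoting"}))

    # --- segment statistics ----------------------------------------------
    segment_tracks = [
        ("SS_H", "ss_segment", {"track": "ss", "states": "H"}),
        ("SS_E", "ss_segment", {"track": "ss", "states": "E"}),
        ("SS_C", "ss_segment", {"track": "ss", "states": "C"}),
        ("RSA_E", "exposure", {"track": "exposed"}),
        ("BFNS_low", "flexibility", {"track": "rigid"}),
        ("FLEXS", "flexibility", {"track": "flex_strict"}),
        ("FLEXNS", "flexibility", {"track": "flex_nonstrict"}),
        ("DOM_in", "domain", {"track": "domain"}),
        ("SIG", "signal", {"track": "signal"}),
    ]
    for prefix, family, base in segment_tracks:
        for stat in _SEGMENT_STATS:
            defs.append(FeatureDef(f"{prefix}_{stat}", family, {**base, "stat": stat}))
        for k in ladder:
            defs.append(FeatureDef(f"{prefix}_Seg_{k}", family,
                                   {**base, "stat": "SegFracGe", "k": k}))
    # longest strand-free stretch, raw residue count
    defs.append(FeatureDef("CHC...CHSeg", "ss_segment",
                           {"track": "ss", "kind": "longest_strand_free", "scale": "raw"}))

    # --- fusion (conjunctions of 2-4 sources) -----------------------------
    sources = list(_FUSION_SOURCES)
    from itertools import combinations, product

    for r in (2, 3, 4):
        for subset in combinations(sources, r):
            for values in product(*(_FUSION_SOURCES[s] for s in subset)):
                combo = dict(zip(subset, values))
                defs.append(FeatureDef(_fusion_id(combo), "fusion", {"combo": combo}))

    # --- profile entropy ---------------------------------------------------
    for matrix in ("PSSM", "WOP"):
        m = matrix.lower()
        defs.append(FeatureDef(f"EntRowMean{matrix}", "profile_entropy",
                               {"matrix": m, "stat": "row_ent_mean"}))
        defs.append(FeatureDef(f"EntRowMin{matrix}", "profile_entropy",
                               {"matrix": m, "stat": "row_ent_min"}))
        defs.append(FeatureDef(f"EntRowMax{matrix}", "profile_entropy",
                               {"matrix": m, "stat": "row_ent_max"}))
        defs.append(FeatureDef(f"RelEntRowMean{matrix}", "profile_entropy",
                               {"matrix": m, "stat": "row_relent_mean"}))
        defs.append(FeatureDef(f"EntAve{matrix}", "profile_entropy",
                               {"matrix": m, "stat": "col_ent"}))
        defs.append(FeatureDef(f"RelEntAve{matrix}", "profile_entropy",
                               {"matrix": m, "stat": "col_relent"}))

    # --- conditioned row entropy ------------------------------------------
    conditions: list[tuple[str, dict]] = []
    for aa in AA_ALPHABET:
        conditions.append((f"AA_{aa}", {"type": "aa", "value": aa}))
    for s in ("H", "E", "C"):
        conditions.append((f"SS_{s}", {"type": "ss", "value": s}))
    conditions.append(("RSA_E", {"type": "exposure", "value": "exposed"}))
    conditions.append(("RSA_B", {"type": "exposure", "value": "buried"}))
    conditions.append(("FLEXS", {"type": "flexibility", "value": "strict"}))
    conditions.append(("FLEXNS", {"type": "flexibility", "value": "nonstrict"}))
    conditions.append(("DOM_in", {"type": "domain", "value": "in"}))
    conditions.append(("DOM_notin", {"type": "domain", "value": "notin"}))
    for matrix in ("PSSM", "WOP"):
        m = matrix.lower()
        for cname, cond in conditions:
            defs.append(FeatureDef(f"EntRow{matrix}_{cname}", "conditioned_entropy",
                                   {"matrix": m, "stat": "ent", "condition": cond}))
            defs.append(FeatureDef(f"RelEntRow{matrix}_{cname}", "conditioned_entropy",
                                   {"matrix": m, "stat": "rel_ent", "condition": cond}))

    return FeatureCatalog(defs)


# ---------------------------------------------------------------------------
# extraction context
# ---------------------------------------------------------------------------

class _Context:
    """Lazily computed per-record derived quantities shared across features."""

    def __init__(self, record: ProteinRecord):
        if not record.derived.get("preprocessed"):
            record = preprocess_tracks(record)
        self.rec = record
        self.L = len(record)
        self._probs: dict[str, Optional[np.ndarray]] = {}
        self._row_ent: dict[str, Optional[np.ndarray]] = {}
        self._row_relent: dict[str, Optional[np.ndarray]] = {}

    # -- binary masks -------------------------------------------------------
    def mask(self, source: str, value) -> Optional[np.ndarray]:
        """Boolean mask for a (source, value) state; None if track is absent."""
        rec = self.rec
        if source == "aa":
            return np.array([c == value for c in rec.sequence])
        if source == "ss":
            if rec.ss is None:
                return None
            return np.array([c in value for c in rec.ss])
        if source == "exposure":
            exposed = rec.derived.get("exposed")
            if exposed is None:
                return None
            m = exposed.astype(bool)
            return m if value == "exposed" else ~m
        if source == "bfactor":
            rigid = rec.derived.get("rigid")
            if rigid is None:
                return None
            m = rigid.astype(bool)
            return m if value == "low" else ~m
        if source == "flexibility":
            track = rec.flex_strict if value == "strict" else rec.flex_nonstrict
            return None if track is None else track.astype(bool)
        if source == "domain":
            if rec.domain is None:
                return None
            m = rec.domain.astype(bool)
            return m if value == "in" else ~m
        raise ValueError(f"unknown mask source '{source}'")

    def track_mask(self, track: str, states: str = "") -> Optional[np.ndarray]:
        """Mask for segment features: an SS state set or a binary track."""
        if track == "ss":
            return self.mask("ss", states)
        if track == "exposed":
            return self.mask("exposure", "exposed")
        if track == "rigid":
            return self.mask("bfactor", "low")
        if track in ("flex_strict", "flex_nonstrict", "domain", "signal"):
            arr = getattr(self.rec, track)
            return None if arr is None else arr.astype(bool)
        raise ValueError(f"unknown segment track '{track}'")

    # -- profile quantities --------------------------------------------------
    def probs(self, matrix: str) -> Optional[np.ndarray]:
        if matrix not in self._probs:
            raw = getattr(self.rec, matrix)
            if raw is None:
                self._probs[matrix] = None
            elif matrix == "pssm":
                self._probs[matrix] = pssm_to_probs(raw)
            else:
                self._probs[matrix] = wop_to_probs(raw)
        return self._probs[matrix]

    def row_entropies(self, matrix: str) -> Optional[np.ndarray]:
        if matrix not in self._row_ent:
            p = self.probs(matrix)
            self._row_ent[matrix] = None if p is None else shannon_entropy(p, axis=1)
        return self._row_ent[matrix]

    def row_rel_entropies(self, matrix: str) -> Optional[np.ndarray]:
        if matrix not in self._row_relent:
            p = self.probs(matrix)
            self._row_relent[matrix] = None if p is None else relative_entropy(p, axis=1)
        return self._row_relent[matrix]


# ---------------------------------------------------------------------------
# feature-family evaluators
# ---------------------------------------------------------------------------

def composition_features(record: ProteinRecord) -> dict[str, float]:
    """20 residue-type fractions plus order-/disorder-promoting group fractions."""
    L = len(record)
    if L == 0:
        raise FormatError(f"{record.id}: empty sequence")
    seq = record.sequence
    out = {f"AAcomp_{aa}": seq.count(aa) / L for aa in AA_ALPHABET}
    out["AAcomp_order_promoting"] = sum(seq.count(a) for a in ORDER_PROMOTING) / L
    out["AAcomp_disorder_promoting"] = sum(seq.count(a) for a in DISORDER_PROMOTING) / L
    return out


def segment_features(mask: np.ndarray, ladder: tuple[int, ...] = SEGMENT_LADDER) -> dict[str, float]:
    """Run statistics of a boolean per-residue mask, mostly normalized by L.

    Location statistics (first start, last end, longest midpoint) are measured
    from the N-terminus as 1-based positions divided by L; all are 0 when the
    mask has no run.
    """
    mask = np.asarray(mask, dtype=bool)
    L = len(mask)
    runs = runs_of(mask)
    out: dict[str, float] = {}
    out["SegCount"] = len(runs) / L
    out["SegFrac"] = float(mask.sum()) / L
    lengths = [r[1] for r in runs]
    out["SegLongest"] = (max(lengths) / L) if lengths else 0.0
    out["SegMeanLen"] = (float(np.mean(lengths)) / L) if lengths else 0.0
    if runs:
        out["SegFirst"] = (runs[0][0] + 1) / L
        out["SegLast"] = (runs[-1][0] + runs[-1][1]) / L
        start, length = max(runs, key=lambda r: (r[1], -r[0]))
        out["SegMid"] = (start + (length + 1) / 2.0) / L
    else:
        out["SegFirst"] = out["SegLast"] = out["SegMid"] = 0.0
    for k in ladder:
        out[f"Seg_{k}"] = sum(n for n in lengths if n >= k) / L
    return out


def longest_strand_free_segment(record: ProteinRecord) -> tuple[int, float]:
    """Longest contiguous SS stretch with no strand; returns (raw, raw / L)."""
    if record.ss is None:
        raise FormatError(f"{record.id}: no secondary-structure track")
    mask = np.array([c != "E" for c in record.ss])
    runs = runs_of(mask)
    longest = max((r[1] for r in runs), default=0)
    return longest, longest / len(record)


def fusion_value(ctx: _Context, combo: dict) -> Optional[float]:
    """Fraction of residues satisfying the conjunction of all combo states."""
    acc = np.ones(ctx.L, dtype=bool)
    for source, value in combo.items():
        m = ctx.mask(source, value)
        if m is None:
            return None
        acc &= m
    return float(acc.sum()) / ctx.L


def conditioned_entropy_value(ctx: _Context, matrix: str, stat: str, condition: dict):
    """Mean per-row (relative) entropy over residues matching the condition.

    Returns (value, qualified) where qualified is False when no residue
    matches (value 0, flagged by the caller) and None when a required track
    or profile is absent.
    """
    rows = ctx.row_entropies(matrix) if stat == "ent" else ctx.row_rel_entropies(matrix)
    if rows is None:
        return None
    m = ctx.mask(condition["type"],
                 condition["value"] if condition["type"] != "flexibility" else condition["value"])
    if m is None:
        return None
    if not m.any():
        return (0.0, False)
    return (float(rows[m].mean()), True)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """Per-protein feature values aligned to a named catalog."""

    protein_id: str
    values: np.ndarray
    fingerprint: str
    missing: list[str] = field(default_factory=list)  # resolved by missing-track policy
    empty_conditions: list[str] = field(default_factory=list)


def extract_features(record: ProteinRecord, catalog: FeatureCatalog) -> FeatureVector:
    """Evaluate every catalog feature on one record.

    Features whose required track or profile is absent evaluate to 0 and are
    listed in ``missing`` (the missing-track policy); conditioned entropies
    whose condition matches no residue evaluate to 0 and are listed in
    ``empty_conditions``.  The output never contains NaN or infinities.
    """
    ctx = _Context(record)
    values = np.zeros(len(catalog), dtype=float)
    missing: list[str] = []
    empty: list[str] = []

    comp = None
    seg_cache: dict[tuple, Optional[dict]] = {}

    for i, fdef in enumerate(catalog):
        fam, p = fdef.family, fdef.params
        if fam == "aa_comp":
            if comp is None:
                comp = composition_features(ctx.rec)
            if p["kind"] == "residue":
                values[i] = comp[f"AAcomp_{p['aa']}"]
            else:
                values[i] = comp[f"AAcomp_{p['group']}"]
        elif fam in ("ss_segment", "exposure", "flexibility", "domain", "signal"):
            if p.get("kind") == "longest_strand_free":
                if ctx.rec.ss is None:
                    missing.append(fdef.id)
                else:
                    raw, rel = longest_strand_free_segment(ctx.rec)
                    values[i] = raw if p.get("scale", "raw") == "raw" else rel
                continue
            key = (p["track"], p.get("states", ""))
            if key not in seg_cache:
                m = ctx.track_mask(p["track"], p.get("states", ""))
                seg_cache[key] = None if m is None else segment_features(m)
            stats = seg_cache[key]
            if stats is None:
                missing.append(fdef.id)
                continue
            stat = p["stat"]
            values[i] = stats[f"Seg_{p['k']}"] if stat == "SegFracGe" else stats[stat]
        elif fam == "fusion":
            v = fusion_value(ctx, p["combo"])
            if v is None:
                missing.append(fdef.id)
            else:
                values[i] = v
        elif fam == "profile_entropy":
            v = _profile_entropy_stat(ctx, p["matrix"], p["stat"])
            if v is None:
                missing.append(fdef.id)
            else:
                values[i] = v
        elif fam == "conditioned_entropy":
            res = conditioned_entropy_value(ctx, p["matrix"], p["stat"], p["condition"])
            if res is None:
                missing.append(fdef.id)
            else:
                values[i], qualified = res
                if not qualified:
                    empty.append(fdef.id)
        else:  # pragma: no cover - catalog constructor rejects unknown families
            raise ValueError(f"unknown family '{fam}'")

    assert np.isfinite(values).all()
    return FeatureVector(ctx.rec.id, values, catalog.fingerprint, missing, empty)


def _profile_entropy_stat(ctx: _Context, matrix: str, stat: str) -> Optional[float]:
    if stat in ("row_ent_mean", "row_ent_min", "row_ent_max"):
        rows = ctx.row_entropies(matrix)
        if rows is None:
            return None
        return {"row_ent_mean": float(rows.mean()),
                "row_ent_min": float(rows.min()),
                "row_ent_max": float(rows.max())}[stat]
    if stat == "row_relent_mean":
        rows = ctx.row_rel_entropies(matrix)
        return None if rows is None else float(rows.mean())
    p = ctx.probs(matrix)
    if p is None:
        return None
    col_means = p.mean(axis=0)
    col_dist = col_means / col_means.sum()
    if stat == "col_ent":
        return float(shannon_entropy(col_dist))
    if stat == "col_relent":
        return float(relative_entropy(col_dist))
    raise ValueError(f"unknown profile-entropy stat '{stat}'")


def extract_matrix(records, catalog: FeatureCatalog, require_uniform_tracks: bool = True):
    """Extract features for many records into an (ids, X, log) triple.

    When ``require_uniform_tracks`` is set (the default for training data),
    records differing in which tracks they carry raise an error rather than
    silently mixing zero-filled and real feature values.
    """
    records = list(records)
    if require_uniform_tracks and records:
        mask0 = records[0].track_mask
        for rec in records[1:]:
            if rec.track_mask != mask0:
                diff = [k for k in mask0 if rec.track_mask[k] != mask0[k]]
                raise FormatError(
                    f"records '{records[0].id}' and '{rec.id}' differ in track "
                    f"completeness ({', '.join(diff)}); pass "
                    f"require_uniform_tracks=False to override"
                )
    ids, rows, logs = [], [], {}
    for rec in records:
        fv = extract_features(rec, catalog)
        ids.append(fv.protein_id)
        rows.append(fv.values)
        if fv.missing:
            logs[fv.protein_id] = list(fv.missing)
    X = np.vstack(rows) if rows else np.empty((0, len(catalog)))
    return ids, X, logs
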