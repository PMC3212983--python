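"""Protein chain records: sequence, profiles, per-residue tracks, disorder labels.

A :class:`ProteinRecord` holds everything known about one chain.  All tracks
are aligned to the sequence (length ``L``); assembly refuses any track whose
length differs.  Positions are 1-based inclusive in every file format; in
memory, arrays are plain 0-based numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Canonical amino-acid column order used for every PSSM/WOP matrix in memory.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: Residues depleted in disordered regions.
ORDER_PROMOTING = frozenset("WYFILVCN")
#: Residues enriched in disordered regions.
DISORDER_PROMOTING = frozenset("ARGQSEPK")


class FormatError(ValueError):
    """Raised for malformed input files or inconsistent record parts."""


@dataclass
class DisorderAnnotation:
    """Per-chain disorder reference: 1-based inclusive ranges or a binary track.

    Exactly one of ``ranges`` / ``labels`` is set.  Ranges are normalized:
    sorted and merged when overlapping or adjacent.
    """

    chain_id: str
    ranges: Optional[list[tuple[int, int]]] = None
    labels: Optional[np.ndarray] = None

    def to_labels(self, length: int) -> np.ndarray:
        """Binary per-residue track of the given length (1 = disordered)."""
        if self.labels is not None:
            if len(self.labels) != length:
                raise FormatError(
                    f"{self.chain_id}: disorder label length {len(self.labels)} "
                    f"!= sequence length {length}"
                )
            return np.asarray(self.labels, dtype=np.int8)
        out = np.zeros(length, dtype=np.int8)
        for start, end in self.ranges or []:
            if end > length:
                raise FormatError(
                    f"{self.chain_id}: disorder range {start}-{end} exceeds length {length}"
                )
            out[start - 1 : end] = 1
        return out


def normalize_ranges(ranges: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping or adjacent 1-based inclusive ranges."""
    for start, end in ranges:
        if start < 1 or start > end:
            raise FormatError(f"invalid disorder range {start}-{end}")
    merged: list[tuple[int, int]] = []
    for start, end in sorted(ranges):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class ProteinRecord:
    """One protein chain with profiles, aligned tracks and disorder reference.

    Fields other than ``id``/``sequence`` are optional; ``track_mask`` reports
    which are present so that feature extraction can apply its missing-track
    policy explicitly instead of imputing silently.
    """

    id: str
    sequence: str
    pssm: Optional[np.ndarray] = None  # L x 20 integer log-odds
    wop: Optional[np.ndarray] = None  # L x 20 percentages in [0, 100]
    ss: Optional[str] = None  # over {H, E, C}
    rsa: Optional[np.ndarray] = None  # raw ASA (A^2) or relative in [0, 1]
    rsa_is_relative: bool = True
    bfactor: Optional[np.ndarray] = None  # normalized real values
    flex_strict: Optional[np.ndarray] = None
    flex_nonstrict: Optional[np.ndarray] = None
    domain: Optional[np.ndarray] = None
    signal: Optional[np.ndarray] = None
    disorder_labels: Optional[np.ndarray] = None
    content: Optional[float] = None
    derived: dict = field(default_factory=dict)  # tracks added by preprocessing

    TRACK_NAMES = (
        "pssm",
        "wop",
        "ss",
        "rsa",
        "bfactor",
        "flex_strict",
        "flex_nonstrict",
        "domain",
        "signal",
    )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def track_mask(self) -> dict[str, bool]:
        """Which optional tracks are present on this record."""
        return {name: getattr(self, name) is not None for name in self.TRACK_NAMES}

    def copy(self) -> "ProteinRecord":
        return replace(self, derived=dict(self.derived))


def assemble_record(
    record_id: str,
    sequence: str,
    *,
    pssm: Optional[np.ndarray] = None,
    wop: Optional[np.ndarray] = None,
    ss: Optional[str] = None,
    rsa: Optional[np.ndarray] = None,
    rsa_is_relative: bool = True,
    bfactor: Optional[np.ndarray] = None,
    flex_strict=None,
    flex_nonstrict=None,
    domain=None,
    signal=None,
    disorder: Optional[DisorderAnnotation] = None,
    content: Optional[float] = None,
) -> ProteinRecord:
    """Build a length-checked :class:`ProteinRecord` from parsed parts.

    Every supplied track must have length ``L = len(sequence)``; a mismatch
    raises :class:`FormatError` naming the track and both lengths.  When a
    disorder annotation is supplied and ``content`` is not, content is
    computed as (# disordered residues) / L.
    """
    length = len(sequence)
    if length == 0:
        raise FormatError(f"{record_id}: zero-length sequence")

    def _check(name: str, track, expected_rows: int = length):
        if track is None:
            return None
        arr = track if isinstance(track, str) else np.asarray(track)
        n = len(arr)
        if n != expected_rows:
            raise FormatError(f"{record_id}: track '{name}' has length {n}, expected {expected_rows}")
        return arr

    pssm = _check("pssm", pssm)
    wop = _check("wop", wop)
    ss = _check("ss", ss)
    rsa = _check("rsa", rsa)
    bfactor = _check("bfactor", bfactor)
    flex_strict = _check("flex_strict", flex_strict)
    flex_nonstrict = _check("flex_nonstrict", flex_nonstrict)
    domain = _check("domain", domain)
    signal = _check("signal", signal)

    labels = None
    if disorder is not None:
        labels = disorder.to_labels(length)
        if content is None:
            content = float(labels.sum()) / length
    if content is not None and not (0.0 <= content <= 1.0):
        raise FormatError(f"{record_id}: content {content} outside [0, 1]")

    for name, arr in (
        ("flex_strict", flex_strict),
        ("flex_nonstrict", flex_nonstrict),
        ("domain", domain),
        ("signal", signal),
    ):
        if arr is not None and not np.isin(arr, (0, 1)).all():
            raise FormatError(f"{record_id}: binary track '{name}' contains values other than 0/1")

    return ProteinRecord(
        id=record_id,
        sequence=sequence,
        pssm=pssm,
        wop=wop,
        ss=ss,
        rsa=None if rsa is None else np.asarray(rsa, dtype=float),
        rsa_is_relative=rsa_is_relative,
        bfactor=None if bfactor is None else np.asarray(bfactor, dtype=float),
        flex_strict=None if flex_strict is None else np.asarray(flex_strict, dtype=np.int8),
        flex_nonstrict=None if flex_nonstrict is None else np.asarray(flex_nonstrict, dtype=np.int8),
        domain=None if domain is None else np.asarray(domain, dtype=np.int8),
        signal=None if signal is None else np.asarray(signal, dtype=np.int8),
        disorder_labels=labels,
        content=content,
    )
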