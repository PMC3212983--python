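"""Readers and writers for the file formats the pipeline consumes and produces.

Supported formats
-----------------
* FASTA (standard, via Biopython).
* PSI-BLAST ASCII profile (the ``-Q`` matrix dump dialect: one row per residue
  with 20 integer log-odds scores followed by 20 weighted observed
  percentages).
* PSIPRED ``.ss2`` 3-state secondary-structure files.
* ``track_tsv`` (project format): tab-separated table with header
  ``pos aa [ss] [rsa] [bf] [flex_strict] [flex_nonstrict] [domain] [signal]``,
  1-based positions, ``.`` for missing scalar values.
* Disorder labels: one chain per line, ``id<TAB>spec`` where spec is either a
  ``{D,O}`` string or a comma-separated list of 1-based inclusive ranges
  (``12-40,77-77``).
* Feature matrix: TSV with first column ``id``, one column per feature id,
  and an optional final ``content`` column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from discon.records import AA_ALPHABET, DisorderAnnotation, FormatError, normalize_ranges

VALID_AA = set(AA_ALPHABET) | {"X"}

TRACK_TSV_COLUMNS = ("ss", "rsa", "bf", "flex_strict", "flex_nonstrict", "domain", "signal")
_BINARY_COLUMNS = {"flex_strict", "flex_nonstrict", "domain", "signal"}


@dataclass
class ParseReport:
    """Per-file bookkeeping: substitutions to X and other recoverable events."""

    substitutions: int = 0
    messages: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> tuple[list[tuple[str, str]], ParseReport]:
    """Read a FASTA file into ``(id, sequence)`` pairs.

    Sequences are uppercased; any letter outside the 20-residue alphabet
    (plus X) is mapped to ``X`` and counted in the returned report.  Empty
    files, duplicate ids and zero-length sequences are format errors.
    """
    report = ParseReport()
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id '{rec.id}'")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"zero-length sequence for '{rec.id}'")
        cleaned = []
        for ch in seq:
            if ch in VALID_AA:
                cleaned.append(ch)
            else:
                cleaned.append("X")
                report.substitutions += 1
        out.append((rec.id, "".join(cleaned)))
    if not out:
        raise FormatError(f"no FASTA records found in {path}")
    if report.substitutions:
        report.messages.append(f"{report.substitutions} non-standard letters mapped to X")
    return out, report


def write_fasta(path, records: list[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII profile
# ---------------------------------------------------------------------------

def read_pssm_ascii(path) -> tuple[np.ndarray, np.ndarray, str]:
    """Parse a PSI-BLAST ASCII profile into ``(pssm, wop, aa)``.

    Returns an L x 20 integer log-odds matrix and an L x 20 percentage matrix,
    both with columns remapped from the file's header order to the canonical
    alphabet ``A, C, D, ... Y``, plus the residue letters concatenated into a
    string.  Rows must carry exactly 40 numeric profile fields (two trailing
    per-row statistics are tolerated); a malformed row raises
    :class:`FormatError` with its line number.
    """
    with open(path) as fh:
        lines = fh.readlines()

    header_cols: Optional[list[str]] = None
    header_lineno = 0
    for lineno, line in enumerate(lines, start=1):
        toks = line.split()
        if len(toks) >= 20 and all(len(t) == 1 and t.isalpha() for t in toks[:20]):
            header_cols = [t.upper() for t in toks[:20]]
            header_lineno = lineno
            break
    if header_cols is None:
        raise FormatError(f"{path}: no amino-acid header line found")
    try:
        remap = [header_cols.index(a) for a in AA_ALPHABET]
    except ValueError as exc:
        raise FormatError(f"{path}: line {header_lineno}: cannot remap header columns: {exc}")

    pssm_rows: list[list[int]] = []
    wop_rows: list[list[float]] = []
    residues: list[str] = []
    expected_idx = 1
    for lineno, line in enumerate(lines[header_lineno:], start=header_lineno + 1):
        toks = line.split()
        if len(toks) < 2 or not toks[0].lstrip("-").isdigit():
            continue  # blank lines / trailing statistics block
        idx = int(toks[0])
        aa = toks[1]
        numeric = toks[2:]
        if len(numeric) == 42:
            numeric = numeric[:40]  # drop per-row information/weight statistics
        if len(numeric) != 40:
            raise FormatError(
                f"{path}: line {lineno}: expected 40 profile fields, found {len(numeric)}"
            )
        if idx != expected_idx:
            raise FormatError(
                f"{path}: line {lineno}: position index {idx}, expected {expected_idx}"
            )
        expected_idx += 1
        try:
            scores = [int(t) for t in numeric[:20]]
            percents = [float(t) for t in numeric[20:]]
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: non-numeric profile field")
        pssm_rows.append([scores[j] for j in remap])
        wop_rows.append([percents[j] for j in remap])
        residues.append(aa.upper())
    if not pssm_rows:
        raise FormatError(f"{path}: no profile rows found")
    return (
        np.asarray(pssm_rows, dtype=int),
        np.asarray(wop_rows, dtype=float),
        "".join(residues),
    )


def write_pssm_ascii(path, pssm: np.ndarray, wop: np.ndarray, sequence: str) -> None:
    """Write matrices in the PSI-BLAST ASCII profile layout (canonical columns)."""
    pssm = np.asarray(pssm)
    wop = np.asarray(wop)
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        cols = "  ".join(AA_ALPHABET)
        fh.write(f"          {cols}  {cols}\n")
        for i, aa in enumerate(sequence):
            scores = " ".join(f"{int(v):3d}" for v in pssm[i])
            pct = " ".join(f"{int(round(v)):3d}" for v in wop[i])
            fh.write(f"{i + 1:5d} {aa} {scores}  {pct}\n")


# ---------------------------------------------------------------------------
# Per-residue track tables
# ---------------------------------------------------------------------------

def read_track_table(path, dialect: str = "track_tsv") -> dict:
    """Read per-residue tracks from ``track_tsv`` or a PSIPRED ``.ss2`` file.

    Returns a dict with only the columns present: ``aa`` and ``ss`` as
    strings, real-valued tracks as float arrays (NaN where the file holds
    ``.``), binary tracks as int arrays restricted to {0, 1}.
    """
    if dialect == "psipred_ss2":
        return _read_ss2(path)
    if dialect != "track_tsv":
        raise FormatError(f"unknown track dialect '{dialect}'")

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "pos" not in df.columns:
        raise FormatError(f"{path}: track_tsv requires a 'pos' column")
    pos = df["pos"].astype(int).to_numpy()
    if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
        raise FormatError(f"{path}: position column must be contiguous 1..L")

    out: dict = {}
    if "aa" in df.columns:
        out["aa"] = "".join(df["aa"].tolist())
    if "ss" in df.columns:
        states = df["ss"].tolist()
        bad = [s for s in states if s not in ("H", "E", "C")]
        if bad:
            raise FormatError(f"{path}: unknown secondary-structure state '{bad[0]}'")
        out["ss"] = "".join(states)
    for col in ("rsa", "bf"):
        if col in df.columns:
            vals = df[col].replace(".", "nan").astype(float).to_numpy()
            out[col] = vals
    for col in _BINARY_COLUMNS:
        if col in df.columns:
            raw = df[col].to_numpy()
            for row_i, v in enumerate(raw):
                if v not in ("0", "1"):
                    raise FormatError(f"{path}: row {row_i + 1}: binary column '{col}' holds '{v}'")
            out[col] = raw.astype(int)
    return out


def _read_ss2(path) -> dict:
    states: list[str] = []
    residues: list[str] = []
    expected = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks or toks[0].startswith("#") or not toks[0].isdigit():
                continue
            if len(toks) < 3:
                raise FormatError(f"{path}: line {lineno}: truncated ss2 row")
            idx = int(toks[0])
            if idx != expected:
                raise FormatError(f"{path}: line {lineno}: non-monotone position {idx}")
            expected += 1
            if toks[2] not in ("H", "E", "C"):
                raise FormatError(f"{path}: line {lineno}: unknown state '{toks[2]}'")
            residues.append(toks[1])
            states.append(toks[2])
    if not states:
        raise FormatError(f"{path}: no ss2 rows found")
    return {"aa": "".join(residues), "ss": "".join(states)}


def write_track_table(path, sequence: str, tracks: dict) -> None:
    """Write the project track_tsv format; ``.`` marks missing scalar values."""
    cols = [c for c in TRACK_TSV_COLUMNS if c in tracks]
    with open(path, "w") as fh:
        fh.write("pos\taa\t" + "\t".join(cols) + "\n")
        for i, aa in enumerate(sequence):
            row = [str(i + 1), aa]
            for c in cols:
                v = tracks[c][i]
                if c == "ss":
                    row.append(v)
                elif c in _BINARY_COLUMNS:
                    row.append(str(int(v)))
                else:
                    row.append("." if (isinstance(v, float) and math.isnan(v)) else f"{float(v):.10g}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Disorder labels
# ---------------------------------------------------------------------------

def read_disorder_labels(path) -> list[DisorderAnnotation]:
    """Read per-chain disorder annotations (``{D,O}`` strings or range lists)."""
    out: list[DisorderAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                chain_id, spec = line.split("\t", 1)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: expected 'id<TAB>spec'")
            spec = spec.strip()
            if set(spec) <= {"D", "O"} and spec:
                labels = np.fromiter((1 if c == "D" else 0 for c in spec), dtype=np.int8)
                out.append(DisorderAnnotation(chain_id, labels=labels))
            else:
                ranges = []
                for part in spec.split(","):
                    part = part.strip()
                    if not part:
                        continue
                    try:
                        start_s, end_s = part.split("-")
                        start, end = int(start_s), int(end_s)
                    except ValueError:
                        raise FormatError(f"{path}: line {lineno}: bad range '{part}'")
                    if start > end or start < 1:
                        raise FormatError(f"{path}: line {lineno}: invalid range {start}-{end}")
                    ranges.append((start, end))
                out.append(DisorderAnnotation(chain_id, ranges=normalize_ranges(ranges)))
    return out


def write_disorder_labels(path, annotations: list[DisorderAnnotation]) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            if ann.labels is not None:
                spec = "".join("D" if v else "O" for v in ann.labels)
            else:
                spec = ",".join(f"{s}-{e}" for s, e in (ann.ranges or []))
            fh.write(f"{ann.chain_id}\t{spec}\n")


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

def write_feature_matrix(path, ids, matrix: np.ndarray, feature_ids, content=None) -> None:
    df = pd.DataFrame(np.asarray(matrix), columns=list(feature_ids))
    df.insert(0, "id", list(ids))
    if content is not None:
        df["content"] = np.asarray(content, dtype=float)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_matrix(path) -> tuple[list[str], np.ndarray, list[str], Optional[np.ndarray]]:
    """Read a feature-matrix TSV → ``(ids, X, feature_ids, content-or-None)``."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "id":
        raise FormatError(f"{path}: first column must be 'id'")
    ids = df["id"].astype(str).tolist()
    content = None
    if "content" in df.columns:
        content = df["content"].to_numpy(dtype=float)
        df = df.drop(columns=["content"])
    feature_ids = [c for c in df.columns if c != "id"]
    return ids, df[feature_ids].to_numpy(dtype=float), feature_ids, content
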