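"""Iterative low-complexity detection (CAST-style) and region LCAA% statistics.

The detector scores the sequence against an infinite homopolymer of each
residue type using per-position substitution scores (BLOSUM62 by default)
and finds the maximal-scoring contiguous segment per type.  While the best
(type, segment) score reaches the threshold (default 40), occurrences of
that dominant residue inside the segment are masked with ``X`` and the scan
repeats.  Only the dominant residue type is replaced, so interleaved
non-repeat residues survive; LCAA% counts masked residues per region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from idrscape.seqio import CANONICAL_AA, ProteinRecord

DEFAULT_THRESHOLD = 40.0

_BLOSUM62 = None


def blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


@dataclass(frozen=True)
class LowComplexitySegment:
    """One masked low-complexity segment (0-based half-open)."""

    protein_id: str
    start: int
    end: int
    dominant_residue: str
    score: float


def _max_segment(scores: np.ndarray) -> tuple[float, int, int]:
    """Maximal-scoring contiguous segment by a single linear scan (Kadane).

    Ties resolve to the leftmost, shortest segment.  Returns
    (score, start, end) with end exclusive; score may be negative when every
    entry is negative (single best element).
    """
    best = -np.inf
    best_start = best_end = 0
    cur = 0.0
    cur_start = 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur = float(s)
            cur_start = i
        else:
            cur += float(s)
        if cur > best:
            best = cur
            best_start, best_end = cur_start, i + 1
    return best, best_start, best_end


def _max_segment_bruteforce(scores: np.ndarray) -> tuple[float, int, int]:
    """O(n^2) enumeration of all segments; oracle for :func:`_max_segment`."""
    best = -np.inf
    best_start = best_end = 0
    n = len(scores)
    for i in range(n):
        total = 0.0
        for j in range(i, n):
            total += float(scores[j])
            if total > best:
                best, best_start, best_end = total, i, j + 1
    return best, best_start, best_end


def cast_mask(
    sequence: str,
    protein_id: str = "",
    matrix=None,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[str, list[LowComplexitySegment]]:
    """Iteratively mask low-complexity segments; returns (masked, segments).

    Deterministic: at each round the candidate with the highest score wins,
    ties broken by leftmost start then alphabetical residue.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if matrix is None:
        matrix = blosum62()
    seq = list(sequence)
    segments: list[LowComplexitySegment] = []
    while True:
        best: tuple[float, int, str, int] | None = None  # (-score, start, res, end)
        for r in CANONICAL_AA:
            scores = np.array([matrix[c, r] for c in seq], dtype=float) if seq else np.array([])
            if scores.size == 0:
                break
            score, start, end = _max_segment(scores)
            if score >= threshold and r in seq[start:end]:
                key = (-score, start, r, end)
                if best is None or key < best:
                    best = key
        if best is None:
            break
        neg_score, start, r, end = best
        for i in range(start, end):
            if seq[i] == r:
                seq[i] = "X"
        segments.append(
            LowComplexitySegment(protein_id, start, end, r, -neg_score)
        )
    return "".join(seq), segments


def masked_positions(sequence: str, masked: str) -> np.ndarray:
    """Boolean array marking residues masked by :func:`cast_mask`."""
    if len(sequence) != len(masked):
        raise ValueError("sequence/mask length mismatch")
    return np.array(
        [m == "X" and s != "X" for s, m in zip(sequence, masked)], dtype=bool
    )


def lcaa_by_region(
    records: Sequence[ProteinRecord],
    masked_seqs: dict[str, str],
) -> pd.DataFrame:
    """Percentage of low-complexity residues per protein and region class.

    Region classes: ``full``, ``ap2``, ``beta``, ``alpha``, ``non_ap2``.
    A region class absent from a protein's annotation yields NaN (missing),
    never 0.
    """
    rows = []
    for rec in records:
        if rec.id not in masked_seqs:
            raise ValueError(f"no mask for {rec.id}")
        mask = masked_positions(rec.sequence, masked_seqs[rec.id])
        n = len(rec.sequence)
        ap2 = np.zeros(n, dtype=bool)
        for r in rec.ap2_spans():
            ap2[r.start:r.end] = True
        classes: dict[str, np.ndarray | None] = {
            "full": np.ones(n, dtype=bool),
            "ap2": ap2 if ap2.any() else None,
            "non_ap2": ~ap2 if (~ap2).any() else None,
        }
        for label, key in (("BETA", "beta"), ("ALPHA", "alpha")):
            sel = np.zeros(n, dtype=bool)
            for r in rec.spans(label):
                sel[r.start:r.end] = True
            classes[key] = sel if sel.any() else None
        row = {"id": rec.id}
        for key in ("full", "ap2", "beta", "alpha", "non_ap2"):
            sel = classes.get(key)
            row[key] = (
                float("nan") if sel is None else 100.0 * mask[sel].mean()
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def write_segments(segments: Sequence[LowComplexitySegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tstart\tend\tresidue\tscore\n")
        for s in segments:
            fh.write(f"{s.protein_id}\t{s.start + 1}\t{s.end}\t"
                     f"{s.dominant_residue}\t{s.score:g}\n")
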