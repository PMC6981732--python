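"""Per-residue disorder tracks and whole-protein binary disorder classifiers.

Two classical sequence-only classifiers are implemented:

* the charge-hydropathy (CH) plot — mean normalised Kyte-Doolittle
  hydropathy ``<H>`` against absolute mean net charge ``<R>``, with the
  linear boundary ``<R> = a*<H> - b`` (defaults a=2.785, b=1.151, the
  published boundary) separating disordered (above) from compact (below);
* the cumulative-distribution-function (CDF) plot — the fraction of residues
  at or below each disorder-score bin, compared against configurable
  boundary points; curves above the boundary indicate ordered proteins.

The two signed boundary distances combine into a CH-CDF phase space whose
quadrants encode the agreement of the classifiers: with x = CDF distance
(positive = ordered by CDF) and y = CH distance (positive = disordered by
CH), Q1 (upper-right) is CH-disordered/CDF-ordered, Q2 (lower-right) ordered
by both, Q3 (lower-left) CDF-disordered/CH-compact, and Q4 (upper-left)
disordered by both.

Per-residue scores normally come from an external predictor track
(:func:`read_track`); :func:`internal_track` is a simple windowed
charge/hydropathy stand-in so the pipeline runs self-contained.  It makes no
claim of reproducing any trained predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from idrscape.seqio import ProteinRecord

logger = logging.getLogger(__name__)

#: Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: default CH boundary <R> = a*<H> - b
CH_BOUNDARY_A = 2.785
CH_BOUNDARY_B = 1.151

#: default CDF evaluation bins
CDF_BINS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))

#: residues counted as disorder-promoting in the compositional IDAA% mode
DISORDER_PROMOTING = set("ARGQSPEK")


@dataclass
class DisorderTrack:
    """Per-residue disorder propensity in [0, 1] for one protein."""

    protein_id: str
    scores: np.ndarray
    source: str = "internal"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError(f"{self.protein_id}: empty or non-1D track")
        if (self.scores < 0).any() or (self.scores > 1).any():
            raise ValueError(f"{self.protein_id}: scores outside [0, 1]")

    def __len__(self) -> int:
        return self.scores.size


@dataclass
class CHPoint:
    """One protein's position on the charge-hydropathy plot."""

    mean_hydropathy: float
    mean_net_charge: float
    ch_distance: float        # raw vertical offset from the boundary
    ch_perpendicular: float   # same offset projected perpendicular to the line


@dataclass
class CDFCurve:
    """Cumulative disorder-score histogram evaluated at fixed bins."""

    bin_scores: np.ndarray
    cdf_values: np.ndarray
    cdf_distance: float | None = None


@dataclass
class PhasePoint:
    """One protein (or region view) in CH-CDF phase space."""

    protein_id: str
    ch_distance: float
    cdf_distance: float
    quadrant: str = field(init=False)

    def __post_init__(self) -> None:
        self.quadrant = chcdf_quadrant(self.ch_distance, self.cdf_distance)


def _rescaled_kd(sequence: str) -> np.ndarray:
    """Kyte-Doolittle values rescaled to [0,1]; X positions are NaN."""
    return np.array(
        [(KYTE_DOOLITTLE[c] + 4.5) / 9.0 if c in KYTE_DOOLITTLE else np.nan
         for c in sequence]
    )


def _window_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average, window truncated at the ends, NaNs ignored."""
    half = window // 2
    n = values.size
    out = np.empty(n)
    for i in range(n):
        w = values[max(0, i - half):min(n, i + half + 1)]
        out[i] = np.nan if np.all(np.isnan(w)) else np.nanmean(w)
    return out


def kd_hydropathy(sequence: str, window: int = 5) -> float:
    """Mean normalised Kyte-Doolittle hydropathy ``<H>`` in [0, 1].

    Per-residue values are rescaled via ``(h + 4.5)/9``, smoothed with a
    centred window (truncated at the ends) and averaged.  ``X`` residues are
    excluded.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(sequence):
        raise ValueError("window exceeds sequence length")
    vals = _rescaled_kd(sequence)
    smoothed = _window_mean(vals, window)
    if np.all(np.isnan(smoothed)):
        raise ValueError("no canonical residues")
    return float(np.nanmean(smoothed))


def mean_net_charge(sequence: str, histidine_charged: bool = False) -> float:
    """Absolute mean net charge ``<R>`` = |#(K,R) - #(D,E)| / length."""
    if not sequence:
        raise ValueError("empty sequence")
    pos = sequence.count("K") + sequence.count("R")
    if histidine_charged:
        pos += sequence.count("H")
    neg = sequence.count("D") + sequence.count("E")
    length = sum(1 for c in sequence if c != "X")
    if length == 0:
        raise ValueError("no canonical residues")
    return abs(pos - neg) / length


def ch_distance(
    mean_h: float,
    mean_r: float,
    a: float = CH_BOUNDARY_A,
    b: float = CH_BOUNDARY_B,
) -> float:
    """Signed raw distance ``<R> - (a*<H> - b)``; positive = disordered side."""
    return mean_r - (a * mean_h - b)


def ch_point(
    sequence: str,
    window: int = 5,
    a: float = CH_BOUNDARY_A,
    b: float = CH_BOUNDARY_B,
    histidine_charged: bool = False,
) -> CHPoint:
    """Charge-hydropathy coordinates and boundary distance for one sequence."""
    h = kd_hydropathy(sequence, window)
    r = mean_net_charge(sequence, histidine_charged)
    raw = ch_distance(h, r, a, b)
    return CHPoint(h, r, raw, raw / np.sqrt(1 + a * a))


def internal_track(
    sequence: str,
    window: int = 21,
    a: float = CH_BOUNDARY_A,
    b: float = CH_BOUNDARY_B,
    gain: float = 0.25,
) -> DisorderTrack:
    """Windowed charge/hydropathy disorder stand-in.

    Per-residue score = clamp to [0,1] of ``0.5 - gain*(a*H_w - b - R_w)``
    where ``H_w`` and ``R_w`` are the windowed mean hydropathy and absolute
    net charge.  Windows rich in charge and poor in hydrophobics score above
    0.5 (disordered), hydrophobic windows below.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    kd = _rescaled_kd(sequence)
    h_w = _window_mean(kd, window)
    charge = np.array(
        [1.0 if c in "KR" else -1.0 if c in "DE" else 0.0 for c in sequence]
    )
    r_w = np.abs(_window_mean(charge, window))
    scores = 0.5 - gain * (a * h_w - b - r_w)
    scores = np.clip(np.nan_to_num(scores, nan=0.5), 0.0, 1.0)
    return DisorderTrack("", scores, source="internal")


def read_track(
    path: str | Path, records: Sequence[ProteinRecord]
) -> dict[str, DisorderTrack]:
    """Read per-residue score tracks (TSV: id, position 1-based, residue, score).

    Positions must be gap-free 1..L and residues must match the FASTA
    sequence; scores outside [0, 1] are clamped with a warning.
    """
    by_id = {r.id: r for r in records}
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "residue": str})
    required = {"id", "position", "residue", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"track table needs columns {sorted(required)}")
    out: dict[str, DisorderTrack] = {}
    for pid, grp in df.groupby("id", sort=False):
        if pid not in by_id:
            raise ValueError(f"track for unknown protein {pid!r}")
        rec = by_id[pid]
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        if not np.array_equal(positions, np.arange(1, len(rec.sequence) + 1)):
            raise ValueError(f"{pid}: track positions are not 1..{len(rec.sequence)}")
        track_res = "".join(grp["residue"])
        if track_res != rec.sequence:
            raise ValueError(f"{pid}: track residues do not match sequence")
        scores = grp["score"].to_numpy(dtype=float)
        if (scores < 0).any() or (scores > 1).any():
            logger.warning("%s: clamping %d score(s) to [0, 1]",
                           pid, int(((scores < 0) | (scores > 1)).sum()))
            scores = np.clip(scores, 0.0, 1.0)
        out[pid] = DisorderTrack(pid, scores, source=f"external:{Path(path).stem}")
    return out


def write_track(
    tracks: dict[str, DisorderTrack],
    records: Sequence[ProteinRecord],
    path: str | Path,
) -> None:
    by_id = {r.id: r for r in records}
    with open(path, "w") as fh:
        fh.write("id\tposition\tresidue\tscore\n")
        for pid, track in tracks.items():
            seq = by_id[pid].sequence
            for i, s in enumerate(track.scores):
                fh.write(f"{pid}\t{i + 1}\t{seq[i]}\t{s:.6g}\n")


def cdf_curve(
    track: DisorderTrack | np.ndarray,
    bins: Sequence[float] = CDF_BINS,
    boundary: Sequence[float] | None = None,
) -> CDFCurve:
    """Cumulative histogram of disorder scores at the given bins.

    The curve value at bin *b* is the fraction of residues with score <= b.
    When boundary points (one per bin) are given, ``cdf_distance`` is the
    mean signed vertical offset curve - boundary; positive = ordered side
    (ordered proteins accumulate low scores early, lifting the curve).
    """
    scores = track.scores if isinstance(track, DisorderTrack) else np.asarray(track)
    if scores.size == 0:
        raise ValueError("empty track")
    bins = np.asarray(bins, dtype=float)
    if not ((bins > 0).all() and (bins < 1).all() and (np.diff(bins) > 0).all()):
        raise ValueError("bins must be strictly increasing within (0, 1)")
    values = np.array([(scores <= b).mean() for b in bins])
    dist = None
    if boundary is not None:
        boundary = np.asarray(boundary, dtype=float)
        if boundary.shape != bins.shape:
            raise ValueError("boundary must align with bins")
        dist = float((values - boundary).mean())
    return CDFCurve(bins, values, dist)


def calibrate_cdf_boundary(
    ordered_tracks: Sequence[DisorderTrack | np.ndarray],
    disordered_tracks: Sequence[DisorderTrack | np.ndarray],
    bins: Sequence[float] = CDF_BINS,
) -> np.ndarray:
    """Fit CDF boundary points as the midpoint between two reference sets.

    For each bin, the boundary is halfway between the mean CDF value of the
    ordered references and that of the disordered references.
    """
    if not ordered_tracks or not disordered_tracks:
        raise ValueError("both reference sets must be non-empty")
    mean_ord = np.mean([cdf_curve(t, bins).cdf_values for t in ordered_tracks], axis=0)
    mean_dis = np.mean(
        [cdf_curve(t, bins).cdf_values for t in disordered_tracks], axis=0
    )
    return (mean_ord + mean_dis) / 2.0


def default_cdf_boundary(bins: Sequence[float] = CDF_BINS) -> np.ndarray:
    """Packaged CDF boundary: midpoint between synthetic reference sets.

    The ordered references emit scores from Beta(2, 8) and the disordered
    references from Beta(8, 2) (the same emission model the synthetic family
    generator uses); 50 tracks of 200 residues per side, fixed internal
    seed, so the boundary is a reproducible constant.
    """
    rng = np.random.default_rng(20740)
    ordered = [rng.beta(2.0, 8.0, size=200) for _ in range(50)]
    disordered = [rng.beta(8.0, 2.0, size=200) for _ in range(50)]
    return calibrate_cdf_boundary(ordered, disordered, bins)


def chcdf_quadrant(ch_dist: float, cdf_dist: float) -> str:
    """Quadrant of CH-CDF phase space from the two signed distances.

    x = CDF distance (positive = ordered by CDF), y = CH distance (positive
    = disordered by CH): (+,+) Q1, (+,-) Q2, (-,-) Q3, (-,+) Q4.  A zero on
    either axis resolves toward the ordered call (CDF zero counts as
    positive, CH zero as negative).
    """
    cdf_ordered = cdf_dist >= 0
    ch_disordered = ch_dist > 0
    if cdf_ordered:
        return "Q1" if ch_disordered else "Q2"
    return "Q4" if ch_disordered else "Q3"


def idaa_fraction(
    track: DisorderTrack | np.ndarray | str,
    threshold: float = 0.5,
    mode: str = "score",
) -> float:
    """Percentage of disordered residues (IDAA%) in a track or sequence.

    In the default ``score`` mode: 100 x #(scores >= threshold) / length.
    In ``composition`` mode the input is a sequence and the count is of
    compositionally disorder-promoting residues instead.
    """
    if mode == "composition":
        if not isinstance(track, str):
            raise TypeError("composition mode needs a sequence string")
        if not track:
            raise ValueError("empty sequence")
        return 100.0 * sum(1 for c in track if c in DISORDER_PROMOTING) / len(track)
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    scores = track.scores if isinstance(track, DisorderTrack) else np.asarray(track)
    if scores.size == 0:
        raise ValueError("empty track")
    return 100.0 * float((scores >= threshold).mean())
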