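"""Amino-acid composition, relative compositional profiling and bootstrap CIs.

A query set of sequences is summarised by its pooled residue fractions
``C_i`` and compared with a fully-structured-protein (FSP) baseline through
the relative profile ``(C_i - C_i^FSP) / C_i^FSP``: positive values mean a
residue type is enriched relative to well-folded proteins, negative values
depleted.  Confidence intervals come from a percentile bootstrap that
resamples whole proteins with replacement, so within-protein compositional
correlation is respected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from idrscape.seqio import CANONICAL_AA

logger = logging.getLogger(__name__)

#: default reporting order: strongest order-promoting residue (W) on the
#: left through to the strongest disorder-promoting residue (E) on the right
DISORDER_AXIS = tuple("WFYIMLVNCTAGRDHQKSPE")


@dataclass
class CompositionProfile:
    """Pooled residue fractions of a protein set.

    ``fractions`` is indexed by the 20 canonical residues (alphabetical) and
    sums to 1; ``X`` residues are excluded from both numerator and
    denominator.
    """

    fractions: pd.Series
    residue_counts: pd.Series
    n_proteins: int
    n_residues: int

    def __post_init__(self) -> None:
        self.fractions = self.fractions.reindex(list(CANONICAL_AA)).astype(float)
        self.residue_counts = (
            self.residue_counts.reindex(list(CANONICAL_AA)).fillna(0).astype(int)
        )
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {self.fractions.sum()}, not 1")
        if (self.residue_counts < 0).any():
            raise ValueError("negative residue count")
        if self.n_residues != int(self.residue_counts.sum()):
            raise ValueError("n_residues inconsistent with counts")


@dataclass
class RelativeProfile:
    """Per-residue relative enrichment against a baseline, with optional CIs."""

    values: pd.Series
    ci_low: pd.Series | None = None
    ci_high: pd.Series | None = None
    axis_order: tuple[str, ...] = DISORDER_AXIS

    def to_frame(self) -> pd.DataFrame:
        order = list(self.axis_order)
        df = pd.DataFrame({"residue": order, "value": self.values.reindex(order).values})
        if self.ci_low is not None:
            df["ci_low"] = self.ci_low.reindex(order).values
            df["ci_high"] = self.ci_high.reindex(order).values
        return df


def composition(sequences: Sequence[str]) -> CompositionProfile:
    """Pooled composition of one or more sequences (``X`` excluded)."""
    counts = {aa: 0 for aa in CANONICAL_AA}
    n_res = 0
    for seq in sequences:
        for c in seq:
            if c in counts:
                counts[c] += 1
                n_res += 1
    if n_res == 0:
        raise ValueError("no canonical residues in input")
    counts_s = pd.Series(counts)
    return CompositionProfile(
        fractions=counts_s / n_res,
        residue_counts=counts_s,
        n_proteins=len(sequences),
        n_residues=n_res,
    )


def relative_profile(
    query: CompositionProfile, baseline: CompositionProfile
) -> RelativeProfile:
    """Elementwise ``(C_i - C_i^FSP) / C_i^FSP``.

    A residue present in the query but absent from the baseline has no
    defined enrichment and raises.
    """
    bad = [
        aa
        for aa in CANONICAL_AA
        if baseline.fractions[aa] == 0 and query.fractions[aa] > 0
    ]
    if bad:
        raise ValueError(f"baseline fraction is 0 for residue(s) {bad}")
    base = baseline.fractions.replace(0, np.nan)
    values = (query.fractions - baseline.fractions) / base
    values = values.fillna(0.0)  # 0/0: residue absent from both
    return RelativeProfile(values=values)


def bootstrap_profile(
    protein_set: Sequence[str],
    baseline: CompositionProfile,
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> RelativeProfile:
    """Relative profile of a protein set with percentile-bootstrap CIs.

    Each replicate resamples whole proteins with replacement (same count as
    the original set) and recomputes the relative profile; the CI bounds per
    residue are the ``(1 +/- ci_level)/2`` percentiles.  Deterministic for a
    fixed seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not (0 < ci_level < 1):
        raise ValueError("ci_level must be in (0, 1)")
    seqs = list(protein_set)
    if len(seqs) == 1:
        logger.warning("single-protein set: bootstrap resampling is degenerate")
    point = relative_profile(composition(seqs), baseline)
    rng = np.random.default_rng(seed)
    # per-protein count vectors; a replicate is a sum of resampled rows
    aa_index = {aa: k for k, aa in enumerate(CANONICAL_AA)}
    counts = np.zeros((len(seqs), len(CANONICAL_AA)))
    for i, seq in enumerate(seqs):
        for c in seq:
            k = aa_index.get(c)
            if k is not None:
                counts[i, k] += 1
    base = baseline.fractions.values
    with np.errstate(divide="ignore", invalid="ignore"):
        reps = np.empty((n_boot, len(CANONICAL_AA)))
        for b in range(n_boot):
            idx = rng.integers(0, len(seqs), size=len(seqs))
            pooled = counts[idx].sum(axis=0)
            frac = pooled / pooled.sum()
            reps[b] = np.where(base > 0, (frac - base) / base, 0.0)
    lo_q, hi_q = (1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100
    lo = np.percentile(reps, lo_q, axis=0)
    hi = np.percentile(reps, hi_q, axis=0)
    aa = list(CANONICAL_AA)
    return RelativeProfile(
        values=point.values,
        ci_low=pd.Series(lo, index=aa),
        ci_high=pd.Series(hi, index=aa),
    )


def order_disorder_axis(order: Sequence[str] | None = None) -> tuple[str, ...]:
    """Reporting order of the 20 residues from order- to disorder-promoting.

    Default places W first and E last.  A custom order must be a permutation
    of the 20 canonical residues.
    """
    if order is None:
        return DISORDER_AXIS
    order = tuple(order)
    if sorted(order) != sorted(CANONICAL_AA):
        raise ValueError("axis order must be a permutation of the 20 residues")
    return order


def load_baseline(path: str | Path | None = None) -> CompositionProfile:
    """Load a baseline composition table (columns: residue, fraction).

    With no path, loads the packaged synthetic stand-in for a
    fully-structured-protein baseline.  Fractions are renormalised to sum
    to 1; counts are not meaningful for a table-only baseline and are scaled
    to a nominal total.
    """
    if path is None:
        ref = resources.files("idrscape.data").joinpath("synthetic_fsp_baseline.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if not {"residue", "fraction"}.issubset(df.columns):
        raise ValueError("baseline table needs columns residue, fraction")
    frac = pd.Series(df["fraction"].values, index=df["residue"].values)
    frac = frac.reindex(list(CANONICAL_AA)).fillna(0.0)
    frac = frac / frac.sum()
    nominal = 100_000
    counts = (frac * nominal).round().astype(int)
    return CompositionProfile(
        fractions=frac,
        residue_counts=counts,
        n_proteins=0,
        n_residues=int(counts.sum()),
    )
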