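"""Predicted-phosphorylation fraction statistics by residue type and region.

Given an ingested site-prediction table (one row per candidate S/T/Y
residue with a boolean call), reports for each region class the percentage
of residues of each type predicted phosphorylated, plus the pooled S+T+Y
percentage.  Denominators are residue counts in the region; a type with no
residues in the region is reported missing (NaN), never zero.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from idrscape.seqio import ProteinRecord

PHOSPHO_RESIDUES = ("S", "T", "Y")
REGION_CLASSES = ("ap2", "non_ap2", "full")


def read_phospho_table(
    path: str | Path, records: Sequence[ProteinRecord]
) -> pd.DataFrame:
    """Read a site TSV (id, position 1-based, residue, predicted[, score]).

    Validates residues against the sequences and position uniqueness per
    protein; returns a frame with 0-based ``position``.
    """
    by_id = {r.id: r for r in records}
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "residue": str})
    required = {"id", "position", "residue", "predicted"}
    if not required.issubset(df.columns):
        raise ValueError(f"phospho table needs columns {sorted(required)}")
    df = df.copy()
    df["position"] = df["position"].astype(int) - 1
    df["predicted"] = df["predicted"].astype(bool)
    if df.duplicated(["id", "position"]).any():
        raise ValueError("duplicate (id, position) rows in phospho table")
    for row in df.itertuples(index=False):
        rec = by_id.get(row.id)
        if rec is None:
            raise ValueError(f"phospho site for unknown protein {row.id!r}")
        if not 0 <= row.position < len(rec.sequence):
            raise ValueError(f"{row.id}: position {row.position + 1} outside sequence")
        if row.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"{row.id}: residue {row.residue!r} not in S/T/Y")
        if rec.sequence[row.position] != row.residue:
            raise ValueError(
                f"{row.id}: residue mismatch at position {row.position + 1}"
            )
    return df


def _region_mask(rec: ProteinRecord, region_class: str) -> np.ndarray:
    n = len(rec.sequence)
    ap2 = np.zeros(n, dtype=bool)
    for r in rec.ap2_spans():
        ap2[r.start:r.end] = True
    if region_class == "full":
        return np.ones(n, dtype=bool)
    if region_class == "ap2":
        return ap2
    if region_class == "non_ap2":
        return ~ap2
    raise ValueError(f"unknown region class {region_class!r}")


def phospho_counts(
    records: Sequence[ProteinRecord],
    sites: pd.DataFrame,
    region_class: str,
) -> dict[str, tuple[int, int]]:
    """(predicted, total-residue) counts per type within a region class."""
    out = {t: [0, 0] for t in PHOSPHO_RESIDUES}
    pred = {
        (row.id, row.position)
        for row in sites.itertuples(index=False)
        if row.predicted
    }
    for rec in records:
        mask = _region_mask(rec, region_class)
        for pos, c in enumerate(rec.sequence):
            if c in out and mask[pos]:
                out[c][1] += 1
                if (rec.id, pos) in pred:
                    out[c][0] += 1
    return {t: (v[0], v[1]) for t, v in out.items()}


def phospho_fractions(
    records: Sequence[ProteinRecord],
    sites: pd.DataFrame,
    region_class: str,
) -> dict[str, float]:
    """Percent of residues predicted phosphorylated, per type and pooled.

    Returns ``{"S": ..., "T": ..., "Y": ..., "all": ...}`` with NaN where a
    type has no residues in the region.
    """
    counts = phospho_counts(records, sites, region_class)
    out: dict[str, float] = {}
    num_all = den_all = 0
    for t in PHOSPHO_RESIDUES:
        num, den = counts[t]
        out[t] = float("nan") if den == 0 else 100.0 * num / den
        num_all += num
        den_all += den
    out["all"] = float("nan") if den_all == 0 else 100.0 * num_all / den_all
    return out


def phospho_table(
    records: Sequence[ProteinRecord], sites: pd.DataFrame
) -> pd.DataFrame:
    """Summary frame with rows ap2 / non_ap2 / full and columns S, T, Y, all."""
    rows = {
        rc: phospho_fractions(records, sites, rc) for rc in REGION_CLASSES
    }
    return pd.DataFrame(rows).T.loc[list(REGION_CLASSES), ["S", "T", "Y", "all"]]
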