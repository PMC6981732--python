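"""Sequence and region-annotation I/O, and domain partitioning.

Internal coordinates are 0-based half-open everywhere; on-disk region tables
are 1-based inclusive (common genomics TSV practice).  Conversion happens at
the I/O boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: residue annotation labels; BETA/ALPHA spans nest inside an AP2 span
REGION_LABELS = ("AP2", "BETA", "ALPHA", "N_FLANK", "C_FLANK")


@dataclass(frozen=True)
class RegionAnnotation:
    """One annotated span on a protein, 0-based half-open."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) for label {self.label}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "RegionAnnotation") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class ProteinRecord:
    """One protein sequence plus its region annotations.

    The sequence is upper-case and restricted to the 20 canonical residues
    plus ``X`` (any non-canonical letter is mapped to ``X`` on input).
    """

    id: str
    sequence: str
    regions: list[RegionAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set(CANONICAL_AA + "X")
        if bad:
            raise ValueError(f"{self.id}: unexpected letters {sorted(bad)}")
        self.validate_regions()

    def validate_regions(self) -> None:
        n = len(self.sequence)
        ap2 = [r for r in self.regions if r.label == "AP2"]
        for r in self.regions:
            if r.end > n:
                raise ValueError(
                    f"{self.id}: region {r.label} [{r.start},{r.end}) exceeds length {n}"
                )
        for i, a in enumerate(ap2):
            for b in ap2[i + 1:]:
                if a.overlaps(b):
                    raise ValueError(f"{self.id}: overlapping AP2 spans")
        for r in self.regions:
            if r.label in ("BETA", "ALPHA"):
                if not any(a.start <= r.start and r.end <= a.end for a in ap2):
                    raise ValueError(
                        f"{self.id}: {r.label} [{r.start},{r.end}) not nested in an AP2 span"
                    )

    def ap2_spans(self) -> list[RegionAnnotation]:
        return sorted(
            (r for r in self.regions if r.label == "AP2"), key=lambda r: r.start
        )

    def spans(self, label: str) -> list[RegionAnnotation]:
        return sorted(
            (r for r in self.regions if r.label == label), key=lambda r: r.start
        )


@dataclass
class Partition:
    """The three sequence views used throughout the pipeline."""

    full: str
    ap2_only: str
    ap2_deleted: str


def _sanitize(seq: str, rec_id: str) -> str:
    seq = seq.upper()
    cleaned = []
    n_mapped = 0
    for c in seq:
        if c in CANONICAL_AA or c == "X":
            cleaned.append(c)
        else:
            cleaned.append("X")
            n_mapped += 1
    if n_mapped:
        logger.warning("%s: mapped %d non-canonical letter(s) to X", rec_id, n_mapped)
    return "".join(cleaned)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA into records; non-canonical letters become ``X``.

    Raises on an empty file and on duplicate ids.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(ProteinRecord(entry.id, _sanitize(str(entry.seq), entry.id)))
    if not records:
        raise ValueError(f"no FASTA entries in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    entries = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(entries, str(path), "fasta")


def read_region_table(path: str | Path) -> dict[str, list[RegionAnnotation]]:
    """Read a region TSV (columns id, label, start, end; 1-based inclusive).

    Coordinates are converted to 0-based half-open.  BETA/ALPHA rows must
    nest inside an AP2 row of the same protein.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str, "label": str})
    required = {"id", "label", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"region table needs columns {sorted(required)}")
    out: dict[str, list[RegionAnnotation]] = {}
    for row in df.itertuples(index=False):
        start1, end1 = int(row.start), int(row.end)
        if start1 > end1:
            raise ValueError(
                f"{row.id}: start {start1} > end {end1} for label {row.label}"
            )
        out.setdefault(row.id, []).append(
            RegionAnnotation(row.label, start1 - 1, end1)
        )
    # nesting check requires all of a protein's rows
    for pid, regions in out.items():
        ap2 = [r for r in regions if r.label == "AP2"]
        for r in regions:
            if r.label in ("BETA", "ALPHA") and not any(
                a.start <= r.start and r.end <= a.end for a in ap2
            ):
                raise ValueError(f"{pid}: {r.label} span outside any AP2 span")
    return out


def write_region_table(
    regions: dict[str, list[RegionAnnotation]], path: str | Path
) -> None:
    """Write regions as 1-based inclusive TSV (inverse of :func:`read_region_table`)."""
    with open(path, "w") as fh:
        fh.write("id\tlabel\tstart\tend\n")
        for pid in regions:
            for r in regions[pid]:
                fh.write(f"{pid}\t{r.label}\t{r.start + 1}\t{r.end}\n")


def attach_regions(
    records: Sequence[ProteinRecord],
    regions: dict[str, list[RegionAnnotation]],
) -> list[ProteinRecord]:
    """Attach annotations to records (validating spans against lengths)."""
    out = []
    for rec in records:
        out.append(ProteinRecord(rec.id, rec.sequence, list(regions.get(rec.id, []))))
    return out


def drop_multi_ap2(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Drop proteins with more than one AP2 span, with a warning.

    Proteins with double (or incomplete) DNA-binding domains are atypical and
    excluded by default so that the per-protein partition is unambiguous.
    """
    kept = []
    for rec in records:
        if len(rec.ap2_spans()) > 1:
            logger.warning("%s: %d AP2 spans, dropped", rec.id, len(rec.ap2_spans()))
        else:
            kept.append(rec)
    return kept


def partition(record: ProteinRecord) -> Partition:
    """Split a protein into full / AP2-only / AP2-deleted sequence views.

    ``ap2_only`` concatenates the AP2 spans in order; ``ap2_deleted`` is the
    full sequence with those spans removed.  With no AP2 annotation,
    ``ap2_only`` is empty and ``ap2_deleted`` equals the full sequence.
    """
    seq = record.sequence
    spans = record.ap2_spans()
    ap2_only = "".join(seq[r.start:r.end] for r in spans)
    keep = np.ones(len(seq), dtype=bool)
    for r in spans:
        keep[r.start:r.end] = False
    ap2_deleted = "".join(c for c, k in zip(seq, keep) if k)
    return Partition(seq, ap2_only, ap2_deleted)


@dataclass
class PositionWeightModel:
    """Per-column log-odds scores for optional domain detection.

    ``weights`` has shape (length, 20) in :data:`CANONICAL_AA` order;
    ``threshold`` is the minimum window score reported as a hit.
    """

    length: int
    weights: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.length, len(CANONICAL_AA)):
            raise ValueError(
                f"weights shape {self.weights.shape} != ({self.length}, 20)"
            )

    def score(self, window: str) -> float:
        idx = [CANONICAL_AA.find(c) for c in window]
        # X contributes the column mean (uninformative position)
        total = 0.0
        for col, i in enumerate(idx):
            total += self.weights[col].mean() if i < 0 else self.weights[col, i]
        return total


def pwm_from_sequences(
    seqs: Sequence[str],
    background: dict[str, float] | None = None,
    pseudocount: float = 0.5,
    threshold: float = 0.0,
) -> PositionWeightModel:
    """Build a log-odds PWM from equal-length example sequences."""
    if not seqs:
        raise ValueError("need at least one sequence")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must share one length")
    if background is None:
        background = {aa: 1.0 / 20 for aa in CANONICAL_AA}
    counts = np.full((length, 20), pseudocount)
    for s in seqs:
        for col, c in enumerate(s):
            i = CANONICAL_AA.find(c)
            if i >= 0:
                counts[col, i] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    bg = np.array([background[aa] for aa in CANONICAL_AA])
    weights = np.log2(probs / bg)
    return PositionWeightModel(length, weights, threshold)


def scan_domain(
    record: ProteinRecord, pwm: PositionWeightModel
) -> list[RegionAnnotation]:
    """Scan a protein with a PWM and return non-overlapping AP2 hits.

    All windows scoring >= threshold are collected; overlapping hits are
    resolved greedily to the highest score (ties to the leftmost window).
    Returns an empty list when the sequence is shorter than the model.
    """
    seq = record.sequence
    if len(seq) < pwm.length:
        return []
    hits = []
    for start in range(len(seq) - pwm.length + 1):
        s = pwm.score(seq[start:start + pwm.length])
        if s >= pwm.threshold:
            hits.append((s, start))
    hits.sort(key=lambda t: (-t[0], t[1]))
    chosen: list[tuple[float, int]] = []
    for s, start in hits:
        if all(
            start + pwm.length <= c or start >= c + pwm.length for _, c in chosen
        ):
            chosen.append((s, start))
    chosen.sort(key=lambda t: t[1])
    return [RegionAnnotation("AP2", start, start + pwm.length) for _, start in chosen]
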