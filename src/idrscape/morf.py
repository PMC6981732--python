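"""Molecular recognition feature (MoRF) detection and subgroup conservation.

MoRFs are short (~5-25 residue) interaction-prone segments inside long
disordered regions; on a per-residue disorder track they appear as downward
dips of order propensity surrounded by high-scoring disordered context.
External predictor tables are first-class and take precedence when supplied;
the dip detector is a self-contained stand-in.

Conserved MoRFs are called per subgroup by mapping member segments into a
multiple sequence alignment, single-linkage clustering them by column
overlap and keeping clusters present in enough members.  Names follow the
convention <subgroup> <side><index> where the side is N (before the AP2
domain), C (after it) or AP2 (inside it), and an exclusivity flag marks
conserved MoRFs whose consensus resembles no other subgroup's.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from idrscape.disorder import DisorderTrack
from idrscape.seqio import ProteinRecord, RegionAnnotation


@dataclass(frozen=True)
class MorfSegment:
    """One MoRF candidate segment, 0-based half-open residue coordinates."""

    protein_id: str
    start: int
    end: int
    source: str = "dip"
    mean_score: float = float("nan")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ConservedMorf:
    """A subgroup-level conserved MoRF.

    ``member_hits`` maps protein id to its (start, end) residue span;
    ``occupancy`` is the fraction of subgroup members with an overlapping
    MoRF; ``consensus`` is the majority residue per alignment column (ties
    recorded as X); ``exclusive`` is set by :func:`flag_exclusive`.
    """

    name: str
    subgroup_id: str
    side: str
    member_hits: dict[str, tuple[int, int]]
    col_span: tuple[int, int]
    occupancy: float
    consensus: str
    exclusive: bool = False


def dip_candidates(
    track: DisorderTrack,
    regions: Sequence[RegionAnnotation] = (),
    dip_threshold: float = 0.5,
    context_threshold: float = 0.5,
    min_length: int = 5,
    max_length: int = 25,
    context: int = 10,
) -> list[MorfSegment]:
    """Order-propensity dips inside disordered context, outside AP2 spans.

    Maximal runs of scores below ``dip_threshold`` qualify when their length
    is within bounds, each non-empty flanking context window of ``context``
    residues has mean score >= ``context_threshold``, and the run does not
    overlap an AP2 span (in-domain MoRFs come from external predictions
    only).  A dip touching a sequence end is judged on its single available
    context side.
    """
    scores = track.scores
    ap2 = [(r.start, r.end) for r in regions if r.label == "AP2"]
    below = scores < dip_threshold
    out: list[MorfSegment] = []
    i = 0
    n = len(scores)
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        length = j - i
        if min_length <= length <= max_length:
            left = scores[max(0, i - context):i]
            right = scores[j:j + context]
            sides = [w for w in (left, right) if w.size > 0]
            if sides and all(w.mean() >= context_threshold for w in sides):
                if not any(i < e and s < j for s, e in ap2):
                    out.append(
                        MorfSegment(
                            track.protein_id, i, j,
                            source="dip",
                            mean_score=float(scores[i:j].mean()),
                        )
                    )
        i = j
    return out


def _merge_segments(segs: list[MorfSegment]) -> list[MorfSegment]:
    """Merge overlapping/adjacent segments of one protein (union of spans)."""
    if not segs:
        return []
    segs = sorted(segs, key=lambda s: s.start)
    merged = [segs[0]]
    for s in segs[1:]:
        last = merged[-1]
        if s.start <= last.end:
            merged[-1] = MorfSegment(
                last.protein_id, last.start, max(last.end, s.end),
                source=last.source, mean_score=last.mean_score,
            )
        else:
            merged.append(s)
    return merged


def read_external_morfs(
    path: str | Path,
    records: Sequence[ProteinRecord],
    score_threshold: float = 0.725,
    min_length: int = 5,
    source: str | None = None,
) -> list[MorfSegment]:
    """Read external MoRF predictions from TSV.

    Two schemas are accepted: span rows (id, start, end; 1-based inclusive)
    or per-residue scores (id, position, score) called at
    ``score_threshold`` with runs of at least ``min_length`` positions.
    Overlapping spans of one protein are merged.
    """
    by_id = {r.id: r for r in records}
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    src = f"external:{source or Path(path).stem}"
    segs: list[MorfSegment] = []
    if {"start", "end"}.issubset(df.columns):
        for row in df.itertuples(index=False):
            if row.id not in by_id:
                raise ValueError(f"MoRF for unknown protein {row.id!r}")
            start, end = int(row.start) - 1, int(row.end)
            n = len(by_id[row.id].sequence)
            if not (0 <= start < end <= n):
                raise ValueError(
                    f"{row.id}: MoRF span [{row.start},{row.end}] outside sequence"
                )
            segs.append(MorfSegment(row.id, start, end, source=src))
    elif {"position", "score"}.issubset(df.columns):
        for pid, grp in df.groupby("id", sort=False):
            if pid not in by_id:
                raise ValueError(f"MoRF track for unknown protein {pid!r}")
            n = len(by_id[pid].sequence)
            passing = np.zeros(n, dtype=bool)
            for row in grp.itertuples(index=False):
                pos = int(row.position) - 1
                if not 0 <= pos < n:
                    raise ValueError(f"{pid}: position {row.position} outside sequence")
                passing[pos] = row.score >= score_threshold
            i = 0
            while i < n:
                if passing[i]:
                    j = i
                    while j < n and passing[j]:
                        j += 1
                    if j - i >= min_length:
                        segs.append(MorfSegment(pid, i, j, source=src))
                    i = j
                else:
                    i += 1
    else:
        raise ValueError("MoRF table needs (id,start,end) or (id,position,score)")
    out: list[MorfSegment] = []
    for pid in dict.fromkeys(s.protein_id for s in segs):
        out.extend(_merge_segments([s for s in segs if s.protein_id == pid]))
    return out


def write_morfs(segs: Sequence[MorfSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tstart\tend\tsource\n")
        for s in segs:
            fh.write(f"{s.protein_id}\t{s.start + 1}\t{s.end}\t{s.source}\n")


def residue_to_column(aligned: str) -> np.ndarray:
    """Column index of each ungapped residue of an aligned sequence."""
    return np.array([i for i, c in enumerate(aligned) if c != "-"], dtype=int)


def map_to_alignment(
    msa: Mapping[str, str], morfs: Sequence[MorfSegment]
) -> list[tuple[MorfSegment, int, int]]:
    """Convert residue spans to alignment-column spans through the gaps.

    Returns (segment, col_start, col_end) with col_end exclusive.  The
    ungapped alignment row must equal the protein's sequence length.
    """
    col_maps: dict[str, np.ndarray] = {}
    out = []
    for m in morfs:
        if m.protein_id not in msa:
            raise ValueError(f"{m.protein_id} missing from alignment")
        if m.protein_id not in col_maps:
            col_maps[m.protein_id] = residue_to_column(msa[m.protein_id])
        cols = col_maps[m.protein_id]
        if m.end > cols.size:
            raise ValueError(f"{m.protein_id}: MoRF beyond ungapped length")
        out.append((m, int(cols[m.start]), int(cols[m.end - 1]) + 1))
    return out


def _ap2_column_span(
    msa: Mapping[str, str],
    ap2_spans: Mapping[str, Sequence[tuple[int, int]]],
) -> tuple[int, int] | None:
    """Union span of AP2 residue positions in alignment columns."""
    lo, hi = None, None
    for pid, spans in ap2_spans.items():
        if pid not in msa:
            continue
        cols = residue_to_column(msa[pid])
        for s, e in spans:
            if e > cols.size or e <= s:
                continue
            c0, c1 = int(cols[s]), int(cols[e - 1]) + 1
            lo = c0 if lo is None else min(lo, c0)
            hi = c1 if hi is None else max(hi, c1)
    return None if lo is None else (lo, hi)


def call_conserved(
    subgroup_id: str,
    member_ids: Sequence[str],
    msa: Mapping[str, str],
    morfs: Sequence[MorfSegment],
    ap2_spans: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    min_occupancy: float = 0.75,
    min_overlap_cols: int = 5,
) -> list[ConservedMorf]:
    """Call conserved MoRFs for one subgroup.

    Aligned member MoRFs are clustered by single linkage on column overlap
    (>= ``min_overlap_cols`` shared columns joins two segments); clusters
    with occupancy >= ``min_occupancy`` become :class:`ConservedMorf`.
    The result is invariant to member order: clustering operates on column
    coordinates and names are assigned by column position.
    """
    if len(member_ids) < 2:
        raise ValueError("subgroup needs at least 2 members")
    members = set(member_ids)
    aligned = [
        (m, c0, c1)
        for m, c0, c1 in map_to_alignment(msa, [x for x in morfs if x.protein_id in members])
    ]
    # single linkage by column overlap
    parent = list(range(len(aligned)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(aligned)):
        for j in range(i + 1, len(aligned)):
            _, a0, a1 = aligned[i]
            _, b0, b1 = aligned[j]
            if min(a1, b1) - max(a0, b0) >= min_overlap_cols:
                parent[find(i)] = find(j)

    clusters: dict[int, list[tuple[MorfSegment, int, int]]] = {}
    for i, item in enumerate(aligned):
        clusters.setdefault(find(i), []).append(item)

    ap2_cols = (
        _ap2_column_span(msa, ap2_spans) if ap2_spans else None
    )
    kept = []
    for items in clusters.values():
        hit_ids = {m.protein_id for m, _, _ in items}
        occupancy = len(hit_ids) / len(member_ids)
        if occupancy < min_occupancy:
            continue
        c0 = min(a for _, a, _ in items)
        c1 = max(b for _, _, b in items)
        side = "N"
        if ap2_cols is not None:
            if c0 < ap2_cols[1] and ap2_cols[0] < c1:
                side = "AP2"
            elif c0 >= ap2_cols[1]:
                side = "C"
        member_hits: dict[str, tuple[int, int]] = {}
        for m, _, _ in sorted(items, key=lambda t: (t[0].protein_id, t[1])):
            if m.protein_id in member_hits:
                s0, e0 = member_hits[m.protein_id]
                member_hits[m.protein_id] = (min(s0, m.start), max(e0, m.end))
            else:
                member_hits[m.protein_id] = (m.start, m.end)
        consensus = _cluster_consensus(msa, items, c0, c1)
        kept.append((side, c0, c1, occupancy, member_hits, consensus))

    out: list[ConservedMorf] = []
    for side in ("N", "AP2", "C"):
        side_clusters = sorted(
            (k for k in kept if k[0] == side), key=lambda k: (k[1], k[2])
        )
        for idx, (s, c0, c1, occ, hits, cons) in enumerate(side_clusters, start=1):
            tag = f"{s}{idx}" if s != "AP2" else f"AP2-{idx}"
            out.append(
                ConservedMorf(
                    name=f"{subgroup_id} {tag}",
                    subgroup_id=subgroup_id,
                    side=s,
                    member_hits=hits,
                    col_span=(c0, c1),
                    occupancy=occ,
                    consensus=cons,
                )
            )
    return out


def _cluster_consensus(
    msa: Mapping[str, str],
    items: Sequence[tuple[MorfSegment, int, int]],
    c0: int,
    c1: int,
) -> str:
    """Majority residue per column over member hits; ties and gaps give X.

    Columns covered by fewer than half of the hits are trimmed from the
    consensus so stragglers do not pad it.
    """
    counts_per_col: list[dict[str, int]] = [dict() for _ in range(c1 - c0)]
    coverage = np.zeros(c1 - c0, dtype=int)
    for m, a0, a1 in items:
        row = msa[m.protein_id]
        for col in range(max(a0, c0), min(a1, c1)):
            ch = row[col]
            if ch != "-":
                counts_per_col[col - c0][ch] = counts_per_col[col - c0].get(ch, 0) + 1
                coverage[col - c0] += 1
    min_cov = max(1, (len(items) + 1) // 2)
    chars = []
    for k, counts in enumerate(counts_per_col):
        if coverage[k] < min_cov:
            chars.append(None)
            continue
        top = max(counts.values())
        winners = sorted(c for c, n in counts.items() if n == top)
        chars.append(winners[0] if len(winners) == 1 else "X")
    # trim uncovered edges, keep interior low-coverage columns as X
    first = next((i for i, c in enumerate(chars) if c is not None), None)
    if first is None:
        return ""
    last = max(i for i, c in enumerate(chars) if c is not None)
    return "".join(c if c is not None else "X" for c in chars[first:last + 1])


def _best_offset_identity(a: str, b: str) -> float:
    """Best ungapped-sliding identity between two motifs, over the shorter."""
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = 0
    for off in range(len(long_) - len(short) + 1):
        matches = sum(
            1 for x, y in zip(short, long_[off:off + len(short)])
            if x == y and x != "X"
        )
        best = max(best, matches)
    return best / len(short)


def flag_exclusive(
    conserved: Sequence[ConservedMorf], identity_threshold: float = 0.6
) -> list[ConservedMorf]:
    """Set the exclusivity flag across subgroups.

    A conserved MoRF is exclusive iff no other subgroup has a conserved MoRF
    whose consensus aligns to it with identity >= the threshold (best
    ungapped offset, over the shorter consensus).  With no other subgroups
    present the condition is vacuously true.
    """
    for cm in conserved:
        cm.exclusive = not any(
            other.subgroup_id != cm.subgroup_id
            and _best_offset_identity(cm.consensus, other.consensus)
            >= identity_threshold
            for other in conserved
        )
    return list(conserved)


def ap2_morf_layout(
    conserved: Sequence[ConservedMorf],
    records: Sequence[ProteinRecord],
    subgroups: Mapping[str, str],
) -> pd.DataFrame:
    """Per-subgroup occupancy of the AP2 sub-regions by in-domain MoRFs.

    For each subgroup and sub-region (beta1, beta2, beta3, alpha) reports
    the fraction of members whose AP2-side MoRF hits overlap it.  Requires
    BETA/ALPHA annotations on every member carrying an AP2 MoRF.
    """
    by_id = {r.id: r for r in records}
    missing = [
        pid
        for cm in conserved if cm.side == "AP2"
        for pid in cm.member_hits
        if pid in by_id and not (by_id[pid].spans("BETA") and by_id[pid].spans("ALPHA"))
    ]
    if missing:
        raise ValueError(f"missing BETA/ALPHA annotations for {sorted(set(missing))}")
    sub_members: dict[str, list[str]] = {}
    for pid, sub in subgroups.items():
        sub_members.setdefault(sub, []).append(pid)
    rows = []
    for sub, members in sorted(sub_members.items()):
        counts = {"beta1": 0, "beta2": 0, "beta3": 0, "alpha": 0}
        for pid in members:
            rec = by_id.get(pid)
            if rec is None:
                continue
            hits = [
                cm.member_hits[pid]
                for cm in conserved
                if cm.side == "AP2" and cm.subgroup_id == sub and pid in cm.member_hits
            ]
            if not hits:
                continue
            betas = rec.spans("BETA")
            alphas = rec.spans("ALPHA")
            subregions = {
                f"beta{i + 1}": (b.start, b.end) for i, b in enumerate(betas[:3])
            }
            if alphas:
                subregions["alpha"] = (alphas[0].start, alphas[0].end)
            for key, (s, e) in subregions.items():
                if any(h0 < e and s < h1 for h0, h1 in hits):
                    counts[key] += 1
        n = len(members)
        rows.append(
            {"subgroup": sub, **{k: counts[k] / n for k in counts}}
        )
    return pd.DataFrame(rows).set_index("subgroup")


def write_conserved(conserved: Sequence[ConservedMorf], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsubgroup\tside\toccupancy\tconsensus\texclusive\n")
        for cm in conserved:
            fh.write(
                f"{cm.name}\t{cm.subgroup_id}\t{cm.side}\t{cm.occupancy:.4g}\t"
                f"{cm.consensus}\t{int(cm.exclusive)}\n"
            )
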