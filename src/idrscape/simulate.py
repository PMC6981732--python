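"""Synthetic protein families with planted ground truth.

The generator emulates the architecture of AP2/ERF-like transcription
factors: a short, well-folded DNA-binding domain (AP2, default 58 residues,
three beta strands plus one alpha helix) built from an order-promoting
composition rich in W/A/R and conserved within a subgroup, flanked on both
sides by intrinsically disordered regions drawn from a disorder-promoting
composition (E-enriched, K-depleted).  Short MoRF-like motifs are planted at
homologous flank positions shared within a subgroup, some exclusive to one
subgroup and some shared between subgroups; a homopolymeric low-complexity
run is planted in the C-terminal flank.  Per-residue disorder scores are
emitted from state-dependent Beta distributions (ordered, disordered and
MoRF-dip states), and a toy motif-based predictor emits a phospho-site
table.  Everything is deterministic given the seed, and the planted truth is
machine-readable so recall/precision of every pipeline stage can be scored.

The default compositions are deliberate caricatures (effect sizes roughly
twice the trends seen in real disordered-protein profiling) so that
classification properties are deterministic at test sample sizes; the
methods note discusses what this does and does not demonstrate about real
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from idrscape.seqio import (
    ProteinRecord,
    RegionAnnotation,
    write_fasta,
    write_region_table,
)
from idrscape.disorder import DisorderTrack, internal_track, write_track
from idrscape.tree import TreeNode, to_newick, tree_splits, parse_newick
from idrscape.morf import MorfSegment, write_morfs
from idrscape.tree import write_subgroups

#: order-promoting composition for the AP2 domain consensus (W/A/R rich,
#: aromatic frame, low E/P/S) — a caricature of a folded DNA-binding domain
ORDERED_COMPOSITION = {
    "W": 0.06, "F": 0.07, "Y": 0.05, "I": 0.09, "M": 0.03, "L": 0.10,
    "V": 0.09, "N": 0.03, "C": 0.02, "T": 0.05, "A": 0.11, "G": 0.06,
    "R": 0.06, "D": 0.04, "H": 0.02, "Q": 0.03, "K": 0.01, "S": 0.04,
    "E": 0.03, "P": 0.01,
}

#: disorder-promoting flank composition: E-enriched, K-depleted, few
#: order-promoting aromatics/aliphatics
DISORDERED_COMPOSITION = {
    "W": 0.002, "F": 0.008, "Y": 0.01, "I": 0.01, "M": 0.01, "L": 0.03,
    "V": 0.02, "N": 0.06, "C": 0.002, "T": 0.06, "A": 0.08, "G": 0.10,
    "R": 0.04, "D": 0.08, "H": 0.028, "Q": 0.08, "K": 0.02, "S": 0.12,
    "E": 0.12, "P": 0.12,
}

#: default planted MoRF motif pool (8-15 residues).  The first four are
#: subgroup-exclusive (EAR-like, acidic, basic, MCGGAI-like patterns); the
#: last two are shared between subgroup pairs (LWSY-like, EDLL-like).
EXCLUSIVE_MOTIFS = (
    "LDLNLNLELRLG",   # EAR-like repression motif caricature
    "DEDEYDSDDEMG",   # acidic motif
    "KRGRKRSSKNKR",   # basic motif
    "MCGGAILNDFFP",   # MCGGAI-like N-end motif
)
SHARED_MOTIFS = (
    "TDDMLWSYLNAG",   # LWSY-like C-terminal motif
    "LAEDLLSSFGDE",   # EDLL-like activation motif
)

#: AP2 sub-region layout within the 58-residue domain (0-based half-open,
#: relative to the domain start): three beta strands then the alpha helix
AP2_SUBREGIONS = (
    ("BETA", 4, 14),
    ("BETA", 17, 25),
    ("BETA", 28, 36),
    ("ALPHA", 40, 56),
)


@dataclass
class FamilySpec:
    """Parameters of one synthetic family; the seed is mandatory."""

    seed: int
    n_subgroups: int = 4
    members_per_subgroup: int = 6
    ap2_length: int = 58
    ap2_mutation_rate: float = 0.08
    subgroup_divergence: float = 0.25     # per-edge AP2 mutation rate between subgroups
    n_flank_range: tuple[int, int] = (40, 90)
    c_flank_range: tuple[int, int] = (60, 120)
    flank_composition: dict[str, float] = field(
        default_factory=lambda: dict(DISORDERED_COMPOSITION)
    )
    ap2_composition: dict[str, float] = field(
        default_factory=lambda: dict(ORDERED_COMPOSITION)
    )
    # state-dependent disorder-score emissions: Beta(a, b)
    ordered_beta: tuple[float, float] = (2.0, 8.0)
    disordered_beta: tuple[float, float] = (8.0, 2.0)
    dip_beta: tuple[float, float] = (2.0, 8.0)
    lc_run_length: int = 12               # planted poly-S low-complexity run
    lc_residue: str = "S"
    # toy phospho predictor emission rates
    p_sp_site: float = 0.8                # S/T followed by P
    p_st_base: float = 0.05
    p_y_ap2: float = 0.3
    p_y_base: float = 0.05
    emit_internal_tracks: bool = False    # derive tracks from sequence instead

    def __post_init__(self) -> None:
        for comp in (self.flank_composition, self.ap2_composition):
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"composition sums to {total}, not 1")
        if self.ap2_length <= 0 or self.n_subgroups < 1:
            raise ValueError("lengths and counts must be positive")


@dataclass
class PlantedMorf:
    """Ground truth for one planted motif occurrence."""

    protein_id: str
    subgroup: str
    motif: str
    side: str          # N or C
    start: int
    end: int
    exclusive: bool


@dataclass
class GroundTruth:
    """Machine-readable planted truth for one generated family."""

    ap2_spans: dict[str, tuple[int, int]]
    subregions: dict[str, list[tuple[str, int, int]]]
    morfs: list[PlantedMorf]
    lc_runs: dict[str, tuple[int, int]]
    subgroups: dict[str, str]
    tree_newick: str

    def to_json(self) -> str:
        payload = {
            "ap2_spans": {k: list(v) for k, v in self.ap2_spans.items()},
            "subregions": {
                k: [[lab, s, e] for lab, s, e in v] for k, v in self.subregions.items()
            },
            "morfs": [asdict(m) for m in self.morfs],
            "lc_runs": {k: list(v) for k, v in self.lc_runs.items()},
            "subgroups": self.subgroups,
            "tree_newick": self.tree_newick,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            ap2_spans={k: tuple(v) for k, v in d["ap2_spans"].items()},
            subregions={
                k: [(lab, s, e) for lab, s, e in v] for k, v in d["subregions"].items()
            },
            morfs=[PlantedMorf(**m) for m in d["morfs"]],
            lc_runs={k: tuple(v) for k, v in d["lc_runs"].items()},
            subgroups=d["subgroups"],
            tree_newick=d["tree_newick"],
        )


@dataclass
class SyntheticFamily:
    """One generated family: records, emitted tables and planted truth."""

    records: list[ProteinRecord]
    tracks: dict[str, DisorderTrack]
    morf_table: list[MorfSegment]
    phospho_rows: list[tuple[str, int, str, bool]]
    subgroups: dict[str, str]
    subgroup_msas: dict[str, dict[str, str]]
    ap2_msa: dict[str, str]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit all pipeline input files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "sequences.fasta",
            "regions": outdir / "regions.tsv",
            "tracks": outdir / "tracks.tsv",
            "morfs": outdir / "morfs.tsv",
            "phospho": outdir / "phospho.tsv",
            "subgroups": outdir / "subgroups.tsv",
            "ap2_msa": outdir / "ap2_alignment.fasta",
            "tree": outdir / "true_tree.nwk",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.records, paths["fasta"])
        write_region_table({r.id: r.regions for r in self.records}, paths["regions"])
        write_track(self.tracks, self.records, paths["tracks"])
        write_morfs(self.morf_table, paths["morfs"])
        with open(paths["phospho"], "w") as fh:
            fh.write("id\tposition\tresidue\tpredicted\n")
            for pid, pos, res, pred in self.phospho_rows:
                fh.write(f"{pid}\t{pos + 1}\t{res}\t{int(pred)}\n")
        write_subgroups(self.subgroups, paths["subgroups"])
        with open(paths["ap2_msa"], "w") as fh:
            for pid, row in self.ap2_msa.items():
                fh.write(f">{pid}\n{row}\n")
        for sub, msa in self.subgroup_msas.items():
            p = outdir / f"msa_{sub}.fasta"
            with open(p, "w") as fh:
                for pid, row in msa.items():
                    fh.write(f">{pid}\n{row}\n")
            paths[f"msa_{sub}"] = p
        paths["tree"].write_text(self.truth.tree_newick + "\n")
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def _draw_sequence(rng: np.random.Generator, length: int, comp: Mapping[str, float]) -> str:
    aas = list(comp)
    probs = np.array([comp[a] for a in aas])
    probs = probs / probs.sum()
    return "".join(rng.choice(aas, size=length, p=probs))


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            comp: Mapping[str, float], protected: set[int] = frozenset()) -> str:
    aas = list(comp)
    probs = np.array([comp[a] for a in aas])
    probs = probs / probs.sum()
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            out[i] = rng.choice(aas, p=probs)
    return "".join(out)


def _random_subgroup_tree(rng: np.random.Generator, labels: Sequence[str]) -> TreeNode:
    """Random binary topology over subgroup labels (branch lengths 1)."""
    nodes = [TreeNode(name=l, branch_length=1.0) for l in labels]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(children=[nodes[i], nodes[j]], branch_length=1.0)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return TreeNode(children=nodes) if len(nodes) > 1 else nodes[0]


def generate_family(spec: FamilySpec) -> SyntheticFamily:
    """Generate one synthetic family; byte-deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    sub_labels = [f"G{i + 1}" for i in range(spec.n_subgroups)]

    # subgroup AP2 consensuses evolve along a random binary tree
    sub_tree = _random_subgroup_tree(rng, sub_labels)
    root_ap2 = _draw_sequence(rng, spec.ap2_length, spec.ap2_composition)
    consensus: dict[str, str] = {}

    def evolve(node: TreeNode, seq: str) -> None:
        for child in node.children:
            child_seq = _mutate(rng, seq, spec.subgroup_divergence, spec.ap2_composition)
            if child.is_leaf:
                consensus[child.name] = child_seq
            else:
                evolve(child, child_seq)

    if sub_tree.is_leaf:
        consensus[sub_tree.name] = root_ap2
    else:
        evolve(sub_tree, root_ap2)

    # motif assignment: each subgroup gets one exclusive N-side motif and one
    # C-side motif shared between subgroup pairs
    n_motifs = {
        s: EXCLUSIVE_MOTIFS[i % len(EXCLUSIVE_MOTIFS)] for i, s in enumerate(sub_labels)
    }
    c_motifs = {
        s: SHARED_MOTIFS[(i // 2) % len(SHARED_MOTIFS)] for i, s in enumerate(sub_labels)
    }
    c_shared = {
        s: sum(1 for t in sub_labels if c_motifs[t] == c_motifs[s]) > 1
        for s in sub_labels
    }
    n_shared = {
        s: sum(1 for t in sub_labels if n_motifs[t] == n_motifs[s]) > 1
        for s in sub_labels
    }

    records: list[ProteinRecord] = []
    tracks: dict[str, DisorderTrack] = {}
    morf_table: list[MorfSegment] = []
    phospho_rows: list[tuple[str, int, str, bool]] = []
    subgroups: dict[str, str] = {}
    subgroup_msas: dict[str, dict[str, str]] = {}
    ap2_msa: dict[str, str] = {}
    truth_morfs: list[PlantedMorf] = []
    ap2_spans: dict[str, tuple[int, int]] = {}
    subregions: dict[str, list[tuple[str, int, int]]] = {}
    lc_runs: dict[str, tuple[int, int]] = {}

    member_tree_children = []
    for si, sub in enumerate(sub_labels):
        n_len = int(rng.integers(spec.n_flank_range[0], spec.n_flank_range[1] + 1))
        c_len = int(rng.integers(spec.c_flank_range[0], spec.c_flank_range[1] + 1))
        n_motif, c_motif = n_motifs[sub], c_motifs[sub]
        # a MoRF is a segment embedded in disordered context, so planted
        # motifs keep at least a context window (10 aa) of flank around them
        margin = 10
        if (
            len(n_motif) + margin + 2 > n_len
            or len(c_motif) + spec.lc_run_length + margin + 4 > c_len
        ):
            raise ValueError("motif longer than flank allows")
        # homologous within-subgroup motif offsets
        n_off = int(rng.integers(margin, n_len - len(n_motif) - 1))
        c_lo = int(
            rng.integers(margin, c_len - len(c_motif) - spec.lc_run_length - 3)
        )
        lc_off = c_lo + len(c_motif) + 2
        # subgroup master flanks (members get substitutions of the master)
        n_master = _draw_sequence(rng, n_len, spec.flank_composition)
        c_master = _draw_sequence(rng, c_len, spec.flank_composition)
        n_master = n_master[:n_off] + n_motif + n_master[n_off + len(n_motif):]
        c_master = (
            c_master[:c_lo] + c_motif
            + c_master[c_lo + len(c_motif):lc_off]
            + spec.lc_residue * spec.lc_run_length
            + c_master[lc_off + spec.lc_run_length:]
        )
        protected_n = set(range(n_off, n_off + len(n_motif)))
        protected_c = set(range(c_lo, c_lo + len(c_motif))) | set(
            range(lc_off, lc_off + spec.lc_run_length)
        )

        member_ids = []
        sub_leaf_nodes = []
        for mi in range(spec.members_per_subgroup):
            pid = f"{sub}_m{mi + 1}"
            member_ids.append(pid)
            subgroups[pid] = sub
            ap2 = _mutate(rng, consensus[sub], spec.ap2_mutation_rate,
                          spec.ap2_composition)
            n_fl = _mutate(rng, n_master, spec.ap2_mutation_rate,
                           spec.flank_composition, protected_n)
            c_fl = _mutate(rng, c_master, spec.ap2_mutation_rate,
                           spec.flank_composition, protected_c)
            seq = n_fl + ap2 + c_fl
            a0, a1 = n_len, n_len + spec.ap2_length
            regions = [
                RegionAnnotation("N_FLANK", 0, n_len),
                RegionAnnotation("AP2", a0, a1),
                RegionAnnotation("C_FLANK", a1, len(seq)),
            ]
            subregions[pid] = []
            for lab, s, e in AP2_SUBREGIONS:
                if e <= spec.ap2_length:
                    regions.append(RegionAnnotation(lab, a0 + s, a0 + e))
                    subregions[pid].append((lab, a0 + s, a0 + e))
            records.append(ProteinRecord(pid, seq, regions))
            ap2_spans[pid] = (a0, a1)
            ap2_msa[pid] = ap2
            lc_runs[pid] = (a1 + lc_off, a1 + lc_off + spec.lc_run_length)

            # planted MoRF truth (N side then C side, in sequence coordinates)
            n_span = (n_off, n_off + len(n_motif))
            c_span = (a1 + c_lo, a1 + c_lo + len(c_motif))
            truth_morfs.append(
                PlantedMorf(pid, sub, n_motif, "N", *n_span, not n_shared[sub])
            )
            truth_morfs.append(
                PlantedMorf(pid, sub, c_motif, "C", *c_span, not c_shared[sub])
            )
            morf_table.append(MorfSegment(pid, *n_span, source="external:planted"))
            morf_table.append(MorfSegment(pid, *c_span, source="external:planted"))

            # emitted disorder track: ordered AP2, disordered flanks, dips at MoRFs
            if spec.emit_internal_tracks:
                tr = internal_track(seq)
                tracks[pid] = DisorderTrack(pid, tr.scores, source="internal")
            else:
                scores = np.empty(len(seq))
                scores[:a0] = rng.beta(*spec.disordered_beta, size=a0)
                scores[a0:a1] = rng.beta(*spec.ordered_beta, size=a1 - a0)
                scores[a1:] = rng.beta(*spec.disordered_beta, size=len(seq) - a1)
                for s, e in (n_span, c_span):
                    scores[s:e] = rng.beta(*spec.dip_beta, size=e - s)
                tracks[pid] = DisorderTrack(pid, scores, source="internal")

            # toy phospho predictor
            for pos, res in enumerate(seq):
                if res in "ST":
                    rate = (
                        spec.p_sp_site
                        if pos + 1 < len(seq) and seq[pos + 1] == "P"
                        else spec.p_st_base
                    )
                    phospho_rows.append((pid, pos, res, bool(rng.random() < rate)))
                elif res == "Y":
                    rate = spec.p_y_ap2 if a0 <= pos < a1 else spec.p_y_base
                    phospho_rows.append((pid, pos, res, bool(rng.random() < rate)))
            sub_leaf_nodes.append(TreeNode(name=pid, branch_length=0.1))

        # within a subgroup all members share flank lengths, so the true
        # alignment is the raw sequences (substitution-only divergence)
        subgroup_msas[sub] = {
            pid: rec.sequence for pid, rec in
            ((r.id, r) for r in records if r.id in member_ids)
        }
        member_tree_children.append((sub, sub_leaf_nodes))

    # member-level generating tree: subgroup tree with member polytomies
    by_sub = dict(member_tree_children)

    def expand(node: TreeNode) -> TreeNode:
        if node.is_leaf:
            return TreeNode(
                branch_length=node.branch_length, children=by_sub[node.name]
            )
        return TreeNode(
            branch_length=node.branch_length,
            children=[expand(c) for c in node.children],
        )

    member_tree = expand(sub_tree) if not sub_tree.is_leaf else TreeNode(
        children=by_sub[sub_tree.name]
    )
    truth = GroundTruth(
        ap2_spans=ap2_spans,
        subregions=subregions,
        morfs=truth_morfs,
        lc_runs=lc_runs,
        subgroups=subgroups,
        tree_newick=to_newick(member_tree),
    )
    return SyntheticFamily(
        records=records,
        tracks=tracks,
        morf_table=morf_table,
        phospho_rows=phospho_rows,
        subgroups=subgroups,
        subgroup_msas=subgroup_msas,
        ap2_msa=ap2_msa,
        truth=truth,
    )


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def match_segments(
    predicted: Sequence[tuple[str, int, int]],
    truth: Sequence[tuple[str, int, int]],
    min_overlap: float = 0.5,
) -> tuple[float, float]:
    """(recall, precision) with >= ``min_overlap`` reciprocal overlap matching.

    Segments are (protein_id, start, end).  Precision is NaN when nothing
    was predicted; recall is NaN when there is no truth.
    """
    def hit(seg, pool):
        return any(
            seg[0] == t[0]
            and _reciprocal_overlap((seg[1], seg[2]), (t[1], t[2])) >= min_overlap
            for t in pool
        )

    recall = (
        float("nan") if not truth
        else sum(hit(t, predicted) for t in truth) / len(truth)
    )
    precision = (
        float("nan") if not predicted
        else sum(hit(p, truth) for p in predicted) / len(predicted)
    )
    return recall, precision


def eval_conserved(
    calls: Sequence, truth: GroundTruth, min_overlap: float = 0.5
) -> dict[str, float]:
    """Score conserved-MoRF calls against the planted subgroup motifs.

    Planted units are (subgroup, side) motif families; a call matches one
    when it is in the same subgroup on the same side and its member hits
    reciprocally overlap the planted spans (>= ``min_overlap``) for at least
    half of the members carrying the plant.  Also reports the fraction of
    matched calls whose exclusivity flag agrees with the plant.
    """
    planted: dict[tuple[str, str], dict[str, tuple[int, int]]] = {}
    planted_excl: dict[tuple[str, str], bool] = {}
    for m in truth.morfs:
        key = (m.subgroup, m.side)
        planted.setdefault(key, {})[m.protein_id] = (m.start, m.end)
        planted_excl[key] = m.exclusive

    def matches(call, key) -> bool:
        if call.subgroup_id != key[0] or call.side != key[1]:
            return False
        spans = planted[key]
        shared = set(call.member_hits) & set(spans)
        if not shared:
            return False
        good = sum(
            _reciprocal_overlap(call.member_hits[pid], spans[pid]) >= min_overlap
            for pid in shared
        )
        return good >= max(1, len(spans) // 2)

    matched_keys = set()
    matched_calls = 0
    excl_ok = excl_n = 0
    for call in calls:
        hit = next((k for k in planted if matches(call, k)), None)
        if hit is not None:
            matched_keys.add(hit)
            matched_calls += 1
            excl_n += 1
            excl_ok += int(call.exclusive == planted_excl[hit])
    recall = len(matched_keys) / len(planted) if planted else float("nan")
    precision = matched_calls / len(calls) if calls else float("nan")
    return {
        "conserved_recall": recall,
        "conserved_precision": precision,
        "exclusivity_agreement": excl_ok / excl_n if excl_n else float("nan"),
    }


def truth_eval(
    truth: GroundTruth,
    morf_segments: Sequence[tuple[str, int, int]] | None = None,
    lc_segments: Sequence[tuple[str, int, int]] | None = None,
    quadrants: Mapping[str, str] | None = None,
    expected_quadrants: Mapping[str, str] | None = None,
    tree: TreeNode | None = None,
) -> dict[str, float]:
    """Score pipeline output against the planted truth.

    MoRF and low-complexity segments are matched by >= 50% reciprocal
    overlap; quadrants by exact label agreement against the supplied
    expectation; trees by Robinson-Foulds distance to the generating tree.
    Metrics for outputs not supplied are omitted.
    """
    out: dict[str, float] = {}
    if morf_segments is not None:
        t = [(m.protein_id, m.start, m.end) for m in truth.morfs]
        r, p = match_segments(morf_segments, t)
        out["morf_recall"], out["morf_precision"] = r, p
    if lc_segments is not None:
        t = [(pid, s, e) for pid, (s, e) in truth.lc_runs.items()]
        r, p = match_segments(lc_segments, t)
        out["lc_recall"], out["lc_precision"] = r, p
    if quadrants is not None and expected_quadrants is not None:
        keys = set(quadrants) & set(expected_quadrants)
        if not keys:
            raise ValueError("no shared protein ids between quadrant maps")
        out["quadrant_accuracy"] = sum(
            quadrants[k] == expected_quadrants[k] for k in keys
        ) / len(keys)
    if tree is not None:
        true_tree = parse_newick(truth.tree_newick)
        shared = tree_splits(tree) ^ tree_splits(true_tree)
        out["tree_rf_distance"] = float(len(shared))
        true_splits = tree_splits(true_tree)
        if true_splits:
            out["tree_split_recall"] = len(
                true_splits & tree_splits(tree)
            ) / len(true_splits)
    return out
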