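"""Tree cutting by differential conservation: SDPs, cut decisions, pipeline.

A merge tree built over identity clusters is traversed from the leaves to
the root. At each internal node the two children's sub-alignments (already
in shared coordinates, since merged alignments follow the profile-profile
alignment path) are compared column by column: a *specificity-determining
position* (SDP) is a column strongly conserved within each child but with
different residues between them. Where two children show enough SDPs the
tree is cut and the children seed separate functional families (FunFams);
small, low-diversity children must show twice the usual SDP evidence.

The full driver partitions functional units by multi-domain architecture
(MDA), classifies each partition independently, then pools the per-MDA
families for one final merge-and-cut iteration so that families spanning
several architectures can coalesce. Identity clusters without any
experimental annotation are held out of classification and afterwards
scanned against the final family profiles for an advisory assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import AA_INDEX, GAP_CHARS, SIMILARITY, encode
from .clustering import (
    MergeNode,
    MergeTree,
    ProfileModel,
    SeqCluster,
    align_profiles,
    build_merge_tree,
    build_profile,
    greedy_cluster,
    S90_THRESHOLD,
)
from .evaluation import dops, member_seq_id
from .sequence_domains import (
    C_LOBE_FAMILY,
    DEFAULT_LINKER_MAX,
    DomainHit,
    FunctionalUnit,
    N_LOBE_FAMILY,
    assign_mda,
    build_functional_units,
    resolve_hits,
)

logger = logging.getLogger("kinfams")

#: Minimum within-group conservation for a column to qualify as an SDP.
TAU_CONS = 0.8
#: Minimum differential-conservation (GroupSim) score for an SDP.
TAU_GS = 0.4
#: Columns with more than this gap fraction in either group are never SDPs.
GAP_MAX = 0.5
#: Children with at least this many members are exempt from the
#: diversity (DOPs) gate in cut decisions; for smaller low-diversity
#: groups the differential-conservation signal is trusted only when the
#: SDP evidence is twice the usual requirement.
SMALL_FAMILY_EXEMPT = 6


def similarity(x: str, y: str) -> float:
    """Residue similarity kernel in [0, 1], sim(x, x) = 1.

    ``max(0, (B62(x,y) + 4) / (max(B62(x,x), B62(y,y)) + 4))``. Unknown
    letters ('X') are treated as gaps and excluded from pair statistics."""
    ix, iy = AA_INDEX.get(x, -1), AA_INDEX.get(y, -1)
    if ix < 0 or iy < 0:
        raise ValueError(f"similarity: unknown residue pair {x!r},{y!r}")
    return float(SIMILARITY[ix, iy])


@dataclass(frozen=True)
class ColumnScores:
    """Differential-conservation scores of one joint-alignment column."""

    position: int  # 1-based column index in the joint alignment
    cons_a: float
    cons_b: float
    between: float
    groupsim: float
    gapfrac_a: float
    gapfrac_b: float
    is_sdp: bool


@dataclass
class FunFam:
    """A final functional family."""

    id: str
    members: list[str]
    alignment: list[str]
    profile: ProfileModel
    sdps_vs_sibling: list[ColumnScores] = field(default_factory=list)
    mda_set: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CutParams:
    """Thresholds governing SDP detection and cut decisions."""

    tau_cons: float = TAU_CONS
    tau_gs: float = TAU_GS
    gap_max: float = GAP_MAX
    n_min: int = 3
    k_min: int = 2
    dops_min: float = 70.0
    small_family_exempt: int = SMALL_FAMILY_EXEMPT


@dataclass(frozen=True)
class ClassifyParams:
    """End-to-end pipeline parameters.

    ``pseudocount_weight`` is deliberately small: pseudocounts flatten
    profiles in proportion to 1/cluster size, so a large weight makes
    profile-profile scores depend on cluster *size* (sharp large-cluster
    pairs outscore flat singleton pairs regardless of family), distorting
    the agglomerative merge order. A small weight keeps every profile
    entry positive while letting merge order follow sequence content.
    """

    s90_threshold: float = S90_THRESHOLD
    pseudocount_weight: float = 0.01
    linker_max: int = DEFAULT_LINKER_MAX
    n_lobe_family: str = N_LOBE_FAMILY
    c_lobe_family: str = C_LOBE_FAMILY
    cut: CutParams = CutParams()


# ---------------------------------------------------------------------------
# column scoring


def _column_stats(col: np.ndarray) -> tuple[np.ndarray, int]:
    res = col[col >= 0]
    counts = np.bincount(res, minlength=20)[:20].astype(float)
    return counts, len(res)


def group_column_scores(
    col_a: Sequence[str],
    col_b: Sequence[str],
    position: int = 1,
    tau_cons: float = TAU_CONS,
    tau_gs: float = TAU_GS,
    gap_max: float = GAP_MAX,
) -> ColumnScores | None:
    """Score one column of the joint alignment of two groups.

    Within-group conservation is the mean similarity over unordered non-gap
    pairs; ``between`` the mean over cross-group pairs; the GroupSim-style
    differential score is ``min(cons_a, cons_b) - between``. Returns ``None``
    (column skipped) when either group has fewer than two non-gap residues.
    """
    if len(col_a) < 2 or len(col_b) < 2:
        raise ValueError("group too small: need >= 2 sequences per group")
    ea = np.array([AA_INDEX.get(c, -1) for c in col_a])
    eb = np.array([AA_INDEX.get(c, -1) for c in col_b])
    ca, ma = _column_stats(ea)
    cb, mb = _column_stats(eb)
    if ma < 2 or mb < 2:
        return None
    cons_a = float((ca @ SIMILARITY @ ca - ma) / 2.0 / (ma * (ma - 1) / 2.0))
    cons_b = float((cb @ SIMILARITY @ cb - mb) / 2.0 / (mb * (mb - 1) / 2.0))
    between = float(ca @ SIMILARITY @ cb / (ma * mb))
    groupsim = min(cons_a, cons_b) - between
    gapfrac_a = 1.0 - ma / len(col_a)
    gapfrac_b = 1.0 - mb / len(col_b)
    is_sdp = (
        cons_a >= tau_cons
        and cons_b >= tau_cons
        and groupsim >= tau_gs
        and gapfrac_a <= gap_max
        and gapfrac_b <= gap_max
    )
    return ColumnScores(
        position=position,
        cons_a=cons_a,
        cons_b=cons_b,
        between=between,
        groupsim=groupsim,
        gapfrac_a=gapfrac_a,
        gapfrac_b=gapfrac_b,
        is_sdp=is_sdp,
    )


def detect_sdps(
    aln_a: Sequence[str],
    aln_b: Sequence[str],
    params: CutParams = CutParams(),
) -> list[ColumnScores]:
    """Score every joint-alignment column between two groups.

    Both alignments must share column coordinates (equal widths). Columns
    with fewer than two usable residues in either group are skipped; the
    rest are returned ranked by differential conservation (descending;
    ties by position), with SDPs flagged.
    """
    if len({len(r) for r in list(aln_a) + list(aln_b)}) != 1:
        raise ValueError("detect_sdps: column-count mismatch between groups")
    ncols = len(aln_a[0])
    out: list[ColumnScores] = []
    for c in range(ncols):
        scores = group_column_scores(
            [row[c] for row in aln_a],
            [row[c] for row in aln_b],
            position=c + 1,
            tau_cons=params.tau_cons,
            tau_gs=params.tau_gs,
            gap_max=params.gap_max,
        )
        if scores is not None:
            out.append(scores)
    out.sort(key=lambda s: (-s.groupsim, s.position))
    return out


# ---------------------------------------------------------------------------
# cut decisions


def _child_rows(node: MergeNode) -> tuple[list[str], list[str]]:
    """Split a node's merged alignment into the two children's row blocks
    (rows are stacked left-then-right at merge time)."""
    n_left = node.left.cluster.size
    rows = node.cluster.alignment
    return rows[:n_left], rows[n_left:]


def decide_cut(
    node: MergeNode,
    n_min: int = 3,
    k_min: int = 2,
    dops_min: float = 70.0,
    tau_cons: float = TAU_CONS,
    tau_gs: float = TAU_GS,
    gap_max: float = GAP_MAX,
    small_family_exempt: int = SMALL_FAMILY_EXEMPT,
) -> bool:
    """Should the two children of this node stay separate families?

    True iff both children have at least ``n_min`` members and the joint
    alignment shows enough SDPs between them. The baseline requirement is
    ``k_min`` SDPs; when either child is both small (fewer than
    ``small_family_exempt`` members) and low-diversity (DOPs below
    ``dops_min``), conservation estimates from that child are less
    trustworthy, so the requirement doubles to ``2 * k_min`` SDPs.
    """
    if node.is_leaf:
        raise ValueError("decide_cut: leaf node has no children to separate")
    left, right = node.left.cluster, node.right.cluster
    if left.size < n_min or right.size < n_min:
        return False
    k_required = k_min
    for child in (left, right):
        if child.size < small_family_exempt and dops(child.alignment) < dops_min:
            k_required = 2 * k_min
            break
    params = CutParams(
        tau_cons=tau_cons, tau_gs=tau_gs, gap_max=gap_max,
        n_min=n_min, k_min=k_min, dops_min=dops_min,
        small_family_exempt=small_family_exempt,
    )
    rows_a, rows_b = _child_rows(node)
    n_sdps = sum(1 for s in detect_sdps(rows_a, rows_b, params) if s.is_sdp)
    return n_sdps >= k_required


@dataclass
class _Group:
    cluster: SeqCluster
    sdps: list[ColumnScores] = field(default_factory=list)


def cut_tree(
    tree: MergeTree,
    params: CutParams = CutParams(),
    pseudocount_weight: float = 1.0,
) -> list[FunFam]:
    """Cut a merge tree into functional families.

    Post-order traversal: whenever both children of a node are still single
    (uncut) groups and :func:`decide_cut` fires, the node becomes a family
    boundary; otherwise the children merge into one group carrying the
    node's merged alignment. A cut propagates — ancestors of a cut node
    never merge across it. The result is a partition of all leaf members.
    """

    def walk(node: MergeNode) -> list[_Group]:
        if node.is_leaf:
            return [_Group(cluster=node.cluster)]
        ga = walk(node.left)
        gb = walk(node.right)
        if len(ga) == 1 and len(gb) == 1:
            cut = decide_cut(
                node,
                n_min=params.n_min,
                k_min=params.k_min,
                dops_min=params.dops_min,
                tau_cons=params.tau_cons,
                tau_gs=params.tau_gs,
                gap_max=params.gap_max,
                small_family_exempt=params.small_family_exempt,
            )
            if not cut:
                return [_Group(cluster=node.cluster)]
            rows_a, rows_b = _child_rows(node)
            sdps = [
                s
                for s in detect_sdps(rows_a, rows_b, params)
                if s.is_sdp
            ]
            ga[0].sdps = sdps
            gb[0].sdps = sdps
            return ga + gb
        return ga + gb

    groups = walk(tree.root)
    groups.sort(key=lambda g: min(g.cluster.members))
    funfams = []
    for i, g in enumerate(groups, start=1):
        funfams.append(
            FunFam(
                id=f"FF-{i:05d}",
                members=list(g.cluster.members),
                alignment=list(g.cluster.alignment),
                profile=build_profile(g.cluster, pseudocount_weight),
                sdps_vs_sibling=g.sdps,
            )
        )
    return funfams


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class UnannotatedAssignment:
    cluster_id: str
    funfam_id: str
    score: float
    confident: bool | None = None


@dataclass
class ClassificationResult:
    funfams: list[FunFam]
    held_out: list[SeqCluster] = field(default_factory=list)
    unannotated_assignments: list[UnannotatedAssignment] = field(default_factory=list)
    mda_of_unit: dict[str, str] = field(default_factory=dict)


def _experimental_map(annotations) -> dict[str, bool]:
    if isinstance(annotations, pd.DataFrame):
        return {
            str(r.seq_id): bool(r.experimental) for r in annotations.itertuples()
        }
    if isinstance(annotations, Mapping):
        return {str(k): bool(v) for k, v in annotations.items()}
    return {a.seq_id: bool(a.experimental) for a in annotations}


def assign_unannotated(
    clusters: Sequence[SeqCluster],
    funfams: Sequence[FunFam],
    pseudocount_weight: float = 1.0,
    score_threshold: float | None = None,
) -> list[UnannotatedAssignment]:
    """Advisory assignment of held-out clusters to their closest family.

    Each cluster's profile is compared against every family profile; the
    best-scoring family is reported (members are NOT added). When a
    ``score_threshold`` is given, assignments below it are flagged as not
    confident."""
    out: list[UnannotatedAssignment] = []
    for cl in clusters:
        prof = build_profile(cl, pseudocount_weight)
        best_ff, best_score = None, -np.inf
        for ff in funfams:
            score, _, _ = align_profiles(prof, ff.profile)
            if score > best_score:
                best_ff, best_score = ff, score
        if best_ff is None:
            continue
        conf = None if score_threshold is None else bool(best_score >= score_threshold)
        out.append(
            UnannotatedAssignment(
                cluster_id=cl.id,
                funfam_id=best_ff.id,
                score=float(best_score),
                confident=conf,
            )
        )
    return out


def classify_superfamily(
    units: Sequence[FunctionalUnit],
    hits: Sequence[DomainHit],
    annotations,
    params: ClassifyParams = ClassifyParams(),
) -> ClassificationResult:
    """Full classification pipeline for one superfamily.

    Units are partitioned by multi-domain architecture; each partition is
    clustered at the identity threshold, stripped of clusters lacking any
    experimental annotation, agglomerated into a merge tree and cut into
    families; the per-MDA families are then pooled as the starting clusters
    of one final merge-and-cut iteration, letting families that span several
    architectures coalesce. Held-out (unannotated) clusters are scanned
    against the final family profiles for an advisory assignment.
    """
    units = list(units)
    if not units:
        raise ValueError("classify_superfamily: no functional units")
    hits_by_seq: dict[str, list[DomainHit]] = {}
    for h in hits:
        hits_by_seq.setdefault(h.seq_id, []).append(h)
    exp = _experimental_map(annotations)

    # MDA per unit
    mda_of_unit: dict[str, str] = {}
    units_by_mda: dict[str, list[FunctionalUnit]] = {}
    for seq_id in sorted({u.seq_id for u in units}):
        seq_units = [u for u in units if u.seq_id == seq_id]
        arch = resolve_hits(hits_by_seq.get(seq_id, []), seq_id=seq_id)
        if not arch.hits:
            raise ValueError(f"classify_superfamily: no hits for {seq_id}")
        mda = assign_mda(arch, seq_units)
        for u in seq_units:
            mda_of_unit[u.uid] = str(mda)
            units_by_mda.setdefault(str(mda), []).append(u)

    pooled: list[SeqCluster] = []
    held_out: list[SeqCluster] = []
    for mda_key in sorted(units_by_mda):
        clusters = greedy_cluster(units_by_mda[mda_key], params.s90_threshold)
        annotated: list[SeqCluster] = []
        for cl in clusters:
            cl.annotated = any(exp.get(member_seq_id(m), False) for m in cl.members)
            (annotated if cl.annotated else held_out).append(cl)
        if not annotated:
            logger.info("MDA %s: no annotated clusters, held out entirely", mda_key)
            continue
        tree = build_merge_tree(annotated, params.pseudocount_weight)
        for ff in cut_tree(tree, params.cut, params.pseudocount_weight):
            pooled.append(
                SeqCluster(
                    id=min(ff.members),
                    members=ff.members,
                    alignment=ff.alignment,
                    annotated=True,
                )
            )
    if not pooled:
        raise ValueError("classify_superfamily: zero annotated clusters")

    final_tree = build_merge_tree(pooled, params.pseudocount_weight)
    funfams = cut_tree(final_tree, params.cut, params.pseudocount_weight)
    for ff in funfams:
        ff.mda_set = {mda_of_unit[m] for m in ff.members}
    assignments = assign_unannotated(held_out, funfams, params.pseudocount_weight)
    return ClassificationResult(
        funfams=funfams,
        held_out=held_out,
        unannotated_assignments=assignments,
        mda_of_unit=mda_of_unit,
    )
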