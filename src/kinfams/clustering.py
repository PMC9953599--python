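"""Identity pre-clustering, frequency profiles and agglomerative merge trees.

The classification pipeline seeds from 90%-identity clusters (S90) inside
each multi-domain-architecture partition, summarises each cluster as a
position-specific frequency profile with background pseudocounts and
position-based sequence weights, and grows a binary merge tree by repeatedly
joining the highest-scoring pair of clusters under global profile-profile
alignment. Cutting that tree into functional families happens in
:mod:`kinfams.funfam_cut`.

Profiles (rather than full HMMs with insert/delete states) are used for the
cluster comparisons: the comparison scores only drive the merge order, and a
profile-profile dynamic-programming score preserves that ordering while
staying directly checkable against a plain sequence-alignment oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._align import (
    AMINO_ACIDS,
    BACKGROUND_FREQS,
    BLOSUM62,
    GAP_CHARS,
    encode,
    gotoh_align,
    run_gotoh_score,
    seq_pair_score_matrix,
)
from .sequence_domains import FunctionalUnit

#: Affine gap penalties for sequence-sequence identity alignments.
SEQ_GAP_OPEN, SEQ_GAP_EXT = -10.0, -0.5
#: Affine gap penalties for profile-profile alignments.
PROFILE_GAP_OPEN, PROFILE_GAP_EXT = -10.0, -1.0

S90_THRESHOLD = 0.90


@dataclass
class SeqCluster:
    """A cluster of functional-unit sequences with a rectangular alignment."""

    id: str
    members: list[str]
    alignment: list[str]
    annotated: bool = False

    def __post_init__(self) -> None:
        if len(self.members) != len(self.alignment):
            raise ValueError(f"cluster {self.id}: one alignment row per member")
        widths = {len(r) for r in self.alignment}
        if len(widths) > 1:
            raise ValueError(f"cluster {self.id}: ragged alignment")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"cluster {self.id}: duplicate members")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def ncols(self) -> int:
        return len(self.alignment[0]) if self.alignment else 0


@dataclass
class ProfileModel:
    """Per-column residue probabilities (rows sum to 1)."""

    columns: np.ndarray  # (ncols, 20)
    pseudocount_weight: float

    @property
    def ncols(self) -> int:
        return int(self.columns.shape[0])


@dataclass
class MergeNode:
    cluster: SeqCluster
    left: "MergeNode | None" = None
    right: "MergeNode | None" = None
    merge_score: float | None = None
    merge_order: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class MergeTree:
    root: MergeNode
    leaves: list[MergeNode] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def internal_nodes(self) -> list[MergeNode]:
        out: list[MergeNode] = []

        def walk(node: MergeNode) -> None:
            if node.is_leaf:
                return
            walk(node.left)
            walk(node.right)
            out.append(node)

        walk(self.root)
        return out


# ---------------------------------------------------------------------------
# pairwise identity


def _align_pair(a: str, b: str):
    Sa, Sb = encode(a), encode(b)
    if (Sa < 0).any() or (Sb < 0).any():
        # Unknown residues get a flat mild mismatch score for alignment.
        S = np.full((len(a), len(b)), -1.0)
        ok_a, ok_b = Sa >= 0, Sb >= 0
        S[np.ix_(ok_a, ok_b)] = BLOSUM62[np.ix_(Sa[ok_a], Sb[ok_b])]
    else:
        S = seq_pair_score_matrix(Sa, Sb)
    return S


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity in [0, 1].

    BLOSUM62-scored global alignment (gap open -10, extend -0.5); identity is
    the number of identically aligned residue pairs divided by the length of
    the shorter sequence. For equal-length pairs where the gapless diagonal
    already achieves the optimal score, the diagonal is used as the (optimal)
    alignment.
    """
    if not a or not b:
        raise ValueError("pairwise_identity: empty sequence")
    S = _align_pair(a, b)
    opt = run_gotoh_score(S, SEQ_GAP_OPEN, SEQ_GAP_EXT)
    denom = min(len(a), len(b))
    if len(a) == len(b):
        diag = float(np.trace(S))
        if diag >= opt - 1e-9:
            matches = sum(x == y for x, y in zip(a, b))
            return matches / denom
    _, a_idx, b_idx = gotoh_align(S, SEQ_GAP_OPEN, SEQ_GAP_EXT)
    matches = 0
    for i, j in zip(a_idx, b_idx):
        if i >= 0 and j >= 0 and a[i] == b[j]:
            matches += 1
    return matches / denom


# ---------------------------------------------------------------------------
# greedy identity clustering (S90)


def _as_id_seq(units: Sequence) -> list[tuple[str, str]]:
    out = []
    for u in units:
        if isinstance(u, FunctionalUnit):
            out.append((u.uid, u.unit_seq))
        else:
            uid, seq = u
            out.append((str(uid), str(seq)))
    return out


def _star_alignment(rep: str, member_seqs: list[str]) -> list[str]:
    """Align each member to the representative and merge on rep coordinates.

    Insertion columns (member residues aligned to no rep position) are pooled
    per rep-gap location, sized by the longest insertion among members.
    """
    if not member_seqs:
        return []
    # per member: list over rep positions 0..len(rep) of inserted residues
    # before that rep position, plus aligned residue (or '-') per position.
    aligned_res = []
    inserts = []
    for seq in member_seqs:
        if seq == rep:
            aligned_res.append(list(seq))
            inserts.append([""] * (len(rep) + 1))
            continue
        S = _align_pair(rep, seq)
        _, r_idx, s_idx = gotoh_align(S, SEQ_GAP_OPEN, SEQ_GAP_EXT)
        res = ["-"] * len(rep)
        ins = [""] * (len(rep) + 1)
        next_rep = 0
        for i, j in zip(r_idx, s_idx):
            if i >= 0 and j >= 0:
                res[i] = seq[j]
                next_rep = i + 1
            elif i >= 0:
                next_rep = i + 1
            else:  # insertion relative to rep
                ins[next_rep] += seq[j]
        aligned_res.append(res)
        inserts.append(ins)
    widths = [max(len(ins[p]) for ins in inserts) for p in range(len(rep) + 1)]
    rows = []
    for res, ins in zip(aligned_res, inserts):
        parts = []
        for p in range(len(rep)):
            parts.append(ins[p].ljust(widths[p], "-"))
            parts.append(res[p])
        parts.append(ins[len(rep)].ljust(widths[len(rep)], "-"))
        rows.append("".join(parts))
    return rows


def greedy_cluster(units: Sequence, threshold: float = S90_THRESHOLD) -> list[SeqCluster]:
    """Greedy incremental identity clustering (CD-HIT style).

    Sequences are visited longest first (ties by id ascending); each joins
    the first existing representative with identity >= ``threshold`` or
    founds a new cluster. Cluster alignments are star alignments against the
    representative.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    items = _as_id_seq(units)
    items.sort(key=lambda t: (-len(t[1]), t[0]))
    reps: list[tuple[str, str]] = []
    assigned: dict[str, list[tuple[str, str]]] = {}
    for uid, seq in items:
        placed = False
        for rep_id, rep_seq in reps:
            if pairwise_identity(seq, rep_seq) >= threshold:
                assigned[rep_id].append((uid, seq))
                placed = True
                break
        if not placed:
            reps.append((uid, seq))
            assigned[uid] = [(uid, seq)]
    clusters = []
    for rep_id, rep_seq in reps:
        member_ids = [uid for uid, _ in assigned[rep_id]]
        member_seqs = [seq for _, seq in assigned[rep_id]]
        rows = _star_alignment(rep_seq, member_seqs)
        clusters.append(SeqCluster(id=rep_id, members=member_ids, alignment=rows))
    return clusters


# ---------------------------------------------------------------------------
# profiles


def position_based_weights(alignment: list[str]) -> np.ndarray:
    """Henikoff position-based sequence weights, normalised to sum to n."""
    n = len(alignment)
    ncols = len(alignment[0]) if alignment else 0
    w = np.zeros(n)
    enc = [encode(row) for row in alignment]
    for c in range(ncols):
        col = np.array([e[c] for e in enc])
        residues, counts = np.unique(col[col >= 0], return_counts=True)
        r = len(residues)
        if r == 0:
            continue
        count_of = dict(zip(residues.tolist(), counts.tolist()))
        for s in range(n):
            a = col[s]
            if a >= 0:
                w[s] += 1.0 / (r * count_of[int(a)])
    total = w.sum()
    if total == 0:
        return np.ones(n)
    return w * (n / total)


def build_profile(cluster: SeqCluster, pseudocount_weight: float = 1.0) -> ProfileModel:
    """Weighted residue-frequency profile with background pseudocounts.

    Column probability of residue a:
    ``(weighted count of a + pc * background(a)) / (weighted non-gap total + pc)``.
    All-gap columns fall back to the background distribution.
    """
    if not cluster.alignment:
        raise ValueError(f"cluster {cluster.id}: empty alignment")
    rows = cluster.alignment
    n, ncols = len(rows), len(rows[0])
    weights = position_based_weights(rows)
    enc = np.stack([encode(r) for r in rows])  # (n, ncols), -1 for gap/X
    cols = np.zeros((ncols, 20))
    for c in range(ncols):
        col = enc[:, c]
        ok = col >= 0
        if not ok.any():
            cols[c] = BACKGROUND_FREQS
            continue
        counts = np.bincount(col[ok], weights=weights[ok], minlength=20)[:20]
        total = counts.sum()
        cols[c] = (counts + pseudocount_weight * BACKGROUND_FREQS) / (
            total + pseudocount_weight
        )
    return ProfileModel(columns=cols, pseudocount_weight=pseudocount_weight)


def _profile_score_matrix(p: ProfileModel, q: ProfileModel) -> np.ndarray:
    """Expected BLOSUM62 substitution score per column pair."""
    return p.columns @ BLOSUM62 @ q.columns.T


def score_profiles(p: ProfileModel, q: ProfileModel) -> float:
    """Global profile-profile alignment score, normalised by the shorter
    profile's column count. Symmetric in its arguments."""
    if p.ncols == 0 or q.ncols == 0:
        raise ValueError("empty profile")
    S = _profile_score_matrix(p, q)
    raw = run_gotoh_score(S, PROFILE_GAP_OPEN, PROFILE_GAP_EXT)
    return raw / min(p.ncols, q.ncols)


def align_profiles(p: ProfileModel, q: ProfileModel):
    """As :func:`score_profiles` but also returns the alignment path
    (per-column source indices, -1 for gaps)."""
    S = _profile_score_matrix(p, q)
    raw, a_idx, b_idx = gotoh_align(S, PROFILE_GAP_OPEN, PROFILE_GAP_EXT)
    return raw / min(p.ncols, q.ncols), a_idx, b_idx


def _merge_alignments(
    ca: SeqCluster, cb: SeqCluster, a_idx: np.ndarray, b_idx: np.ndarray
) -> list[str]:
    """Stack two cluster alignments along a profile-profile alignment path,
    inserting all-gap columns where the path gaps one side."""
    rows = []
    for row in ca.alignment:
        rows.append("".join(row[i] if i >= 0 else "-" for i in a_idx))
    for row in cb.alignment:
        rows.append("".join(row[j] if j >= 0 else "-" for j in b_idx))
    return rows


# ---------------------------------------------------------------------------
# agglomerative merge tree


def build_merge_tree(
    clusters: Sequence[SeqCluster], pseudocount_weight: float = 1.0
) -> MergeTree:
    """Agglomerative profile clustering: repeatedly merge the pair of active
    clusters with the highest profile-profile score (ties: smaller
    lexicographic id pair) until a single root remains.

    Merged alignments follow the profile-profile alignment path, so member
    rows de-gap back to the original sequences at every level.
    """
    if not clusters:
        raise ValueError("build_merge_tree: no clusters")
    nodes = [MergeNode(cluster=c) for c in clusters]
    leaves = list(nodes)
    profiles = {id(n): build_profile(n.cluster, pseudocount_weight) for n in nodes}
    active = sorted(nodes, key=lambda n: n.cluster.id)
    pair_cache: dict[tuple[str, str], tuple[float, np.ndarray, np.ndarray]] = {}

    def pair_result(na: MergeNode, nb: MergeNode):
        key = tuple(sorted((na.cluster.id, nb.cluster.id)))
        if key not in pair_cache:
            if na.cluster.id > nb.cluster.id:
                na, nb = nb, na
            score, a_idx, b_idx = align_profiles(profiles[id(na)], profiles[id(nb)])
            pair_cache[key] = (score, a_idx, b_idx)
        return pair_cache[key]

    order = 0
    while len(active) > 1:
        best_key = None
        best_score = -np.inf
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                score, _, _ = pair_result(active[i], active[j])
                key = tuple(sorted((active[i].cluster.id, active[j].cluster.id)))
                if score > best_score or (score == best_score and key < best_key):
                    best_score = score
                    best_key = key
        by_id = {n.cluster.id: n for n in active}
        na, nb = by_id[best_key[0]], by_id[best_key[1]]
        score, a_idx, b_idx = pair_result(na, nb)
        merged_rows = _merge_alignments(na.cluster, nb.cluster, a_idx, b_idx)
        order += 1
        merged = SeqCluster(
            id=min(na.cluster.id, nb.cluster.id),
            members=na.cluster.members + nb.cluster.members,
            alignment=merged_rows,
            annotated=na.cluster.annotated or nb.cluster.annotated,
        )
        node = MergeNode(
            cluster=merged, left=na, right=nb, merge_score=score, merge_order=order
        )
        profiles[id(node)] = build_profile(merged, pseudocount_weight)
        active = [n for n in active if n is not na and n is not nb]
        active.append(node)
        active.sort(key=lambda n: n.cluster.id)
        # drop cache entries touching the merged ids
        stale = {na.cluster.id, nb.cluster.id}
        pair_cache = {
            k: v for k, v in pair_cache.items() if not (set(k) & stale)
        }
    return MergeTree(root=active[0], leaves=leaves)
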