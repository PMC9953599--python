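"""Family evaluation: conservation, alignment diversity, EC purity,
profile scanning with E-value calibration, and family-to-family mapping.

Conservation of an alignment column is the mean pairwise residue similarity
(substitution-matrix kernel, see :mod:`kinfams._align`) over non-gap pairs,
down-weighted by the column's gap fraction. The diversity-of-positions score
(DOPs) summarises how varied those per-column values are across an
alignment; families scoring above 70 carry enough sequence diversity for
conserved positions to be informative, while low-DOPs families are typically
tiny or taxonomically narrow.

Profile scans replace HMM searches: a query is aligned to each family
profile and the raw score is converted to an E-value through a Gumbel null
distribution fitted (method of moments) to scores of random background
sequences. The default reporting cutoff of 1e-18 marks matches close enough
to imply shared catalytic function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import (
    BACKGROUND_FREQS,
    AMINO_ACIDS,
    BLOSUM62,
    GAP_CHARS,
    SIMILARITY,
    encode,
    run_gotoh_score,
)
from .clustering import PROFILE_GAP_EXT, PROFILE_GAP_OPEN, ProfileModel

EULER_GAMMA = 0.5772156649015329

#: Default reporting threshold for profile scans.
DEFAULT_EVALUE_MAX = 1e-18


# ---------------------------------------------------------------------------
# conservation and DOPs


def conservation_score(column: Sequence[str]) -> float:
    """Mean pairwise similarity of the non-gap residues of one column,
    multiplied by (1 - gap fraction). Columns with fewer than two usable
    residues score 0. 'X' counts as a gap."""
    if len(column) == 0:
        raise ValueError("conservation_score: empty column")
    idx = np.array([encode(c)[0] if c not in GAP_CHARS else -1 for c in column])
    res = idx[idx >= 0]
    m = len(res)
    if m < 2:
        return 0.0
    counts = np.bincount(res, minlength=20)[:20].astype(float)
    pair_sum = (counts @ SIMILARITY @ counts - counts.sum()) / 2.0
    npairs = m * (m - 1) / 2.0
    gap_frac = 1.0 - m / len(column)
    return float(pair_sum / npairs) * (1.0 - gap_frac)


def column_conservation(alignment: Sequence[str]) -> np.ndarray:
    """Vector of conservation scores, one per alignment column."""
    if len(alignment) < 2:
        raise ValueError("need >= 2 sequences")
    enc = np.stack([encode(r) for r in alignment])
    n, ncols = enc.shape
    out = np.empty(ncols)
    for c in range(ncols):
        col = enc[:, c]
        res = col[col >= 0]
        m = len(res)
        if m < 2:
            out[c] = 0.0
            continue
        counts = np.bincount(res, minlength=20)[:20].astype(float)
        pair_sum = (counts @ SIMILARITY @ counts - m) / 2.0
        out[c] = pair_sum / (m * (m - 1) / 2.0) * (m / n)
    return out


def dops(alignment: Sequence[str]) -> float:
    """Diversity-of-positions score in [0, 100].

    100 times the number of distinct per-column conservation scores (rounded
    to 4 decimals) divided by the number of columns. An alignment of
    identical sequences has a single distinct score and thus a low DOPs;
    values above 70 indicate high sequence diversity.
    """
    if len(alignment) < 2:
        raise ValueError("dops undefined for single-sequence alignments")
    ncols = len(alignment[0])
    if ncols < 1:
        raise ValueError("dops: empty alignment")
    scores = column_conservation(alignment)
    distinct = len({round(float(s), 4) for s in scores})
    return 100.0 * distinct / ncols


# ---------------------------------------------------------------------------
# EC purity


@dataclass(frozen=True)
class ECAnnotation:
    """A 4-field Enzyme Commission annotation for one sequence."""

    seq_id: str
    ec4: str
    experimental: bool = True

    def __post_init__(self) -> None:
        fields = self.ec4.split(".")
        if len(fields) != 4 or any(not f for f in fields):
            raise ValueError(f"malformed EC number {self.ec4!r} for {self.seq_id}")

    @property
    def ec3(self) -> str:
        return ".".join(self.ec4.split(".")[:3])


@dataclass
class PurityReport:
    """EC purity of a family set at the 3- and 4-field levels."""

    per_family: pd.DataFrame  # funfam_id, n_seqs_with_ec, unique_ec3, unique_ec4
    fraction_one_ec3: float
    fraction_one_ec4: float
    n_families_with_ec: int


def member_seq_id(member: str) -> str:
    """Map a functional-unit id ('SEQ/10-289') back to its sequence id."""
    return member.split("/", 1)[0]


def _annotation_map(annotations) -> dict[str, ECAnnotation]:
    """Normalise annotations (DataFrame, iterable of ECAnnotation, or mapping)
    to seq_id -> ECAnnotation, keeping experimental annotations only."""
    out: dict[str, ECAnnotation] = {}
    if isinstance(annotations, pd.DataFrame):
        records = (
            ECAnnotation(str(r.seq_id), str(r.ec4), bool(r.experimental))
            for r in annotations.itertuples()
        )
    elif isinstance(annotations, Mapping):
        records = (
            ECAnnotation(str(k), str(v), True) for k, v in annotations.items()
        )
    else:
        records = iter(annotations)
    for ann in records:
        if ann.experimental:
            out[ann.seq_id] = ann
    return out


def ec_purity(funfams, annotations) -> PurityReport:
    """Count distinct EC3/EC4 codes per family among experimentally
    EC-annotated members; summary fractions cover only families with at
    least one annotated member."""
    ann = _annotation_map(annotations)
    rows = []
    one3 = one4 = with_ec = 0
    for ff in funfams:
        anns = [ann[member_seq_id(m)] for m in ff.members if member_seq_id(m) in ann]
        ec4s = {a.ec4 for a in anns}
        ec3s = {a.ec3 for a in anns}
        rows.append((ff.id, len(anns), len(ec3s), len(ec4s)))
        if ec4s:
            with_ec += 1
            one3 += len(ec3s) == 1
            one4 += len(ec4s) == 1
    per_family = pd.DataFrame(
        rows, columns=["funfam_id", "n_seqs_with_ec", "unique_ec3", "unique_ec4"]
    )
    return PurityReport(
        per_family=per_family,
        fraction_one_ec3=one3 / with_ec if with_ec else float("nan"),
        fraction_one_ec4=one4 / with_ec if with_ec else float("nan"),
        n_families_with_ec=with_ec,
    )


# ---------------------------------------------------------------------------
# profile scanning with E-values


@dataclass(frozen=True)
class ScanHit:
    seq_id: str
    funfam_id: str
    bit_score: float
    evalue: float


@dataclass(frozen=True)
class EvalueCalibration:
    """Gumbel null for one profile: E(s) = n_db * P(S >= s) under the null."""

    lam: float
    mu: float

    def evalue(self, score: float, n_db: int) -> float:
        x = -self.lam * (score - self.mu)
        # exceedance of the Gumbel CDF, numerically safe for large scores
        if x < -30:
            p = math.exp(x)  # 1 - exp(-exp(x)) ~ exp(x)
        else:
            p = -math.expm1(-math.exp(x))
        return n_db * p


def score_sequence_against_profile(seq: str, profile: ProfileModel) -> float:
    """Global alignment score of a sequence against a profile, normalised by
    the shorter of (sequence length, profile columns)."""
    enc = encode(seq)
    ok = enc >= 0
    S = np.full((len(seq), profile.ncols), -1.0)
    if ok.any():
        S[ok] = BLOSUM62[enc[ok]] @ profile.columns.T
    raw = run_gotoh_score(S, PROFILE_GAP_OPEN, PROFILE_GAP_EXT)
    return raw / min(len(seq), profile.ncols)


def random_background_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=BACKGROUND_FREQS))


def calibrate_evalues(
    profile: ProfileModel, n_decoys: int = 200, seed: int = 0
) -> EvalueCalibration:
    """Fit a Gumbel null to scores of random background decoys.

    ``n_decoys`` length-matched i.i.d. background sequences are scored
    against the profile; method-of-moments gives
    ``lambda = pi / (sigma * sqrt(6))`` and ``mu = mean - gamma / lambda``.
    """
    if n_decoys < 50:
        raise ValueError("calibrate_evalues: need at least 50 decoys")
    rng = np.random.default_rng(seed)
    scores = np.array(
        [
            score_sequence_against_profile(
                random_background_sequence(profile.ncols, rng), profile
            )
            for _ in range(n_decoys)
        ]
    )
    sigma = scores.std(ddof=1)
    if sigma <= 0 or not np.isfinite(sigma):
        raise ValueError("calibrate_evalues: degenerate decoy score variance")
    lam = math.pi / (sigma * math.sqrt(6.0))
    mu = float(scores.mean()) - EULER_GAMMA / lam
    return EvalueCalibration(lam=lam, mu=mu)


def scan_sequences(
    seqs,
    funfams,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    n_decoys: int = 200,
    seed: int = 0,
    n_db: int | None = None,
    calibrations: Mapping[str, EvalueCalibration] | None = None,
) -> list[ScanHit]:
    """Scan sequences against family profiles; report the best-scoring family
    with E <= ``evalue_max`` per sequence (sequences without such a hit are
    omitted). ``n_db`` defaults to the number of scanned sequences."""
    seqs = list(seqs)
    if n_db is None:
        n_db = max(len(seqs), 1)
    if calibrations is None:
        calibrations = {
            ff.id: calibrate_evalues(ff.profile, n_decoys=n_decoys, seed=seed + i)
            for i, ff in enumerate(funfams)
        }
    hits: list[ScanHit] = []
    for s in seqs:
        seq_id, residues = (s.id, s.residues) if hasattr(s, "residues") else s
        best: ScanHit | None = None
        for ff in funfams:
            score = score_sequence_against_profile(residues, ff.profile)
            ev = calibrations[ff.id].evalue(score, n_db)
            if ev <= evalue_max and (best is None or score > best.bit_score):
                best = ScanHit(seq_id, ff.id, score, ev)
        if best is not None:
            hits.append(best)
    return hits


# ---------------------------------------------------------------------------
# family-to-family mapping


@dataclass
class MappingReport:
    """Relations of reference families to a test partition.

    Each reference family receives exactly one label: ``one-to-one`` (all
    members in a single test family that holds no other reference family),
    ``split`` (members spread over several test families), ``merged``
    (single test family, but that family also holds another reference
    family), or ``unmapped`` (no member present in the test partition).
    A family both split and sharing test families with others is labelled
    ``split``.
    """

    relations: dict[str, str]
    matches: dict[str, list[str]]
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {
                label: sum(1 for v in self.relations.values() if v == label)
                for label in ("one-to-one", "split", "merged", "unmapped")
            }


def map_families(
    reference_partition: Mapping[str, Iterable[str]],
    test_partition: Mapping[str, Iterable[str]],
    scan_hits: Iterable[ScanHit] | None = None,
) -> MappingReport:
    """Map reference families onto test families by shared members.

    Membership comes from the test partition; ``scan_hits`` may supplement it
    for sequences absent from the test partition (hit target = test family).
    """
    member_to_test: dict[str, str] = {}
    for tid, members in test_partition.items():
        for m in members:
            member_to_test[m] = tid
    if scan_hits:
        for h in scan_hits:
            member_to_test.setdefault(h.seq_id, h.funfam_id)
    test_to_refs: dict[str, set[str]] = {}
    ref_to_tests: dict[str, list[str]] = {}
    for rid, members in reference_partition.items():
        tests = {member_to_test[m] for m in members if m in member_to_test}
        ref_to_tests[rid] = sorted(tests)
        for t in tests:
            test_to_refs.setdefault(t, set()).add(rid)
    relations: dict[str, str] = {}
    for rid, tests in ref_to_tests.items():
        if not tests:
            relations[rid] = "unmapped"
        elif len(tests) > 1:
            relations[rid] = "split"
        elif len(test_to_refs[tests[0]]) > 1:
            relations[rid] = "merged"
        else:
            relations[rid] = "one-to-one"
    return MappingReport(relations=relations, matches=ref_to_tests)


def family_recovery_ari(
    funfams, truth_labels: Mapping[str, int | str]
) -> float:
    """Adjusted Rand index between a family partition and ground-truth
    labels (keyed by sequence id); members without a truth label are
    ignored."""
    from sklearn.metrics import adjusted_rand_score

    pred, true = [], []
    for ff in funfams:
        for m in ff.members:
            sid = member_seq_id(m)
            if sid in truth_labels:
                pred.append(ff.id)
                true.append(truth_labels[sid])
    if not pred:
        raise ValueError("no overlap between families and truth labels")
    return float(adjusted_rand_score(true, pred))
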