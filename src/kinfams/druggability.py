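"""Drug-record filtering and drug-target enrichment of families.

A *drug* here is a clinically approved small molecule (maximum development
phase 4) with a direct single-protein binding assay (assay type 'B'),
potency of at least pChEMBL 6 (<= 1 uM half-maximal), activity stronger
than 1 mM, and an ATC code in the antineoplastic protein-kinase-inhibitor
class (prefix "L01E"). Families whose members are over-represented among
the targets of such drugs — exact hypergeometric upper tail, adjusted by
Benjamini-Hochberg — are flagged druggable at q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .evaluation import member_seq_id

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class DrugRecord:
    """One drug-target activity record (ChEMBL-style)."""

    drug_id: str
    target_seq_id: str
    max_phase: int
    assay_type: str
    pchembl: float
    activity_nM: float
    atc_code: str

    def __post_init__(self) -> None:
        if self.pchembl < 0:
            raise ValueError(f"{self.drug_id}: negative pChEMBL")
        if self.activity_nM <= 0:
            raise ValueError(f"{self.drug_id}: non-positive activity")


@dataclass
class EnrichmentResult:
    """Drug-target over-representation for one family."""

    funfam_id: str
    n_members: int
    n_targets: int
    universe_n: int
    universe_targets: int
    p_value: float
    q_value: float | None = None
    druggable: bool | None = None


def filter_drug_records(
    records: Iterable[DrugRecord],
    phase_min: int = 4,
    assay: str = "B",
    pchembl_min: float = 6.0,
    activity_max_nM: float = 1e6,
    atc_prefix: str = "L01E",
) -> list[DrugRecord]:
    """Keep approved, direct-binding, potent kinase-inhibitor records.

    A record passes iff max_phase >= ``phase_min``, assay_type equals
    ``assay``, pChEMBL >= ``pchembl_min``, activity < ``activity_max_nM``
    (stronger than 1 mM by default) and the ATC code starts with
    ``atc_prefix``. Order-preserving and idempotent.
    """
    return [
        r
        for r in records
        if r.max_phase >= phase_min
        and r.assay_type == assay
        and r.pchembl >= pchembl_min
        and r.activity_nM < activity_max_nM
        and r.atc_code.startswith(atc_prefix)
    ]


def family_enrichment(
    funfams, target_ids: set[str], universe_ids: set[str]
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of drug targets per family.

    With N = |universe|, K = |targets|, n = family size and k = targets in
    the family, the p-value is the exact upper tail P(X >= k).
    """
    stray = target_ids - universe_ids
    if stray:
        raise ValueError(f"target ids outside universe: {sorted(stray)[:5]}")
    results = []
    N, K = len(universe_ids), len(target_ids)
    for ff in funfams:
        seq_ids = {member_seq_id(m) for m in ff.members}
        outside = seq_ids - universe_ids
        if outside:
            raise ValueError(
                f"family {ff.id}: members outside universe: {sorted(outside)[:5]}"
            )
        n = len(seq_ids)
        k = len(seq_ids & target_ids)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                funfam_id=ff.id,
                n_members=n,
                n_targets=k,
                universe_n=N,
                universe_targets=K,
                p_value=min(p, 1.0),
            )
        )
    return results


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("bh_fdr: p-values must lie in (0, 1]")
    return [float(q) for q in stats.false_discovery_control(p, method="bh")]


def annotate_fdr(
    results: Sequence[EnrichmentResult], alpha: float = DEFAULT_ALPHA
) -> list[EnrichmentResult]:
    """Attach BH q-values and druggable flags (q < alpha) to results."""
    qs = bh_fdr([r.p_value for r in results])
    return [
        replace(r, q_value=q, druggable=q < alpha) for r, q in zip(results, qs)
    ]


def druggable_families(
    results: Sequence[EnrichmentResult], alpha: float = DEFAULT_ALPHA
) -> list[str]:
    """Ids of families with q < alpha, sorted by q then id. Computes BH
    q-values first if the results carry none."""
    if any(r.q_value is None for r in results):
        results = annotate_fdr(results, alpha)
    flagged = [r for r in results if r.q_value is not None and r.q_value < alpha]
    flagged.sort(key=lambda r: (r.q_value, r.funfam_id))
    return [r.funfam_id for r in flagged]


def drug_family_associations(
    records: Iterable[DrugRecord], funfams
) -> list[tuple[str, str, int]]:
    """Secondary per-drug table: (drug_id, funfam_id, n shared targets)."""
    fam_of_seq: dict[str, set[str]] = {}
    for ff in funfams:
        for m in ff.members:
            fam_of_seq.setdefault(member_seq_id(m), set()).add(ff.id)
    counts: dict[tuple[str, str], int] = {}
    for r in records:
        for fid in fam_of_seq.get(r.target_seq_id, ()):
            counts[(r.drug_id, fid)] = counts.get((r.drug_id, fid), 0) + 1
    return sorted((d, f, n) for (d, f), n in counts.items())
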