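"""Synthetic superfamilies with known ground truth.

The generator emulates the statistical structure the classification
protocol relies on: families that are conserved within but differentially
conserved between, embedded in proteins whose domain content varies.

Each bundle derives from one root consensus of a two-lobe functional unit
(N-lobe + hinge linker + C-lobe, 280 residues by default, matching the
250-300-residue catalytic domain of protein kinases). A family is the root
consensus with

* a family-specific residue at each designated SDP column — drawn from a
  mutually dissimilar residue set, so every family pair differs at every
  SDP column and the planted per-pair SDP lists are exact;
* a family-specific residue at each *separation* column: conserved within
  the family but drawn from a pair of chemically similar residues (e.g.
  K/R, Q/E), with the two letters distributed over families along balanced
  splits. Such columns lower cross-family identity and profile scores —
  keeping families apart through clustering and tree building, as neutral
  lineage-specific substitutions do in real families — yet can never be
  flagged as SDPs, because the between-group similarity at a similar pair
  keeps the differential-conservation score deterministically below the
  SDP threshold;
* substitutions elsewhere at the within-family mutation rate, applied as a
  fixed per-sequence count (rate × mutable columns) at uniformly chosen
  positions, so every member carries the same mutation load.

Units are wrapped with accessory domains according to per-family MDA
layouts, and domain hits (with optional low-scoring decoy overlaps), EC
annotations, experimental flags and ChEMBL-style drug records are emitted
alongside exact truth tables. Indels are disabled so alignment columns map
one-to-one onto unit positions and the ground truth stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import AMINO_ACIDS
from .druggability import DrugRecord
from .sequence_domains import (
    C_LOBE_FAMILY,
    DomainHit,
    N_LOBE_FAMILY,
    ProteinSequence,
)

#: Residues used at SDP columns: pairwise similarity <= 0.3 under the
#: package's kernel, so any two families are strongly differentially
#: conserved at every SDP column.
SDP_RESIDUES = "CDGIRW"

#: Similar residue pairs used at separation columns. Every pair has
#: similarity > 0.6 under the package's kernel, so a column conserved to
#: one letter in group A and the other letter in group B has a
#: differential-conservation score of at most 1 - 0.625 = 0.375 < 0.4 and
#: can never be an SDP — while still lowering cross-family identity and
#: profile scores.
SEPARATION_PAIRS = ("KR", "QE", "FY", "AS", "ML", "IV")

DEFAULT_MDA_LAYOUTS = (("FU",), ("ACC1", "FU"), ("FU", "ACC2"))

ACCESSORY_LEN = 60
FLANK_LEN = 5
N_LOBE_LEN = 100
C_LOBE_LEN = 170

DEFAULT_EC_MAP = {
    0: "2.7.11.1",
    1: "2.7.11.22",
    2: "2.7.10.1",
    3: "2.7.10.2",
    4: "2.7.12.1",
    5: "2.7.1.112",
}


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic superfamily."""

    n_families: int = 6
    seqs_per_family: tuple[int, int] = (18, 22)
    unit_length: int = N_LOBE_LEN + 10 + C_LOBE_LEN  # 280
    linker_length_range: tuple[int, int] = (10, 10)
    n_sdp_columns: int = 5
    n_separation_columns: int = 30
    within_family_mutation_rate: float = 0.05
    mda_layouts: tuple[tuple[str, ...], ...] = DEFAULT_MDA_LAYOUTS
    split_family_across_mdas: bool = False
    ec_map: Mapping[int, str] = field(default_factory=lambda: dict(DEFAULT_EC_MAP))
    unannotated_fraction: float = 0.1
    druggable_families: tuple[int, ...] = (0, 3)
    target_fraction: float = 0.6
    background_target_rate: float = 0.02
    decoy_hit_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (
            self.within_family_mutation_rate,
            self.unannotated_fraction,
            self.target_fraction,
            self.background_target_rate,
            self.decoy_hit_rate,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_sdp_columns < 0:
            raise ValueError("n_sdp_columns must be >= 0")
        lo, hi = self.linker_length_range
        if not 0 <= lo <= hi:
            raise ValueError("invalid linker length range")
        if self.unit_length <= N_LOBE_LEN + C_LOBE_LEN:
            raise ValueError("unit_length leaves no room for the linker")


@dataclass
class FixtureTruth:
    """Exact ground truth of a bundle."""

    family_by_seq: dict[str, int]
    mda_by_seq: dict[str, str]
    unit_span: dict[str, tuple[int, int]]  # 1-based (n_start, c_stop)
    sdp_unit_positions: dict[tuple[int, int], list[int]]  # 1-based unit coords
    separation_unit_positions: list[int]
    ec_by_family: dict[int, str]
    druggable_families: tuple[int, ...]


@dataclass
class FixtureBundle:
    sequences: list[ProteinSequence]
    domain_hits: list[DomainHit]
    annotations: pd.DataFrame  # seq_id, ec4, experimental
    drug_records: list[DrugRecord]
    truth: FixtureTruth


def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def _mutate(
    seq: list[str], rate: float, frozen: set[int], rng: np.random.Generator
) -> list[str]:
    """Substitute a fixed count (rate x mutable positions, rounded) of
    uniformly chosen non-frozen positions with a different residue."""
    out = list(seq)
    mutable = [i for i in range(len(seq)) if i not in frozen]
    k = round(rate * len(mutable))
    if k == 0:
        return out
    for i in rng.choice(mutable, size=k, replace=False):
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def _balanced_splits(n_families: int) -> list[frozenset[int]]:
    """All (n//2)-subsets of families that contain family 0: a balanced
    binary code over families. For 6 families this yields 10 splits with
    every family pair separated by exactly 6 of them."""
    from itertools import combinations

    half = max(1, n_families // 2)
    return [
        frozenset((0,) + rest)
        for rest in combinations(range(1, n_families), half - 1)
    ]


def generate_superfamily(config: FixtureConfig = FixtureConfig()) -> FixtureBundle:
    """Generate a superfamily bundle with planted family structure.

    Deterministic in ``config.seed``: the same config yields a byte-identical
    bundle.
    """
    rng = np.random.default_rng(config.seed)
    L = config.unit_length
    nf = config.n_families
    linker_len = int(rng.integers(config.linker_length_range[0], config.linker_length_range[1] + 1))
    n_len = N_LOBE_LEN
    c_len = L - n_len - linker_len

    root = list(_random_residues(rng, L))
    special = rng.choice(
        [i for i in range(L) if not (n_len <= i < n_len + linker_len)],
        size=config.n_sdp_columns + config.n_separation_columns,
        replace=False,
    )
    sdp_cols = sorted(int(i) for i in special[: config.n_sdp_columns])
    sep_cols = sorted(int(i) for i in special[config.n_sdp_columns :])

    # family-specific SDP residues: a permutation of the dissimilar set per
    # column so that all families differ pairwise at every SDP column
    sdp_residue: dict[tuple[int, int], str] = {}
    for c in sdp_cols:
        perm = rng.permutation(len(SDP_RESIDUES))
        for f in range(nf):
            sdp_residue[(f, c)] = SDP_RESIDUES[perm[f % len(SDP_RESIDUES)]]

    # separation columns: similar residue pair split over a balanced code,
    # so every family pair differs at a fixed, even share of these columns
    splits = _balanced_splits(nf)
    sep_residue: dict[tuple[int, int], str] = {}
    for k, c in enumerate(sep_cols):
        pair = SEPARATION_PAIRS[k % len(SEPARATION_PAIRS)]
        split = splits[k % len(splits)]
        for f in range(nf):
            sep_residue[(f, c)] = pair[0] if f in split else pair[1]

    family_consensus = []
    for f in range(nf):
        cons = list(root)
        for c in sdp_cols:
            cons[c] = sdp_residue[(f, c)]
        for c in sep_cols:
            cons[c] = sep_residue[(f, c)]
        family_consensus.append(cons)

    # accessory domain consensus sequences
    acc_names = sorted({tok for layout in config.mda_layouts for tok in layout if tok != "FU"})
    acc_consensus = {name: _random_residues(rng, ACCESSORY_LEN) for name in acc_names}

    sequences: list[ProteinSequence] = []
    hits: list[DomainHit] = []
    ann_rows = []
    family_by_seq: dict[str, int] = {}
    mda_by_seq: dict[str, str] = {}
    unit_span: dict[str, tuple[int, int]] = {}
    drug_rows: list[DrugRecord] = []
    ec_map = dict(config.ec_map)

    frozen = set(sdp_cols) | set(sep_cols)
    drug_serial = 0
    for f in range(nf):
        n_seqs = int(rng.integers(config.seqs_per_family[0], config.seqs_per_family[1] + 1))
        layout_idx = f % len(config.mda_layouts)
        for s in range(n_seqs):
            seq_id = f"F{f}S{s:03d}"
            if config.split_family_across_mdas and f == 0:
                layout = config.mda_layouts[s % 2]
            else:
                layout = config.mda_layouts[layout_idx]
            unit = _mutate(
                family_consensus[f], config.within_family_mutation_rate, frozen, rng
            )
            unit_str = "".join(unit)

            parts: list[str] = []
            seq_hits: list[tuple[str, int, int]] = []  # family, start, stop (1-based)
            pos = 0
            for tok in layout:
                if parts:
                    parts.append(_random_residues(rng, FLANK_LEN))
                    pos += FLANK_LEN
                if tok == "FU":
                    n_start = pos + 1
                    seq_hits.append((N_LOBE_FAMILY, n_start, pos + n_len))
                    seq_hits.append(
                        (C_LOBE_FAMILY, pos + n_len + linker_len + 1, pos + L)
                    )
                    parts.append(unit_str)
                    unit_span[seq_id] = (n_start, pos + L)
                    pos += L
                else:
                    acc = _mutate(
                        list(acc_consensus[tok]),
                        config.within_family_mutation_rate,
                        set(),
                        rng,
                    )
                    seq_hits.append((tok, pos + 1, pos + ACCESSORY_LEN))
                    parts.append("".join(acc))
                    pos += ACCESSORY_LEN
            residues = "".join(parts)
            sequences.append(ProteinSequence(id=seq_id, residues=residues))
            for fam, start, stop in seq_hits:
                score = round(1.5 * (stop - start + 1), 1)
                hits.append(DomainHit(seq_id, fam, start, stop, score))
            if rng.random() < config.decoy_hit_rate:
                # low-scoring decoy overlapping the N lobe; resolution must drop it
                n_start = unit_span[seq_id][0]
                hits.append(
                    DomainHit(
                        seq_id, "9.99.99.99", n_start + 10, n_start + 50, 15.0
                    )
                )
            family_by_seq[seq_id] = f
            mda_by_seq[seq_id] = "|".join(
                f"FU:{N_LOBE_FAMILY}-{C_LOBE_FAMILY}" if t == "FU" else t
                for t in layout
            )
            experimental = rng.random() >= config.unannotated_fraction
            ec = ec_map.get(f, f"2.7.99.{f + 1}")
            ann_rows.append((seq_id, ec, int(experimental)))

            is_target = False
            if f in config.druggable_families:
                is_target = rng.random() < config.target_fraction
            else:
                is_target = rng.random() < config.background_target_rate
            if is_target:
                drug_serial += 1
                drug_rows.append(
                    DrugRecord(
                        drug_id=f"CHEMBLD{f}{drug_serial:03d}",
                        target_seq_id=seq_id,
                        max_phase=4,
                        assay_type="B",
                        pchembl=round(6.0 + 2.0 * rng.random(), 2),
                        activity_nM=round(float(10 ** (3 * rng.random())), 1),
                        atc_code="L01E" + "AX"[drug_serial % 2] + "01",
                    )
                )
                if rng.random() < 0.3:
                    # a failing record for the same target (filter exercise)
                    drug_rows.append(
                        DrugRecord(
                            drug_id=f"CHEMBLX{drug_serial:03d}",
                            target_seq_id=seq_id,
                            max_phase=3,
                            assay_type="F",
                            pchembl=4.5,
                            activity_nM=2e6,
                            atc_code="N05BA01",
                        )
                    )

    sdp_positions: dict[tuple[int, int], list[int]] = {}
    for i in range(nf):
        for j in range(i + 1, nf):
            cols = [
                c + 1
                for c in sdp_cols
                if sdp_residue[(i, c)] != sdp_residue[(j, c)]
            ]
            sdp_positions[(i, j)] = cols

    truth = FixtureTruth(
        family_by_seq=family_by_seq,
        mda_by_seq=mda_by_seq,
        unit_span=unit_span,
        sdp_unit_positions=sdp_positions,
        separation_unit_positions=[c + 1 for c in sep_cols],
        ec_by_family={f: ec_map.get(f, f"2.7.99.{f + 1}") for f in range(nf)},
        druggable_families=config.druggable_families,
    )
    annotations = pd.DataFrame(ann_rows, columns=["seq_id", "ec4", "experimental"])
    return FixtureBundle(
        sequences=sequences,
        domain_hits=hits,
        annotations=annotations,
        drug_records=drug_rows,
        truth=truth,
    )


def shuffle_decoys(bundle: FixtureBundle, n: int, seed: int = 0) -> list[ProteinSequence]:
    """Length-matched decoys drawn i.i.d. from the bundle's empirical
    residue frequencies."""
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    rng = np.random.default_rng(seed)
    pool = "".join(s.residues for s in bundle.sequences)
    letters, counts = np.unique(list(pool), return_counts=True)
    freqs = counts / counts.sum()
    lengths = [len(s.residues) for s in bundle.sequences]
    out = []
    for i in range(n):
        length = lengths[int(rng.integers(len(lengths)))]
        out.append(
            ProteinSequence(
                id=f"DECOY{i:04d}",
                residues="".join(rng.choice(letters, size=length, p=freqs)),
            )
        )
    return out


def diverse_alignment(
    n_seqs: int = 20,
    ncols: int = 280,
    rate_range: tuple[float, float] = (0.05, 0.6),
    seed: int = 0,
) -> list[str]:
    """A gapless alignment whose per-column mutation rates are drawn
    continuously, giving a near-continuum of conservation values (high
    DOPs) — the 'diverse' end of the information-content spectrum."""
    rng = np.random.default_rng(seed)
    root = _random_residues(rng, ncols)
    rates = rng.uniform(rate_range[0], rate_range[1], size=ncols)
    rows = []
    for _ in range(n_seqs):
        row = list(root)
        mask = rng.random(ncols) < rates
        for i in np.where(mask)[0]:
            choices = [a for a in AMINO_ACIDS if a != row[i]]
            row[i] = choices[rng.integers(len(choices))]
        rows.append("".join(row))
    return rows
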