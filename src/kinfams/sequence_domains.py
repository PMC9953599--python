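"""Sequences, domain hits, non-overlapping architectures and functional units.

A protein of a two-lobe enzyme superfamily (the kinase superfamily being the
motivating case) is described by scored domain hits from an HMM-library scan.
This module resolves those hits into a maximum-score set of non-overlapping
domain annotations (exact weighted-interval scheduling), pairs N-lobe and
C-lobe hits into *functional units* — the concatenated two-lobe catalytic
region including a bounded hinge linker — and derives the protein's
multi-domain architecture (MDA) key, with each paired N+C lobe collapsed into
a single functional-unit token.

Coordinates are 1-based and inclusive throughout, as in residue ranges such
as "583-855". Intervals are closed: two hits overlap iff they share at least
one residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger("kinfams")

#: CATH superfamily of the kinase N-lobe (beta-rich small lobe).
N_LOBE_FAMILY = "3.30.200.20"
#: CATH superfamily of the kinase C-lobe (helical large lobe).
C_LOBE_FAMILY = "1.10.510.10"
#: Longest allowed hinge linker between the two lobes, in residues.
DEFAULT_LINKER_MAX = 20


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence: unique accession plus uppercase residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id}: residues must be non-empty")
        if not self.residues.isupper():
            raise ValueError(f"sequence {self.id}: residues must be uppercase")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class DomainHit:
    """A scored match of a domain superfamily to a sequence interval."""

    seq_id: str
    family_id: str
    start: int
    stop: int
    score: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.stop < self.start:
            raise ValueError(
                f"hit {self.seq_id}/{self.family_id}: invalid interval "
                f"{self.start}-{self.stop}"
            )
        if self.score < 0:
            raise ValueError(f"hit {self.seq_id}/{self.family_id}: negative score")

    def overlaps(self, other: "DomainHit") -> bool:
        return self.start <= other.stop and other.start <= self.stop

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


@dataclass
class ResolvedArchitecture:
    """A maximum-score, pairwise non-overlapping subset of a sequence's hits."""

    seq_id: str
    hits: list[DomainHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hits = sorted(self.hits, key=lambda h: (h.start, h.stop, h.family_id))
        for a, b in zip(self.hits, self.hits[1:]):
            if a.overlaps(b):
                raise ValueError(f"{self.seq_id}: overlapping hits in architecture")

    @property
    def total_score(self) -> float:
        return sum(h.score for h in self.hits)


@dataclass(frozen=True)
class FunctionalUnit:
    """Concatenated N-lobe + linker + C-lobe region of one sequence."""

    seq_id: str
    n_start: int
    n_stop: int
    c_start: int
    c_stop: int
    unit_seq: str = ""

    def __post_init__(self) -> None:
        if not self.n_stop < self.c_start:
            raise ValueError(f"{self.seq_id}: N-lobe must precede C-lobe")
        if self.unit_seq and len(self.unit_seq) != self.c_stop - self.n_start + 1:
            raise ValueError(f"{self.seq_id}: unit_seq length mismatch")

    @property
    def linker_len(self) -> int:
        return self.c_start - self.n_stop - 1

    @property
    def uid(self) -> str:
        """Unique id for the unit: one sequence may hold several units."""
        return f"{self.seq_id}/{self.n_start}-{self.c_stop}"


@dataclass(frozen=True)
class MDA:
    """Multi-domain architecture: ordered domain tokens along the sequence.

    Each paired N+C lobe appears as a single token
    ``FU:<n_family>-<c_family>`` positioned at the N-lobe start; all other
    resolved hits keep their own family id as token.
    """

    key: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.key:
            raise ValueError("MDA key must be non-empty")

    def __str__(self) -> str:
        return "|".join(self.key)

    @classmethod
    def from_string(cls, text: str) -> "MDA":
        return cls(tuple(text.split("|")))


def _solution_key(hits: Sequence[DomainHit]):
    """Ordering key: higher score, then more hits, then lexicographically
    smallest sorted (start, family_id) list. Larger key = preferred."""
    score = sum(h.score for h in hits)
    lex = sorted((h.start, h.family_id) for h in hits)
    return (score, len(hits), [(-s, _NegStr(f)) for s, f in lex])


class _NegStr(str):
    """String with reversed ordering, so that 'smaller lex wins' can be
    expressed inside a 'larger tuple wins' comparison."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def resolve_hits(
    hits: Iterable[DomainHit], seq_id: str | None = None
) -> ResolvedArchitecture:
    """Resolve scored domain hits into a non-overlapping architecture.

    Exact weighted-interval scheduling: returns the subset of ``hits``
    maximising the total score subject to pairwise non-overlap of the closed
    intervals. Ties are broken in favour of more hits, then of the
    lexicographically smallest sorted (start, family_id) list.

    All hits must share one ``seq_id``; an empty input yields an empty
    architecture (``seq_id`` may then be supplied explicitly).
    """
    hits = list(hits)
    if not hits:
        return ResolvedArchitecture(seq_id=seq_id or "", hits=[])
    ids = {h.seq_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"resolve_hits: mixed seq_ids {sorted(ids)}")
    if seq_id is not None and ids != {seq_id}:
        raise ValueError(f"resolve_hits: hits belong to {ids.pop()}, not {seq_id}")

    # DP over hits sorted by stop. best[i] = preferred solution using hits[:i].
    order = sorted(hits, key=lambda h: (h.stop, h.start, h.family_id, h.score))
    stops = [h.stop for h in order]
    import bisect

    best: list[list[DomainHit]] = [[]]
    for i, h in enumerate(order, start=1):
        # p = number of hits ending strictly before h.start (closed intervals:
        # compatible iff stop < start).
        p = bisect.bisect_left(stops, h.start, 0, i - 1)
        take = best[p] + [h]
        skip = best[i - 1]
        best.append(take if _solution_key(take) > _solution_key(skip) else skip)
    return ResolvedArchitecture(seq_id=order[0].seq_id, hits=best[-1])


def build_functional_units(
    arch: ResolvedArchitecture,
    n_family: str = N_LOBE_FAMILY,
    c_family: str = C_LOBE_FAMILY,
    linker_max: int = DEFAULT_LINKER_MAX,
    sequence: str | None = None,
) -> list[FunctionalUnit]:
    """Pair N-lobe hits with C-lobe hits into functional units.

    Scanning the resolved hits left to right, each ``n_family`` hit is paired
    with the immediately following hit when that hit (a) belongs to
    ``c_family``, (b) is not already paired, and (c) starts within
    ``linker_max`` residues of the N-lobe end. Intervening hits of any other
    family break the pairing, and lobes whose gap exceeds ``linker_max``
    stay unpaired (the sequence is then excluded from unit-level
    classification); both cases are logged. Each pairing yields one unit
    spanning N-lobe start to C-lobe stop, linker residues included.
    """
    if n_family == c_family:
        raise ValueError("n_family and c_family must differ")
    units: list[FunctionalUnit] = []
    hits = arch.hits
    paired: set[int] = set()
    for i, h in enumerate(hits):
        if h.family_id != n_family:
            continue
        if i + 1 >= len(hits):
            continue
        nxt = hits[i + 1]
        if nxt.family_id != c_family or (i + 1) in paired:
            continue
        gap = nxt.start - h.stop - 1
        if gap > linker_max:
            logger.info(
                "%s: lobes %d-%d / %d-%d unpaired (linker %d > %d)",
                arch.seq_id, h.start, h.stop, nxt.start, nxt.stop, gap, linker_max,
            )
            continue
        unit_seq = ""
        if sequence is not None:
            unit_seq = sequence[h.start - 1 : nxt.stop]
        paired.add(i)
        paired.add(i + 1)
        units.append(
            FunctionalUnit(
                seq_id=arch.seq_id,
                n_start=h.start,
                n_stop=h.stop,
                c_start=nxt.start,
                c_stop=nxt.stop,
                unit_seq=unit_seq,
            )
        )
    return units


def assign_mda(arch: ResolvedArchitecture, units: list[FunctionalUnit]) -> MDA:
    """Derive the MDA key from a resolved architecture and its units.

    Tokens are emitted in start order. The two lobes of each unit are
    replaced by one ``FU:`` token at the N-lobe start; every other hit keeps
    its family id. Unpaired lobes keep their own family token.
    """
    if not arch.hits:
        raise ValueError(f"{arch.seq_id}: no domains")
    unit_by_nstart = {u.n_start: u for u in units}
    consumed: set[tuple[int, int]] = set()
    for u in units:
        consumed.add((u.n_start, u.n_stop))
        consumed.add((u.c_start, u.c_stop))
    tokens: list[str] = []
    for h in arch.hits:
        u = unit_by_nstart.get(h.start)
        if u is not None and (h.start, h.stop) == (u.n_start, u.n_stop):
            # name the FU token from the lobe families of this architecture
            n_fam = h.family_id
            c_fam = next(
                x.family_id for x in arch.hits if (x.start, x.stop) == (u.c_start, u.c_stop)
            )
            tokens.append(f"FU:{n_fam}-{c_fam}")
        elif (h.start, h.stop) in consumed:
            continue  # C lobe of an emitted unit
        else:
            tokens.append(h.family_id)
    return MDA(tuple(tokens))
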