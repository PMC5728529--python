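"""Domain-architecture construction, the minimum mucin motif, and VWD extraction.

A protein's architecture is the ordered, non-overlapping sequence of its
domain elements (Pfam hits plus compositional PTS regions).  A protein is a
potential gel-forming mucin candidate when its architecture contains the
minimal cassette VWD-C8-TIL in N->C order; PTS elements are transparent to
the match but other domains block it (the cassette is read as contiguous).

VWD domains are additionally extracted and labelled D1..Dk by their rank
from the N-terminus, the labelling used downstream for positional phylogeny.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .formats_io import DomainHit, ProteinRecord
from .pts import PtsRegion

__all__ = [
    "ArchitectureElement",
    "Architecture",
    "LabeledVwd",
    "filter_hits",
    "resolve_overlaps",
    "build_architecture",
    "has_min_mucin_motif",
    "extract_vwd",
]

DEFAULT_EVALUE_MAX = 1e-3
DEFAULT_OVERLAP_TOL = 10

MIN_MUCIN_MOTIF = ("VWD", "C8", "TIL")


@dataclass(frozen=True)
class ArchitectureElement:
    name: str  # domain vocabulary entry or "PTS"
    start: int
    end: int


@dataclass(frozen=True)
class Architecture:
    """Ordered list of non-overlapping domain/PTS elements on one protein."""

    protein_id: str
    elements: tuple[ArchitectureElement, ...]

    def __post_init__(self) -> None:
        starts = [e.start for e in self.elements]
        if starts != sorted(starts):
            raise ValueError(f"{self.protein_id}: elements not sorted by start")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.elements)

    def render(self, group: bool = False, compact: bool = False) -> str:
        """Canonical string form, e.g. ``"VWD-C8-TIL-PTS"``.

        With ``group=True``, each cassette (a VWD followed by its trailing
        non-VWD, non-PTS domains) is parenthesised:
        ``"(VWD-C8-TIL)-PTS-(VWD-C8-TIL)"``.  With ``compact=True``,
        consecutive identical cassettes collapse to ``"3X(...)"``.
        Grouping is presentation only; equality of architectures is defined
        on the flat element sequence.
        """
        names = list(self.names)
        if not group:
            return "-".join(names)
        units: list[str] = []
        i = 0
        while i < len(names):
            if names[i] == "VWD":
                j = i + 1
                while j < len(names) and names[j] not in ("VWD", "PTS"):
                    j += 1
                block = names[i:j]
                units.append(
                    "(" + "-".join(block) + ")" if len(block) > 1 else block[0]
                )
                i = j
            else:
                units.append(names[i])
                i += 1
        if compact:
            collapsed: list[str] = []
            for unit, run in itertools.groupby(units):
                k = len(list(run))
                collapsed.append(f"{k}X{unit}" if k > 1 and unit.startswith("(") else
                                 "-".join([unit] * k))
            units = collapsed
        return "-".join(units)

    def __str__(self) -> str:
        return self.render()


@dataclass(frozen=True)
class LabeledVwd:
    """One VWD domain labelled by its N-terminal rank (D1, D2, ...)."""

    protein_id: str
    label: str
    start: int
    end: int
    sequence: str


def filter_hits(hits: list[DomainHit], evalue_max: float = DEFAULT_EVALUE_MAX) -> list[DomainHit]:
    """Keep hits whose independent E-value is at most ``evalue_max``."""
    if not evalue_max > 0:
        raise ValueError("evalue_max must be > 0")
    return [h for h in hits if h.i_evalue <= evalue_max]


def _overlap_span(s1: int, e1: int, s2: int, e2: int) -> int:
    """Coordinate overlap between two closed intervals (min end - max start).

    Positive when the intervals share more than one residue, zero when they
    share exactly one, negative when disjoint.  This is the measure the
    overlap tolerance is compared against.
    """
    return min(e1, e2) - max(s1, s2)


def resolve_overlaps(
    hits: list[DomainHit], overlap_tol: int = DEFAULT_OVERLAP_TOL
) -> list[DomainHit]:
    """Greedy non-overlapping hit selection for one protein.

    Hits are considered in ascending i-Evalue (ties: higher score, then
    smaller start); a hit is kept iff its coordinate overlap with every
    already-kept hit is at most ``overlap_tol``.  Result sorted by start.
    """
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(protein_ids)}")
    ordered = sorted(hits, key=lambda h: (h.i_evalue, -h.score, h.start))
    kept: list[DomainHit] = []
    for h in ordered:
        if all(
            _overlap_span(h.start, h.end, k.start, k.end) <= overlap_tol
            for k in kept
        ):
            kept.append(h)
    return sorted(kept, key=lambda h: h.start)


def build_architecture(
    resolved_hits: list[DomainHit],
    pts_regions: list[PtsRegion],
    protein_id: str | None = None,
    overlap_tol: int = DEFAULT_OVERLAP_TOL,
) -> Architecture:
    """Interleave resolved domain hits and PTS regions by start coordinate.

    A PTS region that overlaps a kept domain by more than ``overlap_tol``
    is truncated to the largest domain-free sub-interval; if nothing of at
    least one residue remains, it is dropped.
    """
    ids = {h.protein_id for h in resolved_hits} | {r.protein_id for r in pts_regions}
    if protein_id is not None:
        ids.add(protein_id)
    if len(ids) > 1:
        raise ValueError(f"inputs span multiple proteins: {sorted(ids)}")
    pid = protein_id if protein_id is not None else (next(iter(ids)) if ids else "")

    elements = [ArchitectureElement(h.family, h.start, h.end) for h in resolved_hits]
    for region in pts_regions:
        start, end = region.start, region.end
        for h in sorted(resolved_hits, key=lambda h: h.start):
            if _overlap_span(start, end, h.start, h.end) <= overlap_tol:
                continue
            # keep the larger domain-free flank
            left = (start, min(end, h.start - 1))
            right = (max(start, h.end + 1), end)
            left_len = left[1] - left[0] + 1
            right_len = right[1] - right[0] + 1
            start, end = left if left_len >= right_len else right
            if end < start:
                break
        if end >= start:
            elements.append(ArchitectureElement("PTS", start, end))
    elements.sort(key=lambda e: (e.start, e.end))
    return Architecture(protein_id=pid, elements=tuple(elements))


def has_min_mucin_motif(
    arch: Architecture, pts_transparent: bool = True
) -> bool:
    """True iff the architecture contains VWD, C8, TIL consecutively (N->C).

    With ``pts_transparent`` (default), interleaved PTS elements are ignored
    when reading the cassette; any other domain element breaks it.
    """
    names = [n for n in arch.names if not (pts_transparent and n == "PTS")]
    k = len(MIN_MUCIN_MOTIF)
    return any(
        tuple(names[i : i + k]) == MIN_MUCIN_MOTIF
        for i in range(len(names) - k + 1)
    )


def extract_vwd(arch: Architecture, protein: ProteinRecord) -> list[LabeledVwd]:
    """Extract VWD domain sequences labelled D1..Dk from the N-terminus."""
    if arch.protein_id != protein.id:
        raise ValueError(
            f"architecture is for {arch.protein_id!r}, protein is {protein.id!r}"
        )
    vwds = [e for e in arch.elements if e.name == "VWD"]
    out: list[LabeledVwd] = []
    for rank, e in enumerate(sorted(vwds, key=lambda e: e.start), start=1):
        if e.end > len(protein.sequence):
            raise ValueError(
                f"{protein.id}: VWD coordinates {e.start}..{e.end} exceed "
                f"sequence length {len(protein.sequence)}"
            )
        out.append(
            LabeledVwd(
                protein_id=protein.id,
                label=f"D{rank}",
                start=e.start,
                end=e.end,
                sequence=protein.sequence[e.start - 1 : e.end],
            )
        )
    return out
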