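"""The three-layer evidence funnel for gel-forming mucin candidates.

Candidate mucins must pass three independent evidence layers:

1. annotation — the genome annotation calls the gene a mucin
   (case-insensitive keyword match on the description line);
2. transcription — FPKM above a threshold in at least one tissue of an
   RNA-seq panel (genes at or below the threshold everywhere are treated
   as not expressed);
3. domain structure — the architecture contains the minimal VWD-C8-TIL
   cassette.

Stage counts are reported within the annotated universe (transcription and
motif counts are of annotated genes), so the funnel reads as a nested
narrowing: annotated -> annotated & transcribed / annotated & motif ->
all three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .architecture import Architecture, has_min_mucin_motif
from .formats_io import ExpressionMatrix, ProteinRecord

__all__ = ["FunnelConfig", "FunnelReport", "annotation_filter",
           "transcription_filter", "run_funnel"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FunnelConfig:
    annotation_keyword: str = "mucin"
    fpkm_threshold: float = 1.0
    require_motif: bool = True

    def __post_init__(self) -> None:
        if self.fpkm_threshold < 0:
            raise ValueError("fpkm_threshold must be >= 0")


@dataclass(frozen=True)
class FunnelReport:
    """Per-gene evidence flags and nested stage counts."""

    annotated: frozenset[str]
    transcribed: frozenset[str]  # within the annotated set
    has_motif: frozenset[str]    # within the annotated set
    candidates: tuple[str, ...]  # sorted, conjunction of the three layers

    @property
    def n_annotated(self) -> int:
        return len(self.annotated)

    @property
    def n_transcribed(self) -> int:
        return len(self.transcribed)

    @property
    def n_motif(self) -> int:
        return len(self.has_motif)

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n_annotated, self.n_transcribed, self.n_motif,
                self.n_candidates)

    def flags(self) -> dict[str, dict[str, bool]]:
        genes = self.annotated | self.transcribed | self.has_motif
        return {
            g: {
                "annotated": g in self.annotated,
                "transcribed": g in self.transcribed,
                "has_motif": g in self.has_motif,
                "candidate": g in self.candidates,
            }
            for g in sorted(genes)
        }


def annotation_filter(records: Iterable[ProteinRecord], keyword: str = "mucin") -> set[str]:
    """Ids whose description contains ``keyword`` (case-insensitive)."""
    kw = keyword.lower()
    return {r.id for r in records if kw in r.description.lower()}


def transcription_filter(matrix: ExpressionMatrix, threshold: float = 1.0,
                         genes: Iterable[str] | None = None) -> set[str]:
    """Ids transcribed above ``threshold`` FPKM in at least one tissue.

    When ``genes`` is given, only those ids are considered; ids absent from
    the matrix are treated as not transcribed (and logged).
    """
    universe = list(genes) if genes is not None else matrix.genes
    out: set[str] = set()
    for g in universe:
        if g not in matrix:
            logger.warning("gene %s absent from expression matrix; "
                           "treated as not transcribed", g)
            continue
        if matrix.max_fpkm(g) > threshold:
            out.add(g)
    return out


def run_funnel(
    records: list[ProteinRecord],
    matrix: ExpressionMatrix,
    architectures: Mapping[str, Architecture],
    config: FunnelConfig = FunnelConfig(),
) -> FunnelReport:
    """Apply the three evidence layers and intersect.

    ``architectures`` maps protein id to its built architecture; a protein
    without an entry has no domain evidence.
    """
    annotated = annotation_filter(records, config.annotation_keyword)
    transcribed_all = transcription_filter(
        matrix, config.fpkm_threshold, genes=[r.id for r in records]
    )
    motif_all = {
        pid for pid, arch in architectures.items() if has_min_mucin_motif(arch)
    }
    transcribed = annotated & transcribed_all
    motif = annotated & motif_all
    candidates = annotated & transcribed
    if config.require_motif:
        candidates &= motif
    return FunnelReport(
        annotated=frozenset(annotated),
        transcribed=frozenset(transcribed),
        has_motif=frozenset(motif),
        candidates=tuple(sorted(candidates)),
    )
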