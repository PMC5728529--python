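"""Synthetic data with known ground truth for every pipeline stage.

The generator mirrors the three evidence layers of the mucin funnel:
annotation (description keyword), transcription (FPKM panel over nine
tissues) and domain structure (planted architectures with VWD-C8-TIL
cassettes and PTS segments).  Decoy proteins violate exactly the layer
their mode names, so funnel recovery is exact by construction.  A qPCR
designer emulates the stress-experiment layout: groups of fish with known
log2 effects on target genes, technical duplicates, stable and unstable
reference genes, and per-primer dilution series.

Background sequence is drawn from a fixed amino-acid frequency table that
is deliberately poor in Ser/Thr/Pro (S+T well below the PTS threshold), so
no decoy can qualify as PTS by accident.  Planted PTS segments are drawn by
rejection sampling until every 100-residue window satisfies the detector's
compositional criterion; if sampling keeps failing, a fixed-composition
100-mer is tiled instead (every window of a period-100 sequence has
identical composition, so the per-window guarantee is exact).

All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import CtRecord, DomainHit, ExpressionMatrix, ProteinRecord
from .pts import PtsParams

__all__ = [
    "SimProteomeConfig",
    "SimProteinTruth",
    "SimTruth",
    "SimQpcrDesign",
    "MUC5B_TEMPLATE",
    "MUC2_TEMPLATE",
    "TISSUES",
    "simulate_proteome",
    "simulate_domain_hits",
    "simulate_expression",
    "simulate_qpcr",
    "simulate_funnel_population",
]

# Gel-forming mucin architecture templates.  The Muc5 form carries VWC after
# each N-terminal cassette; the Muc2 form is three bare cassettes, the PTS
# segment, and a C-terminal cassette.
MUC5B_TEMPLATE: tuple[str, ...] = (
    "VWD", "C8", "TIL", "VWC",
    "VWD", "C8", "TIL", "VWC",
    "VWD", "C8", "TIL", "VWC",
    "PTS",
    "VWD", "C8", "TIL",
)
MUC2_TEMPLATE: tuple[str, ...] = (
    "VWD", "C8", "TIL",
    "VWD", "C8", "TIL",
    "VWD", "C8", "TIL",
    "PTS",
    "VWD", "C8", "TIL",
)

#: The nine tissues of the RNA-seq expression panel.
TISSUES: tuple[str, ...] = (
    "pyloric_caeca", "foregut", "skin", "pancreas", "gill",
    "spleen", "liver", "heart", "brain",
)

DOMAIN_LENGTHS: Mapping[str, int] = {
    "VWD": 170, "C8": 70, "TIL": 60, "VWC": 50, "CTCK": 90,
    "Mucin2_WxxW": 25, "other": 80,
}
LINKER_LEN = 15

# Fixed background amino-acid frequencies, deliberately S/T/P-poor so that
# background segments can never satisfy the PTS window criterion.
_BACKGROUND_FREQS: Mapping[str, float] = {
    "A": 0.10, "C": 0.02, "D": 0.06, "E": 0.07, "F": 0.04, "G": 0.09,
    "H": 0.02, "I": 0.06, "K": 0.07, "L": 0.11, "M": 0.02, "N": 0.04,
    "P": 0.02, "Q": 0.04, "R": 0.06, "S": 0.02, "T": 0.02, "V": 0.08,
    "W": 0.01, "Y": 0.03, "X": 0.02,
}
_BG_RESIDUES = np.array(list(_BACKGROUND_FREQS))
_BG_P = np.array(list(_BACKGROUND_FREQS.values()))
_BG_P = _BG_P / _BG_P.sum()

DECOY_MODES = (
    "annotated_not_transcribed",
    "transcribed_no_motif",
    "motif_not_annotated",
    "shuffled_motif_order",
)

_MOTIF = ("VWD", "C8", "TIL")


def _template_has_motif(template: Sequence[str]) -> bool:
    names = [n for n in template if n != "PTS"]
    return any(
        tuple(names[i:i + 3]) == _MOTIF for i in range(len(names) - 2)
    )


@dataclass(frozen=True)
class SimProteomeConfig:
    """Layout of a synthetic proteome with planted mucins and decoys.

    ``pts_st_frac``/``pts_pro_frac`` set the target composition of planted
    PTS segments; they must clear the detector thresholds (S+T > 0.40,
    P >= 0.05) or the per-window planting guarantee is unsatisfiable.
    """

    n_proteins: int = 12
    n_true_mucins: int = 2
    architecture_templates: tuple[tuple[str, ...], ...] = (
        MUC5B_TEMPLATE, MUC2_TEMPLATE,
    )
    pts_length: int = 300
    pts_st_frac: float = 0.60
    pts_pro_frac: float = 0.10
    decoy_modes: frozenset[str] = frozenset(DECOY_MODES)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_true_mucins < 0:
            raise ValueError("counts must be positive")
        if self.n_true_mucins > self.n_proteins:
            raise ValueError("n_true_mucins cannot exceed n_proteins")
        if not (0 < self.pts_st_frac <= 1) or not (0 <= self.pts_pro_frac <= 1):
            raise ValueError("PTS fractions must be in (0, 1]")
        if self.pts_st_frac + self.pts_pro_frac > 1:
            raise ValueError("pts_st_frac + pts_pro_frac must be <= 1")
        default = PtsParams()
        if self.pts_st_frac <= default.st_min_frac or \
                self.pts_pro_frac < default.pro_min_frac:
            raise ValueError(
                "planted PTS composition must clear the detector thresholds "
                f"(S+T > {default.st_min_frac}, P >= {default.pro_min_frac})"
            )
        unknown = self.decoy_modes - set(DECOY_MODES)
        if unknown:
            raise ValueError(f"unknown decoy modes {sorted(unknown)}")
        if self.pts_length < 1:
            raise ValueError("pts_length must be >= 1")


@dataclass(frozen=True)
class SimProteinTruth:
    """Ground truth for one simulated protein."""

    protein_id: str
    role: str
    annotated: bool
    transcribed: bool
    has_motif: bool
    elements: tuple[tuple[str, int, int], ...]  # (name, start, end), 1-based
    pts_intervals: tuple[tuple[int, int], ...]

    @property
    def is_true_mucin(self) -> bool:
        return self.annotated and self.transcribed and self.has_motif


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for a whole simulated proteome."""

    proteins: tuple[SimProteinTruth, ...]

    def __iter__(self):
        return iter(self.proteins)

    def true_mucin_ids(self) -> set[str]:
        return {p.protein_id for p in self.proteins if p.is_true_mucin}

    def annotated_ids(self) -> set[str]:
        return {p.protein_id for p in self.proteins if p.annotated}

    def transcribed_ids(self) -> set[str]:
        return {p.protein_id for p in self.proteins if p.transcribed}

    def motif_ids(self) -> set[str]:
        return {p.protein_id for p in self.proteins if p.has_motif}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.proteins:
            rows.append(
                {
                    "protein_id": p.protein_id,
                    "role": p.role,
                    "annotated": p.annotated,
                    "transcribed": p.transcribed,
                    "has_motif": p.has_motif,
                    "is_true_mucin": p.is_true_mucin,
                    "architecture": "-".join(e[0] for e in p.elements),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sequence construction


def _background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BG_RESIDUES, size=n, p=_BG_P))


def _pts_windows_ok(seq: str, params: PtsParams) -> bool:
    """Check that every full window inside ``seq`` satisfies the criterion."""
    w = params.window
    if len(seq) < w:
        # guarantee is defined per full window; short segments are checked
        # on their whole length instead
        w = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    st = np.cumsum(np.concatenate([[0], (arr == ord("S")) | (arr == ord("T"))]))
    pp = np.cumsum(np.concatenate([[0], arr == ord("P")]))
    starts = np.arange(0, len(seq) - w + 1)
    st_cnt = st[starts + w] - st[starts]
    p_cnt = pp[starts + w] - pp[starts]
    return bool(
        ((st_cnt / w > params.st_min_frac) & (p_cnt / w >= params.pro_min_frac)).all()
    )


def _pts_segment(
    rng: np.random.Generator,
    length: int,
    st_frac: float,
    pro_frac: float,
    params: PtsParams = PtsParams(),
    max_tries: int = 50,
) -> str:
    """A PTS segment whose every window passes the detector criterion."""
    other = 1.0 - st_frac - pro_frac
    residues = np.array(["S", "T", "P", "A", "G", "V", "Q"])
    probs = np.array(
        [st_frac / 2, st_frac / 2, pro_frac,
         other * 0.4, other * 0.3, other * 0.2, other * 0.1]
    )
    probs = probs / probs.sum()
    for _ in range(max_tries):
        seq = "".join(rng.choice(residues, size=length, p=probs))
        if _pts_windows_ok(seq, params):
            return seq
    # deterministic fallback: tile a fixed-composition window; any window of
    # a period-w sequence has exactly this composition
    w = min(params.window, length)
    n_st = max(int(math.floor(st_frac * w)) + 1, int(params.st_min_frac * w) + 1)
    n_p = max(int(round(pro_frac * w)), int(math.ceil(params.pro_min_frac * w)))
    n_st = min(n_st, w - n_p)
    unit = list("S" * (n_st // 2) + "T" * (n_st - n_st // 2) + "P" * n_p
                + "A" * (w - n_st - n_p))
    rng.shuffle(unit)
    tiled = ("".join(unit) * (length // w + 1))[:length]
    return tiled


def _build_protein(
    pid: str,
    role: str,
    config: SimProteomeConfig,
    template: Sequence[str],
    rng: np.random.Generator,
) -> tuple[ProteinRecord, SimProteinTruth]:
    descriptions = {
        "true_mucin": "mucin-5-like gel-forming protein",
        "annotated_not_transcribed": "mucin-2-like protein",
        "transcribed_no_motif": "mucin-like protein, partial",
        "shuffled_motif_order": "mucin-related protein",
        "annotated_only": "mucin-like protein, fragment",
        "motif_not_annotated": "von Willebrand factor-like protein",
        "background": "hypothetical protein",
    }
    annotated = role not in ("motif_not_annotated", "background")
    transcribed = role in (
        "true_mucin", "transcribed_no_motif", "motif_not_annotated",
        "shuffled_motif_order",
    )
    parts: list[str] = [_background(rng, LINKER_LEN)]
    elements: list[tuple[str, int, int]] = []
    pts_intervals: list[tuple[int, int]] = []
    pos = LINKER_LEN
    for name in template:
        if name == "PTS":
            seg = _pts_segment(
                rng, config.pts_length, config.pts_st_frac, config.pts_pro_frac
            )
        else:
            seg = _background(rng, DOMAIN_LENGTHS[name])
        start, end = pos + 1, pos + len(seg)
        parts.append(seg)
        elements.append((name, start, end))
        if name == "PTS":
            pts_intervals.append((start, end))
        pos = end
        linker = _background(rng, LINKER_LEN)
        parts.append(linker)
        pos += LINKER_LEN
    sequence = "".join(parts)
    record = ProteinRecord(id=pid, description=descriptions[role], sequence=sequence)
    truth = SimProteinTruth(
        protein_id=pid,
        role=role,
        annotated=annotated,
        transcribed=transcribed,
        has_motif=_template_has_motif(template),
        elements=tuple(elements),
        pts_intervals=tuple(pts_intervals),
    )
    return record, truth


_DECOY_TEMPLATES: Mapping[str, tuple[str, ...]] = {
    # violates only transcription: full mucin architecture, annotated
    "annotated_not_transcribed": MUC2_TEMPLATE,
    # violates only the motif: VWD and TIL present but no C8 between them
    "transcribed_no_motif": ("VWD", "VWC", "TIL", "PTS"),
    # violates only annotation: full mucin architecture, non-mucin name
    "motif_not_annotated": MUC2_TEMPLATE,
    # violates only the motif: cassette domains in scrambled order
    "shuffled_motif_order": ("C8", "VWD", "TIL", "PTS"),
    # annotated but neither transcribed nor motif-bearing
    "annotated_only": ("VWD", "TIL"),
    "background": (),
}


def simulate_proteome(
    config: SimProteomeConfig,
) -> tuple[list[ProteinRecord], SimTruth]:
    """Generate a proteome of true mucins, targeted decoys and background.

    The first ``n_true_mucins`` proteins are true mucins cycling through
    ``architecture_templates``; the remainder cycle through the configured
    decoy modes plus plain background proteins.  Deterministic for a fixed
    seed.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    truths: list[SimProteinTruth] = []
    decoy_cycle = sorted(config.decoy_modes) + ["background"]
    for i in range(config.n_proteins):
        pid = f"sim{i + 1:04d}"
        if i < config.n_true_mucins:
            role = "true_mucin"
            template = config.architecture_templates[
                i % len(config.architecture_templates)
            ]
        else:
            role = decoy_cycle[(i - config.n_true_mucins) % len(decoy_cycle)]
            template = _DECOY_TEMPLATES[role]
        rec, truth = _build_protein(pid, role, config, template, rng)
        records.append(rec)
        truths.append(truth)
    return records, SimTruth(tuple(truths))


def simulate_funnel_population(
    n_annotated: int,
    n_transcribed: int,
    n_motif: int,
    n_candidates: int,
    n_unannotated: int = 0,
    seed: int = 0,
    config: SimProteomeConfig | None = None,
) -> tuple[list[ProteinRecord], SimTruth]:
    """A proteome with exact nested evidence counts.

    ``n_transcribed`` and ``n_motif`` are counted within the annotated set,
    matching how the funnel reports its stages, so the population contains
    ``n_candidates`` true mucins, ``n_transcribed - n_candidates`` annotated
    transcribed proteins without the motif, ``n_motif - n_candidates``
    annotated motif-bearing proteins that are not transcribed, and enough
    annotated proteins with neither to reach ``n_annotated``;
    ``n_unannotated`` motif-bearing, transcribed but unannotated decoys are
    appended.
    """
    n_t_only = n_transcribed - n_candidates
    n_m_only = n_motif - n_candidates
    n_neither = n_annotated - n_transcribed - n_m_only
    if min(n_candidates, n_t_only, n_m_only, n_neither, n_unannotated) < 0:
        raise ValueError("inconsistent nested funnel counts")
    if config is None:
        config = SimProteomeConfig(seed=seed)
    else:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    roles = (
        ["true_mucin"] * n_candidates
        + ["transcribed_no_motif"] * n_t_only
        + ["annotated_not_transcribed"] * n_m_only
        + ["annotated_only"] * n_neither
        + ["motif_not_annotated"] * n_unannotated
    )
    records, truths = [], []
    for i, role in enumerate(roles):
        pid = f"sim{i + 1:04d}"
        if role == "true_mucin":
            template = config.architecture_templates[
                i % len(config.architecture_templates)
            ]
        else:
            template = _DECOY_TEMPLATES[role]
        rec, truth = _build_protein(pid, role, config, template, rng)
        records.append(rec)
        truths.append(truth)
    return records, SimTruth(tuple(truths))


# ---------------------------------------------------------------------------
# Domain hits


def simulate_domain_hits(
    truth: SimTruth, fp_rate: float = 0.0, seed: int = 0
) -> list[DomainHit]:
    """Emit one confident hit per planted domain, plus optional decoy hits.

    Planted hits get i-Evalues far below the default threshold.  With
    ``fp_rate`` > 0, spurious hits are added on top of planted domains with
    the same span but clearly worse (yet still sub-threshold) E-values, so
    overlap resolution must discard them in favour of the planted hit.
    """
    if not 0.0 <= fp_rate < 1.0:
        raise ValueError("fp_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    hits: list[DomainHit] = []
    for protein in truth:
        for name, start, end in protein.elements:
            if name == "PTS":
                continue
            hits.append(
                DomainHit(
                    protein_id=protein.protein_id,
                    family=name,
                    start=start,
                    end=end,
                    i_evalue=float(10.0 ** -rng.uniform(8, 20)),
                    score=float(rng.uniform(50, 250)),
                )
            )
            if fp_rate > 0 and rng.random() < fp_rate:
                hits.append(
                    DomainHit(
                        protein_id=protein.protein_id,
                        family="other",
                        start=start,
                        end=end,
                        i_evalue=float(10.0 ** -rng.uniform(4, 6)),
                        score=float(rng.uniform(10, 40)),
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(truth: SimTruth, seed: int = 0) -> ExpressionMatrix:
    """FPKM matrix over the nine-tissue panel.

    Transcribed genes get 1-3 tissues with FPKM well above the
    transcription threshold; every other cell, and every cell of
    non-transcribed genes, stays at or below 1.
    """
    rng = np.random.default_rng(seed)
    data = {}
    for protein in truth:
        row = np.round(rng.uniform(0.0, 1.0, size=len(TISSUES)), 4)
        if protein.transcribed:
            k = int(rng.integers(1, 4))
            idx = rng.choice(len(TISSUES), size=k, replace=False)
            row[idx] = np.round(rng.uniform(5.0, 300.0, size=k), 4)
        data[protein.protein_id] = row
    frame = pd.DataFrame.from_dict(data, orient="index", columns=list(TISSUES))
    return ExpressionMatrix(frame)


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class SimQpcrDesign:
    """Layout of a simulated stress-response qPCR experiment.

    ``effects`` maps each non-control group to per-gene true log2 effects
    vs the control group (one log2 unit = one Ct cycle at doubling
    efficiency); unlisted genes have effect 0.  Reference genes never carry
    effects; their spread is set per gene via ``reference_drift_sd`` (a
    scalar, or a mapping for mixing stable and unstable candidates).
    """

    targets: tuple[str, ...] = ("muc5ac.1", "muc5b", "muc2.1/2")
    references: tuple[str, ...] = ("elf1a", "etif3")
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    control_group: str = "control"
    tissues: tuple[str, ...] = ("skin",)
    n_fish: int = 15
    duplicate_sd: float = 0.1
    biological_sd: float = 0.3
    reference_drift_sd: float | Mapping[str, float] = 0.05
    efficiency_true: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.references) < 1:
            raise ValueError("at least one reference gene required")
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        drift = self.reference_drift_sd
        drifts = list(drift.values()) if isinstance(drift, Mapping) else [drift]
        if any(s < 0 for s in [self.duplicate_sd, self.biological_sd, *drifts]):
            raise ValueError("standard deviations must be >= 0")
        if not (1.0 < self.efficiency_true <= 2.0):
            raise ValueError("efficiency_true must be in (1, 2]")
        ctrl = self.effects.get(self.control_group, {})
        if any(v != 0 for v in ctrl.values()):
            raise ValueError("control group effects must all be 0")

    @property
    def groups(self) -> tuple[str, ...]:
        extra = [g for g in self.effects if g != self.control_group]
        return (self.control_group, *sorted(extra))

    def drift_sd(self, gene: str) -> float:
        if isinstance(self.reference_drift_sd, Mapping):
            return float(self.reference_drift_sd.get(gene, 0.05))
        return float(self.reference_drift_sd)


def simulate_qpcr(
    design: SimQpcrDesign,
) -> tuple[list[CtRecord], pd.DataFrame]:
    """Long-format Ct table with technical duplicates, plus dilution series.

    Target Ct = gene baseline - group effect + N(0, biological_sd);
    reference Ct = gene baseline + N(0, drift sd); each well is measured
    twice with independent N(0, duplicate_sd) replicate noise.  The
    dilution-series table holds five noiseless points per gene at 1:2
    steps following Ct = a + b log10(conc) with b = -1/log10(E).
    """
    rng = np.random.default_rng(design.seed)
    genes = list(design.targets) + list(design.references)
    baseline = {}
    for g in design.targets:
        baseline[g] = float(rng.uniform(22, 28))
    for g in design.references:
        baseline[g] = float(rng.uniform(16, 20))

    records: list[CtRecord] = []
    for group in design.groups:
        group_effects = design.effects.get(group, {})
        for tissue in design.tissues:
            for fish in range(1, design.n_fish + 1):
                fish_id = f"{group}_f{fish:02d}"
                sample_id = f"{group}_{tissue}_f{fish:02d}"
                for gene in genes:
                    if gene in design.references:
                        true_ct = baseline[gene] + rng.normal(
                            0.0, design.drift_sd(gene)
                        )
                    else:
                        effect = float(group_effects.get(gene, 0.0))
                        true_ct = (
                            baseline[gene] - effect
                            + rng.normal(0.0, design.biological_sd)
                        )
                    for rep in (1, 2):
                        ct = true_ct + rng.normal(0.0, design.duplicate_sd)
                        records.append(
                            CtRecord(
                                sample_id=sample_id,
                                fish_id=fish_id,
                                tissue=tissue,
                                group=group,
                                gene=gene,
                                replicate=rep,
                                ct=float(max(ct, 1e-6)),
                            )
                        )

    slope = -1.0 / math.log10(design.efficiency_true)
    rows = []
    for gene in genes:
        for step in range(5):
            conc = 0.5 ** step
            rows.append(
                {
                    "gene": gene,
                    "concentration": conc,
                    "ct": baseline[gene] + slope * math.log10(conc),
                }
            )
    dilution = pd.DataFrame(rows)
    return records, dilution
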