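"""End-to-end orchestration: simulate -> identify -> phylogeny -> qPCR.

``run_all`` drives a complete, fully reproducible demonstration run on
synthetic data: it generates a proteome with planted mucins, writes every
intermediate in its standard on-disk format, re-reads them through the
format layer (so the run exercises the same code paths as a run on real
inputs), applies the evidence funnel, builds a bootstrap NJ tree of the
candidates' VWD domains, and runs the qPCR chain on a simulated stress
experiment.  Reruns with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import architecture as arch_mod
from . import formats_io as fio
from . import funnel as funnel_mod
from . import phylo as phylo_mod
from . import qpcr as qpcr_mod
from . import synthetic as sim
from .pts import PtsParams, scan_pts

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass(frozen=True)
class RunConfig:
    """All thresholds and sizes of one pipeline run."""

    outdir: Path
    seed: int = 0
    # synthetic proteome
    n_proteins: int = 12
    n_true_mucins: int = 3
    fp_rate: float = 0.3
    # thresholds
    pts_params: PtsParams = field(default_factory=PtsParams)
    evalue_max: float = arch_mod.DEFAULT_EVALUE_MAX
    overlap_tol: int = arch_mod.DEFAULT_OVERLAP_TOL
    fpkm_threshold: float = 1.0
    qc_limit: float = qpcr_mod.DEFAULT_QC_LIMIT
    bootstrap_b: int = 100
    # qPCR design
    qpcr_effects: dict = field(
        default_factory=lambda: {
            "stress_3h": {"muc5b": -1.4, "muc2.1/2": 0.9},
            "stress_24h": {"muc5b": -1.5, "muc2.1/2": 1.4},
        }
    )
    n_fish: int = 15


def run_all(config: RunConfig) -> dict:
    """Run every stage in dependency order; returns the summary manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage 1: simulate and write inputs
    proteome_cfg = sim.SimProteomeConfig(
        n_proteins=config.n_proteins,
        n_true_mucins=config.n_true_mucins,
        seed=config.seed,
    )
    records, truth = sim.simulate_proteome(proteome_cfg)
    hits = sim.simulate_domain_hits(truth, fp_rate=config.fp_rate,
                                    seed=config.seed + 1)
    matrix = sim.simulate_expression(truth, seed=config.seed + 2)
    fio.write_fasta(records, out / "proteome.fasta")
    fio.write_domtblout(hits, out / "domains.domtblout")
    fio.write_expression_tsv(matrix, out / "expression.tsv")
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)

    # -- stage 2: identify (read everything back through the format layer)
    records = fio.read_fasta(out / "proteome.fasta")
    hits = fio.parse_domtblout(out / "domains.domtblout")
    matrix = fio.read_expression_tsv(out / "expression.tsv")
    architectures = {}
    pts_rows = []
    for rec in records:
        own_hits = [h for h in hits if h.protein_id == rec.id]
        resolved = arch_mod.resolve_overlaps(
            arch_mod.filter_hits(own_hits, config.evalue_max),
            overlap_tol=config.overlap_tol,
        )
        regions = scan_pts(rec, config.pts_params)
        pts_rows += [
            f"{r.protein_id}\t{r.start}\t{r.end}\t{r.st_frac_max:.4f}\t"
            f"{r.pro_frac_max:.4f}" for r in regions
        ]
        architectures[rec.id] = arch_mod.build_architecture(
            resolved, regions, protein_id=rec.id, overlap_tol=config.overlap_tol
        )
    (out / "pts_regions.tsv").write_text(
        "protein_id\tstart\tend\tst_frac_max\tpro_frac_max\n"
        + "".join(line + "\n" for line in pts_rows)
    )
    funnel_cfg = funnel_mod.FunnelConfig(fpkm_threshold=config.fpkm_threshold)
    report = funnel_mod.run_funnel(records, matrix, architectures, funnel_cfg)
    with open(out / "funnel_report.tsv", "w") as fh:
        fh.write("gene\tannotated\ttranscribed\thas_motif\tcandidate\n")
        for gene, flags in report.flags().items():
            fh.write(
                f"{gene}\t{int(flags['annotated'])}\t{int(flags['transcribed'])}"
                f"\t{int(flags['has_motif'])}\t{int(flags['candidate'])}\n"
            )
    (out / "architectures.tsv").write_text(
        "protein_id\tarchitecture\n"
        + "".join(f"{pid}\t{a.render(group=True)}\n"
                  for pid, a in sorted(architectures.items()))
    )

    # -- stage 3: VWD phylogeny of candidates
    vwds = []
    by_id = {r.id: r for r in records}
    for pid in report.candidates:
        vwds += arch_mod.extract_vwd(architectures[pid], by_id[pid])
    tree_file = None
    if len(vwds) >= 3:
        aln = phylo_mod.DomainAlignment(
            ids=tuple(f"{v.protein_id}_{v.label}" for v in vwds),
            rows=tuple(v.sequence for v in vwds),
        )
        phylo_mod.write_alignment_fasta(aln, out / "vwd_domains.fasta")
        tree = phylo_mod.bootstrap_support(aln, B=config.bootstrap_b,
                                           seed=config.seed + 3)
        tree_file = out / "vwd_tree.nwk"
        phylo_mod.write_newick(tree, tree_file)
    else:
        logger.warning("fewer than 3 VWD domains among candidates; no tree")

    # -- stage 4: qPCR chain
    design = sim.SimQpcrDesign(
        effects=config.qpcr_effects,
        n_fish=config.n_fish,
        reference_drift_sd={"elf1a": 0.4, "etif3": 0.05},
        seed=config.seed + 4,
    )
    ct_records, dilution = sim.simulate_qpcr(design)
    fio.write_ct_table(ct_records, out / "ct_table.tsv")
    dilution.to_csv(out / "dilution_series.tsv", sep="\t", index=False)
    ct_records = fio.read_ct_table(out / "ct_table.tsv")
    collapsed, qc_log = qpcr_mod.collapse_duplicates(ct_records, config.qc_limit)
    efficiencies = {
        gene: qpcr_mod.efficiency_from_dilution(
            list(zip(grp["concentration"], grp["ct"]))
        )
        for gene, grp in dilution.groupby("gene")
    }
    stability = qpcr_mod.stability_ranking(
        collapsed[collapsed["gene"].isin(design.references)]
    )
    stability.to_csv(out / "reference_stability.tsv", sep="\t")
    best_ref = str(stability.index[0])
    dct = qpcr_mod.delta_ct(
        collapsed[collapsed["gene"].isin(list(design.targets) + [best_ref])],
        best_ref,
    )
    dct.to_csv(out / "delta_ct.tsv", sep="\t", index=False)
    qpcr_mod.tissue_profile_matrix(dct).to_csv(
        out / "tissue_profile.tsv", sep="\t"
    )
    effects = qpcr_mod.log2fc_vs_control(dct, design.control_group)
    qpcr_mod.effects_frame(effects).to_csv(
        out / "group_effects.tsv", sep="\t", index=False
    )
    (out / "qc_log.txt").write_text("".join(line + "\n" for line in qc_log))

    manifest = {
        "config": _jsonable(config),
        "funnel_counts": {
            "annotated": report.n_annotated,
            "transcribed": report.n_transcribed,
            "motif": report.n_motif,
            "candidates": report.n_candidates,
        },
        "candidates": list(report.candidates),
        "n_vwd_domains": len(vwds),
        "tree": str(tree_file) if tree_file else None,
        "efficiencies": {g: round(e, 3) for g, e in efficiencies.items()},
        "most_stable_reference": best_ref,
        "n_significant_effects": sum(e.significant for e in effects),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _jsonable(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["outdir"] = str(d["outdir"])
    return d
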