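"""Synthetic generators: determinism, planted ground truth, recoverability."""

import numpy as np
import pytest

from mucinscan.architecture import (
    build_architecture,
    filter_hits,
    has_min_mucin_motif,
    resolve_overlaps,
)
from mucinscan.formats_io import write_fasta
from mucinscan.pts import PtsParams, scan_pts
from mucinscan.qpcr import collapse_duplicates, delta_ct, log2fc_vs_control
from mucinscan.synthetic import (
    TISSUES,
    SimProteomeConfig,
    SimQpcrDesign,
    simulate_domain_hits,
    simulate_expression,
    simulate_funnel_population,
    simulate_proteome,
    simulate_qpcr,
)
from mucinscan.funnel import transcription_filter


class TestProteome:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        cfg = SimProteomeConfig(n_proteins=10, n_true_mucins=2, seed=1)
        for name in ("a.fasta", "b.fasta"):
            records, _ = simulate_proteome(cfg)
            write_fasta(records, tmp_path / name)
        assert (tmp_path / "a.fasta").read_bytes() == (
            tmp_path / "b.fasta"
        ).read_bytes()

    def test_planted_pts_recovered_by_detector(self):
        cfg = SimProteomeConfig(n_proteins=4, n_true_mucins=2,
                                pts_length=300, pts_st_frac=0.6,
                                pts_pro_frac=0.1, seed=7)
        records, truth = simulate_proteome(cfg)
        for rec, tr in zip(records, truth):
            for (start, end) in tr.pts_intervals:
                regions = scan_pts(rec, PtsParams())
                covering = [r for r in regions
                            if r.start <= start and r.end >= end]
                assert covering, f"{rec.id}: planted {start}..{end} not recovered"

    def test_background_composition_cannot_qualify_as_pts(self):
        cfg = SimProteomeConfig(n_proteins=8, n_true_mucins=0, seed=3)
        records, truth = simulate_proteome(cfg)
        for rec, tr in zip(records, truth):
            if not tr.pts_intervals:
                assert scan_pts(rec) == []

    def test_decoys_violate_exactly_their_named_layer(self, small_proteome):
        _, _, truth = small_proteome
        by_role = {}
        for tr in truth:
            by_role.setdefault(tr.role, tr)
        tr = by_role["annotated_not_transcribed"]
        assert tr.annotated and tr.has_motif and not tr.transcribed
        tr = by_role["transcribed_no_motif"]
        assert tr.annotated and tr.transcribed and not tr.has_motif
        tr = by_role["motif_not_annotated"]
        assert tr.transcribed and tr.has_motif and not tr.annotated
        tr = by_role["shuffled_motif_order"]
        assert tr.annotated and tr.transcribed and not tr.has_motif

    def test_shuffled_motif_decoy_fails_matcher_on_built_architecture(
        self, small_world
    ):
        records, truth, hits, _ = small_world
        shuffled = [t.protein_id for t in truth if t.role == "shuffled_motif_order"]
        for pid in shuffled:
            own = [h for h in hits if h.protein_id == pid]
            rec = [r for r in records if r.id == pid][0]
            arch = build_architecture(
                resolve_overlaps(filter_hits(own)), scan_pts(rec),
                protein_id=pid,
            )
            assert not has_min_mucin_motif(arch)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            SimProteomeConfig(n_proteins=2, n_true_mucins=3)
        with pytest.raises(ValueError, match="<= 1"):
            SimProteomeConfig(pts_st_frac=0.95, pts_pro_frac=0.10)
        with pytest.raises(ValueError, match="thresholds"):
            SimProteomeConfig(pts_st_frac=0.35)

    def test_funnel_population_counts(self):
        _, truth = simulate_funnel_population(20, 10, 6, 3, n_unannotated=2,
                                              seed=4)
        annotated = truth.annotated_ids()
        assert len(annotated) == 20
        assert len(annotated & truth.transcribed_ids()) == 10
        assert len(annotated & truth.motif_ids()) == 6
        assert len(truth.true_mucin_ids()) == 3


class TestDomainHits:
    def test_noiseless_hit_count_equals_planted_domains(self, small_proteome):
        _, _, truth = small_proteome
        hits = simulate_domain_hits(truth, fp_rate=0.0, seed=1)
        planted = sum(
            1 for tr in truth for name, _, _ in tr.elements if name != "PTS"
        )
        assert len(hits) == planted

    def test_overlap_resolution_strips_false_positives(self, small_proteome):
        _, _, truth = small_proteome
        clean = simulate_domain_hits(truth, fp_rate=0.0, seed=5)
        noisy = simulate_domain_hits(truth, fp_rate=0.5, seed=5)
        assert len(noisy) > len(clean)
        for tr in truth:
            own_noisy = [h for h in noisy if h.protein_id == tr.protein_id]
            resolved = resolve_overlaps(filter_hits(own_noisy))
            spans = [(h.family, h.start, h.end) for h in resolved]
            planted = [(n, s, e) for n, s, e in tr.elements if n != "PTS"]
            assert spans == planted

    def test_invalid_fp_rate_rejected(self, small_proteome):
        _, _, truth = small_proteome
        with pytest.raises(ValueError, match="fp_rate"):
            simulate_domain_hits(truth, fp_rate=1.0)


class TestExpression:
    def test_matrix_has_nine_tissue_panel(self, small_proteome):
        _, _, truth = small_proteome
        matrix = simulate_expression(truth, seed=2)
        assert len(matrix.tissues) == 9 and matrix.tissues == list(TISSUES)

    def test_non_transcribed_rows_stay_at_or_below_threshold(self, small_proteome):
        _, _, truth = small_proteome
        matrix = simulate_expression(truth, seed=2)
        for tr in truth:
            if not tr.transcribed:
                assert matrix.max_fpkm(tr.protein_id) <= 1.0

    def test_transcription_filter_recovers_planted_set(self, small_proteome):
        _, _, truth = small_proteome
        matrix = simulate_expression(truth, seed=2)
        assert transcription_filter(matrix, 1.0) == truth.transcribed_ids()


class TestQpcr:
    def test_zero_duplicate_sd_collapse_removes_nothing(self):
        design = SimQpcrDesign(duplicate_sd=0.0, n_fish=4, seed=1)
        records, _ = simulate_qpcr(design)
        collapsed, qc_log = collapse_duplicates(records)
        assert qc_log == []
        assert len(collapsed) == len(records) // 2

    def test_effect_recovery_within_tolerance(self):
        design = SimQpcrDesign(
            targets=("muc5b",), references=("etif3",),
            effects={"stress": {"muc5b": -1.5}},
            n_fish=15, biological_sd=0.05, duplicate_sd=0.02,
            reference_drift_sd=0.01, seed=11,
        )
        records, _ = simulate_qpcr(design)
        collapsed, _ = collapse_duplicates(records)
        dct = delta_ct(collapsed, "etif3")
        effects = {e.group: e for e in log2fc_vs_control(dct, "control")}
        assert effects["stress"].log2fc == pytest.approx(-1.5, abs=0.1)

    def test_effect_recovery_envelope(self):
        """Within the generator's guaranteed envelope (biological sd <= 0.2,
        n >= 12), injected log2 effects in {-2,-1,0,1,2} are recovered
        within +/-0.2 in >= 95% of 200 simulations."""
        from mucinscan.qpcr import log2fc_vs_control as fc

        effects = (-2.0, -1.0, 0.0, 1.0, 2.0)
        hits = 0
        for rep in range(40):
            for k, effect in enumerate(effects):
                design = SimQpcrDesign(
                    targets=("muc5b",), references=("etif3",),
                    effects={"stress": {"muc5b": effect}},
                    n_fish=12, duplicate_sd=0.05, biological_sd=0.2,
                    reference_drift_sd=0.02, seed=7_000 + rep * 5 + k,
                )
                records, _ = simulate_qpcr(design)
                collapsed, _ = collapse_duplicates(records)
                dct = delta_ct(collapsed, "etif3")
                est = {e.group: e for e in fc(dct, "control")}["stress"]
                hits += abs(est.log2fc - effect) <= 0.2
        assert hits / 200 >= 0.95

    def test_dilution_series_shape_and_recovery(self):
        from mucinscan.qpcr import efficiency_from_dilution

        design = SimQpcrDesign(efficiency_true=2.0, n_fish=2, seed=3)
        _, dilution = simulate_qpcr(design)
        for gene, grp in dilution.groupby("gene"):
            assert len(grp) == 5
            assert sorted(grp["concentration"]) == [
                0.0625, 0.125, 0.25, 0.5, 1.0
            ]
            e = efficiency_from_dilution(
                list(zip(grp["concentration"], grp["ct"]))
            )
            assert e == pytest.approx(2.0, abs=1e-9)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            SimQpcrDesign(efficiency_true=2.5)
        with pytest.raises(ValueError, match="control"):
            SimQpcrDesign(effects={"control": {"muc5b": 1.0}})
        with pytest.raises(ValueError, match=">= 0"):
            SimQpcrDesign(biological_sd=-0.1)
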