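"""qPCR chain: duplicate QC, efficiency, stability, delta-Ct, group effects."""

import math

import numpy as np
import pandas as pd
import pytest

from mucinscan.formats_io import CtRecord
from mucinscan.qpcr import (
    collapse_duplicates,
    delta_ct,
    effects_frame,
    efficiency_from_dilution,
    log2fc_vs_control,
    stability_ranking,
    tissue_profile_matrix,
)


def ct(sample, gene, rep, value, fish=None, tissue="skin", group="control"):
    return CtRecord(sample, fish or sample, tissue, group, gene, rep, value)


def collapsed_frame(rows):
    """rows: (sample_id, tissue, group, gene, ct)"""
    return pd.DataFrame(
        [
            {"sample_id": s, "fish_id": s, "tissue": t, "group": g,
             "gene": gene, "ct": v, "n_replicates": 2}
            for s, t, g, gene, v in rows
        ]
    )


class TestCollapseDuplicates:
    def test_close_pair_retained_with_mean(self):
        frame, log = collapse_duplicates(
            [ct("s1", "muc5b", 1, 24.0), ct("s1", "muc5b", 2, 24.2)]
        )
        assert len(frame) == 1 and frame.iloc[0]["ct"] == pytest.approx(24.1)
        assert log == []

    def test_divergent_pair_discarded_conventionally_retained_literally(self):
        records = [ct("s1", "muc5b", 1, 24.0), ct("s1", "muc5b", 2, 24.8)]
        conv, log_conv = collapse_duplicates(records, mode="conventional")
        assert conv.empty and len(log_conv) == 1
        lit, _ = collapse_duplicates(records, mode="literal")
        assert len(lit) == 1

    def test_singleton_passes_with_warning(self):
        frame, log = collapse_duplicates([ct("s1", "muc5b", 1, 24.0)])
        assert len(frame) == 1 and "singleton" in log[0]

    def test_more_than_two_replicates_rejected(self):
        records = [ct("s1", "muc5b", 1, 24.0), ct("s1", "muc5b", 2, 24.1)]
        records.append(ct("s1", "muc5b", 1, 24.2))
        with pytest.raises(ValueError, match="replicates"):
            collapse_duplicates(records)


class TestEfficiency:
    @pytest.mark.parametrize("efficiency", [1.8, 1.9, 2.0])
    def test_noiseless_series_recovered_exactly(self, efficiency):
        slope = -1.0 / math.log10(efficiency)
        series = [(0.5 ** k, 20.0 + slope * math.log10(0.5 ** k))
                  for k in range(5)]
        assert efficiency_from_dilution(series) == pytest.approx(
            efficiency, abs=5e-4
        )

    def test_perfect_doubling_gives_two(self):
        series = [(2.0 ** -k, 20.0 + k) for k in range(5)]
        assert efficiency_from_dilution(series) == pytest.approx(2.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            efficiency_from_dilution([(1.0, 20.0), (0.5, 21.0)])

    def test_increasing_ct_with_concentration_rejected(self):
        series = [(0.5 ** k, 20.0 - k) for k in range(5)]
        with pytest.raises(ValueError, match="slope"):
            efficiency_from_dilution(series)


class TestStability:
    def test_constant_offset_genes_have_zero_genorm(self):
        rows = []
        for i, base in enumerate([20.0, 21.5, 19.2, 22.0]):
            rows.append((f"s{i}", "skin", "control", "ref1", base))
            rows.append((f"s{i}", "skin", "control", "ref2", base + 3.0))
        result = stability_ranking(collapsed_frame(rows))
        assert (result["genorm_m"] == 0.0).all()
        assert (result["comparative_dct_stability"] == 0.0).all()

    def test_stable_gene_outranks_unstable_on_all_measures(self, rng):
        rows = []
        for i in range(20):
            rows.append((f"s{i}", "skin", "control", "stable",
                         20.0 + rng.normal(0, 0.1)))
            rows.append((f"s{i}", "skin", "control", "wobbly",
                         20.0 + rng.normal(0, 2.0)))
            rows.append((f"s{i}", "skin", "control", "middling",
                         20.0 + rng.normal(0, 0.5)))
        result = stability_ranking(collapsed_frame(rows))
        assert result.index[0] == "stable"
        for measure in ("genorm_m", "bestkeeper_sd",
                        "comparative_dct_stability", "normfinder_stability"):
            assert result.loc["stable", f"{measure}_rank"] == 1

    def test_sample_shift_invariance_of_pairwise_measures(self, rng):
        rows = [(f"s{i}", "skin", "control", g, 20.0 + rng.normal(0, 0.5))
                for i in range(10) for g in ("r1", "r2", "r3")]
        frame = collapsed_frame(rows)
        base = stability_ranking(frame)
        shifted = frame.copy()
        mask = shifted["sample_id"] == "s0"
        shifted.loc[mask, "ct"] += 2.5
        moved = stability_ranking(shifted)
        for measure in ("genorm_m", "comparative_dct_stability"):
            assert np.allclose(
                base[measure].sort_index(), moved[measure].sort_index()
            )

    def test_too_few_samples_rejected(self):
        rows = [("s0", "skin", "control", "r1", 20.0),
                ("s0", "skin", "control", "r2", 21.0)]
        with pytest.raises(ValueError, match="samples"):
            stability_ranking(collapsed_frame(rows))

    def test_single_gene_rejected(self):
        rows = [(f"s{i}", "skin", "control", "r1", 20.0) for i in range(5)]
        with pytest.raises(ValueError, match="2 candidate genes"):
            stability_ranking(collapsed_frame(rows))


class TestDeltaCt:
    def _frame(self):
        return collapsed_frame([
            ("s1", "skin", "control", "muc5b", 25.0),
            ("s1", "skin", "control", "etif3", 20.0),
            ("s2", "skin", "control", "muc5b", 26.0),
        ])

    def test_target_minus_reference(self):
        dct = delta_ct(self._frame(), "etif3")
        assert dct.iloc[0]["delta_ct"] == pytest.approx(5.0)

    def test_sample_missing_reference_is_dropped(self, caplog):
        dct = delta_ct(self._frame(), "etif3")
        assert list(dct["sample_id"]) == ["s1"]

    def test_reference_absent_entirely_is_error(self):
        with pytest.raises(ValueError, match="ghost"):
            delta_ct(self._frame(), "ghost")

    def test_target_equal_to_reference_gives_zero(self):
        frame = collapsed_frame([
            ("s1", "skin", "control", "muc5b", 20.0),
            ("s1", "skin", "control", "etif3", 20.0),
        ])
        assert delta_ct(frame, "etif3").iloc[0]["delta_ct"] == 0.0


class TestTissueProfile:
    def _dct(self):
        rows = []
        for i, v in enumerate([4.0, 5.0, 6.0]):
            rows.append({"sample_id": f"s{i}", "fish_id": f"f{i}",
                         "tissue": "skin", "group": "c", "gene": "muc5b",
                         "delta_ct": v})
        rows.append({"sample_id": "s9", "fish_id": "f9", "tissue": "gill",
                     "group": "c", "gene": "muc2", "delta_ct": 1.0})
        return pd.DataFrame(rows)

    def test_cell_is_negated_mean(self):
        m = tissue_profile_matrix(self._dct())
        assert m.loc["muc5b", "skin"] == pytest.approx(-5.0)

    def test_missing_combination_is_absent_not_zero(self):
        m = tissue_profile_matrix(self._dct())
        assert np.isnan(m.loc["muc2", "skin"])
        assert np.isnan(m.loc["muc5b", "gill"])

    def test_invariant_under_fish_reordering(self):
        dct = self._dct()
        shuffled = dct.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(
            tissue_profile_matrix(dct), tissue_profile_matrix(shuffled)
        )


def dct_frame(groups, gene="muc5b", tissue="skin"):
    """groups: mapping group -> list of delta-Ct values."""
    rows = []
    for group, values in groups.items():
        for i, v in enumerate(values):
            rows.append({"sample_id": f"{group}{i}", "fish_id": f"{group}{i}",
                         "tissue": tissue, "group": group, "gene": gene,
                         "delta_ct": float(v)})
    return pd.DataFrame(rows)


class TestLog2FcVsControl:
    def test_identical_groups_give_zero_effect_and_p_one(self):
        effects = log2fc_vs_control(
            dct_frame({"control": [5.0, 5.0, 5.0], "stress": [5.0, 5.0, 5.0]}),
            "control",
        )
        stress = [e for e in effects if e.group == "stress"][0]
        assert stress.log2fc == 0.0 and stress.p_value == 1.0

    def test_exact_shift_recovered_with_tiny_p(self):
        effects = log2fc_vs_control(
            dct_frame({"control": [5.0] * 15, "stress": [3.5] * 15}), "control"
        )
        stress = [e for e in effects if e.group == "stress"][0]
        assert stress.log2fc == pytest.approx(1.5)
        assert stress.p_value < 1e-6 and stress.significant

    def test_control_effect_is_exactly_zero(self):
        effects = log2fc_vs_control(
            dct_frame({"control": [5.1, 4.9, 5.0], "a": [4.0, 4.2, 4.1]}),
            "control",
        )
        ctrl = [e for e in effects if e.group == "control"][0]
        assert ctrl.log2fc == 0.0 and ctrl.p_value is None

    def test_singleton_group_reports_effect_without_p(self):
        effects = log2fc_vs_control(
            dct_frame({"control": [5.0, 5.2, 4.8], "solo": [3.0]}), "control"
        )
        solo = [e for e in effects if e.group == "solo"][0]
        assert solo.p_value is None and solo.log2fc == pytest.approx(2.0)

    def test_missing_control_or_single_group_rejected(self):
        with pytest.raises(ValueError, match="control"):
            log2fc_vs_control(dct_frame({"a": [1.0, 2.0]}), "control")
        with pytest.raises(ValueError, match="2 groups"):
            log2fc_vs_control(dct_frame({"control": [1.0, 2.0]}), "control")

    def test_matches_statsmodels_ols_treatment_coding(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        data = dct_frame(
            {
                "control": rng.normal(5.0, 0.4, 12),
                "h3": rng.normal(4.0, 0.4, 12),
                "h24": rng.normal(5.5, 0.4, 12),
            }
        )
        effects = {e.group: e for e in log2fc_vs_control(data, "control")}
        fit = smf.ols(
            "delta_ct ~ C(group, Treatment('control'))", data=data
        ).fit()
        for grp in ("h3", "h24"):
            name = f"C(group, Treatment('control'))[T.{grp}]"
            assert effects[grp].log2fc == pytest.approx(-fit.params[name])
            assert effects[grp].p_value == pytest.approx(fit.pvalues[name])
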