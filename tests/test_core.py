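import numpy as np
import pandas as pd
import pytest

from refstab.core import (
    CtMatrix,
    CtValidationError,
    GroupDesign,
    ReplicateSpreadWarning,
    aggregate_technical_replicates,
    filter_high_missing_genes,
    read_ct_table,
    to_quantities,
    write_ct_table,
)

from conftest import make_ct


class TestCtMatrixValidation:
    def test_duplicate_gene_ids_rejected(self):
        df = pd.DataFrame([[20.0, 21.0], [22.0, 23.0]], index=["ACT", "ACT"], columns=["s1", "s2"])
        with pytest.raises(CtValidationError, match="duplicate gene"):
            CtMatrix(df)

    def test_ct_outside_plausible_window_rejected(self):
        with pytest.raises(CtValidationError, match="outside plausible window"):
            make_ct([[20.0, 55.0]])

    def test_missing_values_allowed(self):
        ct = make_ct([[20.0, np.nan]])
        assert np.isnan(ct.values.iloc[0, 1])

    def test_annotations_must_cover_all_samples(self):
        df = pd.DataFrame([[20.0, 21.0]], index=["g"], columns=["s1", "s2"])
        ann = pd.DataFrame({"organ": ["leaf"]}, index=["s1"])
        with pytest.raises(CtValidationError, match="without annotation"):
            CtMatrix(df, ann)

    def test_select_by_annotation_level(self, small_ct):
        sub = small_ct.select(organ="leaf")
        assert sub.samples == ["s0", "s1", "s2"]
        assert sub.genes == small_ct.genes

    def test_select_empty_subset_errors(self, small_ct):
        with pytest.raises(ValueError, match="matched no samples"):
            small_ct.select(organ="root")


class TestIO:
    def test_long_layout_parsing(self, tmp_path):
        p = tmp_path / "ct.csv"
        p.write_text("gene,sample,ct\nACT,s1,20.0\nACT,s2,21.0\nTUB,s1,25.0\nTUB,s2,26.0\n")
        ct = read_ct_table(p, "long")
        assert ct.genes == ["ACT", "TUB"] and ct.samples == ["s1", "s2"]
        assert ct.values.at["TUB", "s2"] == 26.0
        assert not ct.values.isna().any().any()

    def test_undetermined_cell_becomes_missing_wide(self, tmp_path):
        p = tmp_path / "ct.csv"
        p.write_text("gene,s1,s2\nACT,20.0,Undetermined\nTUB,25.0,26.0\n")
        ct = read_ct_table(p, "wide")
        assert np.isnan(ct.values.at["ACT", "s2"])
        assert ct.values.at["TUB", "s2"] == 26.0

    def test_duplicate_cell_is_hard_error(self, tmp_path):
        p = tmp_path / "ct.csv"
        p.write_text("gene,sample,ct\nACT,s1,20.0\nACT,s1,20.5\n")
        with pytest.raises(CtValidationError, match="ACT.*s1"):
            read_ct_table(p, "long")

    def test_non_numeric_ct_is_hard_error(self, tmp_path):
        p = tmp_path / "ct.csv"
        p.write_text("gene,sample,ct\nACT,s1,20.0\nACT,s2,oops\n")
        with pytest.raises(CtValidationError, match="line 2"):
            read_ct_table(p, "long")

    def test_cq_header_accepted(self, tmp_path):
        p = tmp_path / "ct.csv"
        p.write_text("gene,sample,cq\nACT,s1,20.0\n")
        ct = read_ct_table(p, "long")
        assert ct.values.at["ACT", "s1"] == 20.0

    def test_long_annotations_inline(self, tmp_path):
        p = tmp_path / "ct.csv"
        p.write_text(
            "gene,sample,ct,organ,species\nACT,s1,20.0,leaf,RJ\nTUB,s1,25.0,leaf,RJ\n"
            "ACT,s2,21.0,flower,RS\nTUB,s2,24.0,flower,RS\n"
        )
        ct = read_ct_table(p, "long")
        assert ct.annotations.at["s2", "organ"] == "flower"
        assert ct.annotations.at["s1", "species"] == "RJ"

    @pytest.mark.parametrize("layout", ["long", "wide"])
    def test_round_trip_identity_study_sized(self, tmp_path, layout, preset_refs):
        """A 12-gene x 36-sample matrix survives write -> read exactly."""
        ct, _ = preset_refs
        p = tmp_path / f"rt_{layout}.csv"
        write_ct_table(ct, p, layout)
        back = read_ct_table(p, layout)
        pd.testing.assert_frame_equal(
            back.values, ct.values, check_exact=False, rtol=0, atol=1e-12
        )
        assert back.genes == ct.genes and back.samples == ct.samples
        if layout == "long":
            assert list(back.annotations["organ"]) == list(ct.annotations["organ"])


class TestReplicateAggregation:
    def _ct_with_reps(self, cts):
        n = len(cts)
        return make_ct(
            [cts],
            genes=["ACT"],
            samples=[f"r{i}" for i in range(n)],
            annotations={
                "organ": ["leaf"] * n,
                "species": ["RJ"] * n,
                "replicate": [1] * n,
            },
        )

    def test_triplicate_mean(self):
        ct = self._ct_with_reps([20.0, 20.2, 20.4])
        out = aggregate_technical_replicates(ct)
        assert out.n_samples == 1
        assert out.values.iloc[0, 0] == pytest.approx(20.2)

    def test_missing_replicate_excluded(self):
        ct = self._ct_with_reps([20.0, np.nan, 20.4])
        out = aggregate_technical_replicates(ct)
        assert out.values.iloc[0, 0] == pytest.approx(20.2)

    def test_wide_spread_warns_but_averages(self):
        ct = self._ct_with_reps([20.0, 20.0, 22.0])
        with pytest.warns(ReplicateSpreadWarning):
            out = aggregate_technical_replicates(ct)
        assert out.values.iloc[0, 0] == pytest.approx(20.0 + 2.0 / 3.0, abs=1e-9)

    def test_median_option(self):
        ct = self._ct_with_reps([20.0, 20.1, 23.0])
        with pytest.warns(ReplicateSpreadWarning):
            out = aggregate_technical_replicates(ct, method="median")
        assert out.values.iloc[0, 0] == pytest.approx(20.1)


class TestToQuantities:
    def test_powers_of_two(self):
        ct = make_ct([[20.0, 21.0, 23.0]])
        q = to_quantities(ct)
        assert list(q.values.iloc[0]) == pytest.approx([1.0, 0.5, 0.125])

    def test_empirical_base(self):
        ct = make_ct([[20.0, 21.0]])
        q = to_quantities(ct, 2.1)
        assert q.values.iloc[0, 1] == pytest.approx(1.0 / 2.1)

    def test_min_ct_sample_is_calibrator(self, preset_refs):
        ct, _ = preset_refs
        q = to_quantities(ct)
        assert np.allclose(q.values.max(axis=1), 1.0)

    def test_gene_constant_shift_leaves_q_unchanged(self, small_ct):
        q1 = to_quantities(small_ct)
        shifted = small_ct.copy()
        shifted.values.loc["stableA"] += 3.0
        q2 = to_quantities(shifted)
        pd.testing.assert_frame_equal(q1.values, q2.values)

    def test_single_sample_shift_scales_q_by_base_power(self):
        ct = make_ct([[20.0, 21.0, 23.0]])
        q1 = to_quantities(ct)
        ct2 = make_ct([[20.0, 22.0, 23.0]])  # +1 cycle on one sample
        q2 = to_quantities(ct2)
        assert q2.values.iloc[0, 1] == pytest.approx(q1.values.iloc[0, 1] * 2.0**-1)

    def test_all_missing_gene_errors(self):
        ct = make_ct([[20.0, 21.0], [np.nan, np.nan]], genes=["ok", "empty"])
        with pytest.raises(CtValidationError, match="empty"):
            to_quantities(ct)

    def test_bad_efficiency_rejected(self, small_ct):
        with pytest.raises(CtValidationError, match="efficiency"):
            to_quantities(small_ct, 2.5)

    def test_aggregate_then_transform_order(self):
        """Aggregation happens on the Ct scale before the transform."""
        ct = make_ct(
            [[20.0, 20.4, 25.0, 25.4]],
            genes=["ACT"],
            samples=["a1", "a2", "b1", "b2"],
            annotations={"organ": ["leaf"] * 4, "species": ["RJ"] * 4,
                         "replicate": [1, 1, 2, 2]},
        )
        agg = aggregate_technical_replicates(ct)
        q = to_quantities(agg)
        assert q.values.iloc[0, 1] == pytest.approx(2.0 ** (20.2 - 25.2))


class TestGroupDesignAndFiltering:
    def test_group_design_from_annotation(self, small_ct):
        d = GroupDesign.from_annotation(small_ct, "organ")
        assert d.labels() == ["flower", "leaf"]
        assert set(d.members("leaf")) == {"s0", "s1", "s2"}

    def test_small_group_fails_validation(self, small_ct):
        d = GroupDesign.from_annotation(small_ct, "species")
        with pytest.raises(CtValidationError, match="minimum size"):
            d.validate_for(small_ct, min_size=3)

    def test_high_missing_gene_flagged_and_dropped(self):
        vals = [[20.0, 21.0, 20.5, 21.5], [np.nan, np.nan, np.nan, 22.0]]
        ct = make_ct(vals, genes=["kept", "sparse"])
        with pytest.warns(UserWarning, match="sparse"):
            out, dropped = filter_high_missing_genes(ct)
        assert dropped == ["sparse"] and out.genes == ["kept"]
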