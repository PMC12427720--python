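import numpy as np
import pandas as pd
import pytest

from refstab.core import to_quantities
from refstab.delta_ct import pairwise_delta_sd
from refstab.genorm import (
    genorm_m,
    genorm_rank,
    normalization_factor,
    pairwise_variation,
)

from conftest import make_ct


def brute_force_m(q: pd.DataFrame, genes) -> pd.Series:
    """Independent reimplementation: M_j = mean_k SD(log2 Qj/Qk)."""
    out = {}
    for j in genes:
        sds = []
        for k in genes:
            if j == k:
                continue
            r = np.log2(q.loc[j] / q.loc[k]).to_numpy()
            sds.append(np.std(r, ddof=1))
        out[j] = np.mean(sds)
    return pd.Series(out)


def brute_force_trace(q, genes):
    """Re-run the exclusion loop independently; returns exclusion order."""
    remaining = list(genes)
    excluded = []
    while len(remaining) > 2:
        m = brute_force_m(q, remaining)
        worst = sorted(m.index[m == m.max()])[-1]
        remaining.remove(worst)
        excluded.append(worst)
    return remaining, excluded


@pytest.fixture
def random_q():
    rng = np.random.default_rng(11)
    vals = 21.0 + rng.normal(0, 0.8, size=(5, 10))
    return to_quantities(make_ct(vals, genes=list("ABCDE")))


class TestGenormM:
    def test_proportional_quantities_have_zero_m(self):
        ct = make_ct([[20.0, 22.0, 24.0], [21.0, 23.0, 25.0]])
        q = to_quantities(ct)
        m = genorm_m(q)
        assert np.allclose(m, 0.0, atol=1e-12)

    def test_two_gene_hand_computation(self):
        # Q rows (1, 0.5) and (1, 0.25): log2 ratios (0, 1), SD = 0.7071
        ct = make_ct([[20.0, 21.0], [20.0, 22.0]])
        q = to_quantities(ct)
        m = genorm_m(q)
        assert m.iloc[0] == pytest.approx(np.sqrt(0.5), abs=1e-9)
        assert m.iloc[1] == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_equals_delta_ct_sd_at_base_two(self, small_ct):
        """log2 of 2^-ΔCt ratios reduces to Ct differences, so each
        pairwise A_jk equals the ΔCt pairwise SD and M equals the ΔCt
        score."""
        q = to_quantities(small_ct)
        m = genorm_m(q)
        sd = pairwise_delta_sd(small_ct)
        arr = sd.to_numpy().astype(float)
        np.fill_diagonal(arr, np.nan)
        expected = np.nanmean(arr, axis=1)
        np.testing.assert_allclose(m.to_numpy(), expected, atol=1e-9)

    def test_matches_brute_force(self, random_q):
        m = genorm_m(random_q)
        expected = brute_force_m(random_q.values, random_q.genes)
        pd.testing.assert_series_equal(m, expected, atol=1e-12, rtol=0)

    def test_invariant_to_per_sample_scaling(self, random_q):
        m1 = genorm_m(random_q)
        scaled = random_q.values.copy()
        scaled["s3"] *= 7.3  # loading change in quantity space
        q2 = type(random_q)(scaled, random_q.efficiencies, random_q.annotations)
        m2 = genorm_m(q2)
        pd.testing.assert_series_equal(m1, m2, atol=1e-12, rtol=0)


class TestGenormRank:
    def test_noisy_gene_excluded_first(self):
        rng = np.random.default_rng(3)
        a = 20.0 + rng.normal(0, 0.05, 8)
        ct = make_ct([a, a + 2.0, 24.0 + rng.normal(0, 1.5, 8)],
                     genes=["A", "B", "C"])
        trace = genorm_rank(to_quantities(ct))
        assert trace.steps[0]["excluded"] == "C"
        assert trace.final_pair == ("A", "B")

    def test_final_pair_tied_at_rank_one_then_three(self, random_q):
        trace = genorm_rank(random_q)
        a, b = trace.final_pair
        assert trace.ranks[a] == trace.ranks[b] == 1
        assert trace.ranks[trace.ordering[2]] == 3
        assert trace.ranking_display()[0] == f"{a}|{b}"
        # the tied pair share an identical final M by construction
        assert trace.m_at_exclusion[a] == pytest.approx(trace.m_at_exclusion[b])

    def test_full_trace_matches_brute_force(self, random_q):
        trace = genorm_rank(random_q)
        pair, excluded = brute_force_trace(random_q.values, random_q.genes)
        assert trace.final_pair == tuple(sorted(pair))
        assert [s["excluded"] for s in trace.steps[:-1]] == excluded

    def test_mean_m_never_increases_along_trace(self, preset_refs):
        """Dropping the least stable gene should not worsen the mean
        stability of the remainder."""
        ct, _ = preset_refs
        trace = genorm_rank(to_quantities(ct))
        means = [s["m"].mean() for s in trace.steps]
        assert all(b <= a + 1e-12 for a, b in zip(means, means[1:]))

    def test_needs_three_genes(self):
        q = to_quantities(make_ct([[20.0, 21.0], [21.0, 22.0]]))
        with pytest.raises(ValueError, match="3 genes"):
            genorm_rank(q)


class TestNormalizationFactor:
    def test_single_gene_reduces_to_its_quantity(self, random_q):
        nf = normalization_factor(random_q, random_q.genes, 1)
        pd.testing.assert_series_equal(
            nf, random_q.values.loc[random_q.genes[0]],
            check_names=False, atol=1e-12, rtol=0,
        )

    def test_geometric_mean_of_two(self):
        ct = make_ct([[21.0, 20.0], [20.0, 21.0]])
        q = to_quantities(ct)  # sample quantities (0.5, 1) and (1, 0.5)
        nf = normalization_factor(q, ["g0", "g1"], 2)
        assert nf.iloc[0] == pytest.approx(np.sqrt(0.5))
        assert nf.iloc[1] == pytest.approx(np.sqrt(0.5))

    def test_three_gene_cube_roots(self):
        ct = make_ct([[20.0, 21.0, 22.0, 20.5],
                      [22.0, 22.0, 23.0, 24.0],
                      [25.0, 26.0, 25.0, 27.0]])
        q = to_quantities(ct)
        nf = normalization_factor(q, ["g0", "g1", "g2"], 3)
        expected = (q.values.iloc[0] * q.values.iloc[1] * q.values.iloc[2]) ** (1 / 3)
        np.testing.assert_allclose(nf.to_numpy(), expected.to_numpy(), atol=1e-12)

    def test_missing_gene_propagates_with_warning(self):
        ct = make_ct([[20.0, 21.0, 22.0], [22.0, np.nan, 23.0], [23.0, 24.0, 22.0]])
        q = to_quantities(ct)
        with pytest.warns(UserWarning, match="NF_2 missing"):
            nf = normalization_factor(q, ["g0", "g1"], 2)
        assert np.isnan(nf.iloc[1]) and not np.isnan(nf.iloc[0])


class TestPairwiseVariation:
    def brute_force_v(self, q, ordering):
        out = {}
        for n in range(2, len(ordering)):
            nf_n = np.exp(np.log(q.loc[ordering[:n]]).mean(axis=0))
            nf_n1 = np.exp(np.log(q.loc[ordering[: n + 1]]).mean(axis=0))
            out[n] = float(np.std(np.log2(nf_n / nf_n1), ddof=1))
        return out

    def test_proportional_extra_gene_gives_zero_v(self):
        rng = np.random.default_rng(9)
        a = 20.0 + rng.normal(0, 0.5, 6)
        ct = make_ct([a, a + 1.0, a + 2.0], genes=["A", "B", "C"])
        q = to_quantities(ct)
        trace = genorm_rank(q)
        v = pairwise_variation(q, trace)
        assert v["v"][2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_six_genes(self):
        rng = np.random.default_rng(21)
        vals = 22.0 + rng.normal(0, 0.7, size=(6, 9))
        q = to_quantities(make_ct(vals, genes=list("ABCDEF")))
        trace = genorm_rank(q)
        v = pairwise_variation(q, trace)
        expected = self.brute_force_v(q.values, trace.ordering)
        for n in expected:
            assert v["v"][n] == pytest.approx(expected[n], abs=1e-12)

    def test_decision_rule_straddling_threshold(self):
        """When V3/4 sits above the cutoff but V4/5 below it, four
        genes are deemed sufficient (first n with V < threshold).

        The ordering is imposed through a hand-built trace: the
        fourth-ranked gene deviates from the top three (keeping V3/4
        high) while the fifth adds essentially nothing.
        """
        from refstab.genorm import GenormTrace

        n = 12
        base = 21.0 + 0.1 * np.arange(n)
        dev1 = 0.8 * np.tile([1.0, -1.0], n // 2)  # alternating deviation
        dev2 = 0.8 * np.tile([1.0, 1.0, -1.0, -1.0], n // 4)  # orthogonal phase
        genes = [base, base + 1.0, base + 2.0 + dev1, base + 3.0 + dev2, base + 4.0]
        q = to_quantities(make_ct(genes, genes=list("ABCDE")))
        ordering = list("ABCDE")
        trace = GenormTrace(
            steps=[], final_pair=("A", "B"), ordering=ordering,
            ranks=pd.Series([1, 1, 3, 4, 5], index=ordering),
            m_at_exclusion=pd.Series(0.0, index=ordering),
        )
        v = pairwise_variation(q, trace, threshold=0.15)
        assert v["v"][2] >= 0.15 and v["v"][3] >= 0.15 > v["v"][4]
        assert v["n_sufficient"] == 4 and v["threshold_met"]

    def test_threshold_not_met_flag(self):
        rng = np.random.default_rng(8)
        vals = 22.0 + rng.normal(0, 2.0, size=(4, 8))
        q = to_quantities(make_ct(vals))
        trace = genorm_rank(q)
        v = pairwise_variation(q, trace, threshold=0.05)
        assert not v["threshold_met"]
        assert v["n_sufficient"] == min(v["v"], key=v["v"].get)
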