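import numpy as np
import pytest
from scipy import stats

from drugtarget_mr.io import GeneRegion, LDMatrix
from drugtarget_mr.simulate import simulate_eqtl_gwas_pair
from drugtarget_mr.smr import (CisDataset, heidi_select_snps, heidi_test,
                               mixture_chi2_tail, positive_control_filter,
                               run_smr, select_top_eqtl, smr_test)
from conftest import make_table


def cis_from_pair(scenario="shared_causal", seed=0, m=100, **kw):
    eqtl, gwas, truth, ld = simulate_eqtl_gwas_pair(
        m_snps=m, scenario=scenario, seed=seed, **kw)
    df = eqtl.df
    region = GeneRegion("GENE", "1", int(df["pos"].min()),
                        int(df["pos"].max()))
    return CisDataset("GENE", "tissue", eqtl, gwas, ld, region)


class TestSmrTest:
    def test_closed_form_example(self):
        # z1 = 4, z2 = 8 -> T = 16*64/80 = 12.8
        b, se, p = smr_test(0.02, 0.005, 0.4, 0.05)
        assert b == pytest.approx(0.05)
        assert se == pytest.approx(0.013975, abs=1e-6)
        assert p == pytest.approx(stats.chi2.sf(12.8, 1), rel=1e-12)
        assert p == pytest.approx(3.47e-4, abs=2e-6)

    def test_null_gwas(self):
        b, se, p = smr_test(0.0, 0.005, 0.4, 0.05)
        assert b == 0.0 and p == pytest.approx(1.0) and np.isinf(se)

    def test_strong_eqtl_limit_recovers_gwas_p(self):
        z1 = 3.0
        b, se, p = smr_test(z1 * 0.01, 0.01, 100.0, 0.001)  # z2 = 1e5
        assert p == pytest.approx(stats.chi2.sf(z1 ** 2, 1), rel=1e-4)

    def test_t_smr_bounded_by_component_chi2(self):
        for z1, z2 in [(2, 3), (5, 1), (4, 4)]:
            _, _, p = smr_test(z1 * 0.01, 0.01, z2 * 0.05, 0.05)
            t = stats.chi2.isf(p, 1)
            assert t <= min(z1 ** 2, z2 ** 2) + 1e-9

    def test_monotone_in_each_z(self):
        _, _, p_lo = smr_test(0.02, 0.01, 0.4, 0.05)
        _, _, p_hi = smr_test(0.03, 0.01, 0.4, 0.05)
        assert p_hi < p_lo

    def test_zero_eqtl_effect_is_error(self):
        with pytest.raises(ValueError):
            smr_test(0.02, 0.005, 0.0, 0.05)


class TestSelectTopEqtl:
    def _data(self, rows):
        eqtl = make_table(rows)
        gwas = make_table([{**r, "beta": 0.01} for r in rows],
                          trait_type="binary")
        ids = [r["snp_id"] for r in rows]
        ld = LDMatrix(ids, np.eye(len(ids)))
        region = GeneRegion("G", "1", 1, 10 ** 7)
        return CisDataset("G", "t", eqtl, gwas, ld, region)

    def test_smallest_p_wins(self):
        data = self._data([
            {"snp_id": "a", "beta": 0.5, "se": 0.05, "pval": 1e-12},
            {"snp_id": "b", "beta": 0.4, "se": 0.05, "pval": 1e-9},
        ])
        assert select_top_eqtl(data)["snp_id"] == "a"

    def test_maf_filter_excludes_rare(self):
        data = self._data([
            {"snp_id": "a", "beta": 0.5, "se": 0.05, "pval": 1e-12,
             "eaf": 0.005},
        ])
        with pytest.raises(ValueError, match="no significant cis-eQTL"):
            select_top_eqtl(data)

    def test_no_significant_snp_is_error(self):
        data = self._data([
            {"snp_id": "a", "beta": 0.1, "se": 0.05, "pval": 1e-3},
        ])
        with pytest.raises(ValueError, match="no significant cis-eQTL"):
            select_top_eqtl(data)


def test_positive_control_filter():
    assert positive_control_filter(["G1", "G2"],
                                   {"G1": 0.01, "G2": 0.2}) == ["G1"]
    assert positive_control_filter([], {}) == []
    assert positive_control_filter(["G1", "G2"],
                                   {"G1": [0.3, 0.01], "G2": 0.001},
                                   alpha=0.05) == ["G1", "G2"]


class TestHeidiSelect:
    def test_ld_window_and_truncation(self):
        data = cis_from_pair("shared_causal", seed=1, m=60)
        top = select_top_eqtl(data)["snp_id"]
        snps = heidi_select_snps(data, top, m_max=20)
        assert top not in snps
        assert len(snps) <= 20
        for s in snps:
            r2 = data.ld.r2_between(s, top)
            assert 0.05 <= r2 <= 0.9
            row = data.eqtl.df.set_index("snp_id").loc[s]
            assert row["pval"] < 1.57e-3

    def test_extreme_ld_excluded(self):
        # ar1(0.99): immediate neighbours exceed r2 = 0.9 and are excluded
        data = cis_from_pair("shared_causal", seed=1, m=21,
                             ld_model=("ar1", 0.99))
        top = select_top_eqtl(data)["snp_id"]
        snps = heidi_select_snps(data, top)
        ti = data.ld.index_of(top)
        for s in snps:
            assert abs(data.ld.index_of(s) - ti) > 1


class TestHeidiTest:
    def test_proportional_effects_give_p_one(self):
        """Exactly proportional eQTL/GWAS effects: every d_i = 0, T = 0."""
        ids = [f"s{i}" for i in range(5)]
        be = np.array([0.8, 0.6, 0.5, 0.4, 0.3])
        rows_e = [{"snp_id": s, "beta": b, "se": 0.05, "pval": 1e-10}
                  for s, b in zip(ids, be)]
        rows_g = [{"snp_id": s, "beta": 0.1 * b, "se": 0.01, "pval": 1e-10}
                  for s, b in zip(ids, be)]
        r = np.full((5, 5), 0.3)
        np.fill_diagonal(r, 1.0)
        data = CisDataset("G", "t", make_table(rows_e),
                          make_table(rows_g, trait_type="binary"),
                          LDMatrix(ids, r), GeneRegion("G", "1", 1, 10 ** 7))
        p, m = heidi_test(data, "s0", ids[1:], mc_draws=5000, seed=0)
        assert m == 4
        assert p == pytest.approx(1.0)

    def test_fewer_than_three_snps_withholds_p(self):
        data = cis_from_pair("shared_causal", seed=2, m=30)
        top = select_top_eqtl(data)["snp_id"]
        snps = heidi_select_snps(data, top, m_max=2)
        p, m = heidi_test(data, top, snps[:2], mc_draws=1000, seed=0)
        assert p is None and m == 2

    def test_relabeling_invariance(self):
        data = cis_from_pair("shared_causal", seed=3, m=40)
        top = select_top_eqtl(data)["snp_id"]
        snps = heidi_select_snps(data, top, m_max=8)
        p1, _ = heidi_test(data, top, snps, mc_draws=20_000, seed=5)
        p2, _ = heidi_test(data, top, snps[::-1], mc_draws=20_000, seed=5)
        assert p1 == pytest.approx(p2, abs=0.01)


def test_mixture_tail_matches_chi2_under_identity():
    """With unit eigenvalues the mixture is exactly chi-square(m)."""
    m, draws = 5, 100_000
    for t in (5.0, 10.0, 15.0):
        p_mc = mixture_chi2_tail(np.ones(m), t, mc_draws=draws, seed=11)
        p_exact = stats.chi2.sf(t, m)
        mc_se = np.sqrt(p_exact * (1 - p_exact) / draws)
        assert abs(p_mc - p_exact) < 3 * mc_se


class TestRunSmr:
    def test_shared_causal_detects_association(self):
        data = cis_from_pair("shared_causal", seed=4, n_gwas=100_000)
        res = run_smr(data, mc_draws=20_000, seed=4)
        # true expression->outcome effect is b_gwas/b_eqtl = 0.15/0.8
        assert res.p_smr < 1e-4
        assert res.b_smr == pytest.approx(0.1875, abs=0.08)
        assert res.p_heidi is not None and res.p_heidi > 0.01

    def test_linked_causal_flagged_by_heidi(self):
        data = cis_from_pair(("linked_causal", 0.4), seed=4, n_gwas=100_000)
        res = run_smr(data, mc_draws=20_000, seed=4)
        assert res.p_heidi is not None and res.p_heidi < 0.01
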