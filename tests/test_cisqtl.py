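"""Association engine: casewise OLS, permutation/Beta machinery, FDR, signals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm

from svmolqtl import (PhenotypeTable, SimConfig, association_single,
                      conditional_scan, fdr_and_thresholds, grouped_permutation,
                      map_molqtl, nominal_scan, permutation_pass,
                      simulate_genotypes, simulate_phenotypes)
from svmolqtl.cisqtl import fit_beta_minp, qvalues, scan_feature, covariate_matrix
from test_datamodel import _toy_matrix


def _sm_oracle(dose, y, cov):
    """Independent normal-equations fit on the complete-dosage subset."""
    ok = ~np.isnan(dose)
    X = sm.add_constant(np.column_stack([cov[ok], dose[ok]]) if cov is not None
                        else dose[ok])
    fit = sm.OLS(y[ok], X).fit()
    return fit.params[-1], fit.bse[-1], fit.pvalues[-1]


class TestCasewiseOls:
    def test_matches_statsmodels_on_toy_with_covariate(self):
        rng = np.random.default_rng(0)
        n = 8
        dose = np.array([0, 1, 2, 0, 1, 2, 1, 0], dtype=float)
        cov = rng.normal(size=(n, 1))
        y = 0.7 * dose + 0.4 * cov[:, 0] + rng.normal(size=n)
        st = association_single(dose, y, cov)
        b, se, p = _sm_oracle(dose, y, cov)
        assert st.n_used == 8
        assert st.beta == pytest.approx(b, rel=1e-10)
        assert st.se == pytest.approx(se, rel=1e-10)
        assert st.p == pytest.approx(p, rel=1e-8)

    def test_casewise_deletion_matches_subset_refit(self):
        rng = np.random.default_rng(1)
        n = 60
        dose = rng.integers(0, 3, n).astype(float)
        dose[[3, 17, 41]] = np.nan
        cov = rng.normal(size=(n, 2))
        y = 0.5 * np.nan_to_num(dose) + rng.normal(size=n)
        st = association_single(dose, y, cov)
        b, se, p = _sm_oracle(dose, y, cov)
        assert st.n_used == 57
        assert st.beta == pytest.approx(b, rel=1e-10)
        assert st.p == pytest.approx(p, rel=1e-8)

    def test_identical_dosage_and_missingness_gives_identical_stats(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, 50).astype(float)
        col[[5, 9]] = np.nan
        G = np.column_stack([col, col])
        y = rng.normal(size=50)
        C1 = covariate_matrix(None, 50)
        beta, se, p, n_used = scan_feature(G, y, C1)
        assert beta[0] == beta[1] and se[0] == se[1] and p[0] == p[1]
        assert n_used[0] == n_used[1] == 48

    def test_too_few_samples_after_deletion_is_skipped(self):
        dose = np.array([0, 1, 2, np.nan, np.nan, np.nan, np.nan, np.nan])
        y = np.arange(8.0)
        cov = np.arange(8.0)[:, None]
        st = association_single(dose, y, cov)
        assert st.n_used == 3 and np.isnan(st.p)


class TestMissingnessMechanism:
    """Perfect-LD pairs: p-values coincide iff missingness patterns do."""

    def test_equal_patterns_give_exactly_equal_p(self):
        rng = np.random.default_rng(3)
        dose = rng.integers(0, 3, 80).astype(float)
        a = dose.copy(); a[[2, 7]] = np.nan
        b = dose.copy(); b[[2, 7]] = np.nan
        y = 0.8 * dose + rng.normal(size=80)
        pa = association_single(a, y, None).p
        pb = association_single(b, y, None).p
        assert pa == pb

    def test_unequal_patterns_generally_differ(self):
        rng = np.random.default_rng(4)
        dose = rng.integers(0, 3, 80).astype(float)
        a = dose.copy(); a[[2]] = np.nan
        y = 0.8 * dose + rng.normal(size=80)
        pa = association_single(a, y, None).p
        pb = association_single(dose, y, None).p
        assert pa != pb


class TestPermutationPass:
    def test_single_null_variant_gives_uniform_adjusted_p(self):
        # one cis variant: the permutation minimum is the p itself, so the
        # Beta fit should be near Beta(1, 1) and adjusted p near-uniform
        rng = np.random.default_rng(5)
        n, m = 80, 60
        g = _toy_matrix(rng.integers(0, 3, size=(n, 1)).astype(float))
        feats = pd.DataFrame({"chrom": "1", "start": 50, "end": 60,
                              "pid": [f"f{i}" for i in range(m)],
                              "gid": [f"f{i}" for i in range(m)], "strand": "+"})
        phenos = PhenotypeTable(feats, rng.normal(size=(m, n)), g.samples)
        df = permutation_pass(g, phenos, n_perm=200, seed=1)
        assert len(df) == m
        adj = df["p_adjusted"].to_numpy()
        assert 0.35 < adj.mean() < 0.65
        assert stats.kstest(adj, "uniform").pvalue > 0.01

    def test_planted_effect_is_far_below_fdr_cutoff(self, mapped):
        perm, _, _ = mapped
        planted = perm[perm["feature"].str.startswith(("svgene", "gene"))]
        assert (planted["p_adjusted"] < 0.005).all()

    def test_beta_adjustment_tracks_brute_force_empirical_p(self):
        rng = np.random.default_rng(6)
        n = 60
        G = rng.integers(0, 3, size=(n, 5)).astype(float)
        g = _toy_matrix(G)
        y = 0.35 * G[:, 2] + rng.normal(size=n)
        feats = pd.DataFrame([{"chrom": "1", "start": 50, "end": 60,
                               "pid": "f", "gid": "f", "strand": "+"}])
        phenos = PhenotypeTable(feats, y[None, :], g.samples)
        df = permutation_pass(g, phenos, n_perm=1000, seed=2)
        p_adj = float(df["p_adjusted"].iloc[0])
        # brute force: 20k direct permutations of the phenotype
        C1 = covariate_matrix(None, n)
        _, _, p_obs, _ = scan_feature(G, y, C1)
        p0 = np.nanmin(p_obs)
        hits = 0
        B = 20_000
        rng2 = np.random.default_rng(7)
        for idx in np.argsort(rng2.random((B, n)), axis=1):
            _, _, pp, _ = scan_feature(G, y[idx], C1)
            hits += np.nanmin(pp) <= p0
        emp = (1 + hits) / (1 + B)
        assert 0.001 < emp < 0.5  # informative regime
        mc = np.sqrt(emp * (1 - emp) / 1000)
        assert abs(p_adj - emp) < 2 * mc

    def test_beta_mle_recovers_known_shapes(self):
        rng = np.random.default_rng(8)
        x = stats.beta.rvs(1.2, 8.0, size=4000, random_state=rng)
        a, b, conv = fit_beta_minp(x)
        assert conv
        assert a == pytest.approx(1.2, rel=0.1)
        assert b == pytest.approx(8.0, rel=0.1)


class TestGroupedPermutation:
    def _phenos(self, rows, gids, samples):
        feats = pd.DataFrame({"chrom": "1", "start": 50, "end": 60,
                              "pid": [f"p{i}" for i in range(len(gids))],
                              "gid": gids, "strand": "+"})
        return PhenotypeTable(feats, np.asarray(rows), samples)

    def test_group_of_one_reduces_to_ungrouped_pass(self):
        rng = np.random.default_rng(9)
        n = 60
        g = _toy_matrix(rng.integers(0, 3, size=(n, 6)).astype(float))
        y = 0.5 * g.dosages[:, 1] + rng.normal(size=n)
        phenos = self._phenos(y[None, :], ["gene"], g.samples)
        single = permutation_pass(g, phenos, n_perm=200, seed=3)
        grouped = grouped_permutation(g, phenos, n_perm=200, seed=3)
        assert grouped["p_adjusted"].iloc[0] == pytest.approx(
            single["p_adjusted"].iloc[0], rel=1e-12)
        assert grouped["best_variant"].iloc[0] == single["best_variant"].iloc[0]

    def test_identical_members_match_single_member_within_mc_error(self):
        rng = np.random.default_rng(10)
        n = 60
        g = _toy_matrix(rng.integers(0, 3, size=(n, 6)).astype(float))
        y = 0.5 * g.dosages[:, 1] + rng.normal(size=n)
        one = grouped_permutation(g, self._phenos(y[None, :], ["gene"], g.samples),
                                  n_perm=400, seed=4)
        three = grouped_permutation(
            g, self._phenos(np.tile(y, (3, 1)), ["gene"] * 3, g.samples),
            n_perm=400, seed=4)
        # perfect dependence between members: the group minimum equals the
        # single-member minimum in every permutation
        assert three["p_nominal"].iloc[0] == one["p_nominal"].iloc[0]
        assert three["empirical_p"].iloc[0] == one["empirical_p"].iloc[0]

    def test_independent_null_members_min_p_is_stochastically_smaller(self):
        rng = np.random.default_rng(11)
        n = 60
        g = _toy_matrix(rng.integers(0, 3, size=(n, 4)).astype(float))
        rows = rng.normal(size=(2, n))
        grouped = grouped_permutation(g, self._phenos(rows, ["g", "g"], g.samples),
                                      n_perm=200, seed=5)
        singles = permutation_pass(g, self._phenos(rows, ["a", "b"], g.samples),
                                   n_perm=200, seed=5)
        assert grouped["p_nominal"].iloc[0] <= singles["p_nominal"].min()
        assert 0.0 <= grouped["p_adjusted"].iloc[0] <= 1.0


class TestFdrAndThresholds:
    def _stub(self, p_adj):
        return pd.DataFrame({
            "feature": [f"f{i}" for i in range(len(p_adj))],
            "gid": [f"f{i}" for i in range(len(p_adj))],
            "p_adjusted": p_adj,
            "beta_alpha": 1.0, "beta_beta": 30.0, "beta_converged": True,
        })

    def test_bh_step_up_matches_hand_computation(self):
        # m = 4 forces the BH fallback; step-up at 5% rejects the first three
        df = fdr_and_thresholds(self._stub([0.01, 0.02, 0.03, 0.2]))
        assert df["significant"].tolist() == [True, True, True, False]
        q, _ = qvalues(np.array([0.01, 0.02, 0.03, 0.2]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.2])

    def test_all_adjusted_p_one_yields_no_calls(self):
        df = fdr_and_thresholds(self._stub([1.0, 1.0, 1.0]))
        assert not df["significant"].any()
        assert df["threshold"].isna().all()

    def test_threshold_inverts_beta_cdf_at_the_cutoff(self):
        df = fdr_and_thresholds(self._stub([0.001, 0.004, 0.3, 0.6]))
        cutoff = (0.004 + 0.3) / 2
        sig = df[df["significant"]]
        back = stats.beta.cdf(sig["threshold"], sig["beta_alpha"], sig["beta_beta"])
        assert np.allclose(back, cutoff, atol=1e-10)

    def test_empty_input_gives_empty_output(self):
        out = fdr_and_thresholds(pd.DataFrame(columns=["feature", "p_adjusted",
                                                       "beta_alpha", "beta_beta"]))
        assert out.empty


class TestConditionalScan:
    def test_two_unlinked_planted_variants_give_two_signals(self):
        cfg = SimConfig(n_samples=200, n_blocks=1, variants_per_block=20,
                        maf_range=(0.2, 0.5), sv_fraction=0.0, ld_rho=0.0,
                        missingness_rate_small=0.0, seed=17)
        g, truth = simulate_genotypes(cfg)
        # pick two essentially uncorrelated variants
        from svmolqtl.datamodel import r2_pairwise
        ids = list(g.variants["id"])
        va, vb = None, None
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                r2, _ = r2_pairwise(g.dosages[:, i], g.dosages[:, j])
                if r2 < 0.01:
                    va, vb = ids[i], ids[j]
                    break
            if va:
                break
        y = (1.2 * g.dosage_of(va) + 1.2 * g.dosage_of(vb)
             + np.random.default_rng(18).normal(size=200))
        truth.causal_map["f"] = (va, 1.2)
        phenos, _ = simulate_phenotypes(g, truth, cfg)
        phenos.values[0] = stats.norm.ppf(
            (stats.rankdata(y) - 0.5) / len(y))
        perm, signals = map_molqtl(g, phenos, None, n_perm=300, seed=19)
        f_signals = [s for s in signals if s.feature == "f"]
        assert len(f_signals) == 2
        leads = {s.lead for s in f_signals}
        for lead in leads:
            assert (r2_pairwise(g.dosage_of(lead), g.dosage_of(va))[0] > 0.8
                    or r2_pairwise(g.dosage_of(lead), g.dosage_of(vb))[0] > 0.8)

    def test_single_planted_variant_lead_is_in_high_ld_with_truth(self, cohort, mapped):
        from svmolqtl.datamodel import r2_pairwise
        _, signals, _ = mapped
        recovered = 0
        planted = {f: v for f, (v, _) in cohort.truth.causal_map.items()}
        rank0 = {s.feature: s for s in signals if s.rank == 0}
        for fid, vid in planted.items():
            s = rank0.get(fid)
            if s is None:
                continue
            r2, _ = r2_pairwise(cohort.genotypes_clean.dosage_of(s.lead),
                                cohort.genotypes_clean.dosage_of(vid))
            recovered += r2 > 0.8
        assert recovered >= len(planted) - 1

    def test_no_variant_below_threshold_yields_zero_signals(self):
        rng = np.random.default_rng(20)
        g = _toy_matrix(rng.integers(0, 3, size=(40, 5)).astype(float))
        feats = pd.DataFrame([{"chrom": "1", "start": 50, "end": 60,
                               "pid": "f", "gid": "f", "strand": "+"}])
        phenos = PhenotypeTable(feats, rng.normal(size=(1, 40)), g.samples)
        fdr_df = pd.DataFrame([{"feature": "f", "gid": "f", "p_adjusted": 0.001,
                                "q": 0.001, "significant": True,
                                "threshold": 1e-12}])
        assert conditional_scan(g, phenos, None, fdr_df) == []


class TestNominalScan:
    def test_null_scan_p_values_are_roughly_uniform(self):
        rng = np.random.default_rng(21)
        g = _toy_matrix(rng.integers(0, 3, size=(100, 30)).astype(float))
        feats = pd.DataFrame([{"chrom": "1", "start": 1500, "end": 1600,
                               "pid": "f", "gid": "f", "strand": "+"}])
        phenos = PhenotypeTable(feats, rng.normal(size=(1, 100)), g.samples)
        out = nominal_scan(g, phenos)
        assert len(out) == 30
        assert out["p"].between(0, 1).all()
        assert abs(out["beta"].mean()) < 0.1
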