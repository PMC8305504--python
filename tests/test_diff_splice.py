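"""Per-bin mixed models: recovery, degenerate rows, BH oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

from psipath import SimConfig, simulate_cohort, fdr_adjust
from psipath.diff_splice import fit_bin_lmm, fit_group_lmm
from psipath.psi import compute_psi_array
from oracles import brute_force_bh


@pytest.fixture(scope="module")
def cohort_meta():
    return simulate_cohort(SimConfig(seed=9)).meta


def simulate_row(meta, rng, base=0.5, loc_delta=0.0, individual_sd=0.2,
                 coverage=170.0, name="bin"):
    """Observed-PSI row under the generative model (binomial at NB coverage)."""
    inds = sorted(meta["individual_id"].unique())
    codes = meta["individual_id"].map({k: i for i, k in enumerate(inds)}).to_numpy()
    u = rng.normal(0, individual_sd, len(inds))
    mu = base + loc_delta * (meta["location"] == "rectum").to_numpy(float)
    p = np.clip(expit(logit(np.clip(mu, 0.001, 0.999)) + u[codes]), 0.001, 0.999)
    cov = rng.negative_binomial(5, 5 / (5 + coverage), len(p))
    ir = rng.binomial(cov, p)
    psi = compute_psi_array(ir, cov - ir)
    psi = np.where(np.isnan(psi), np.clip(mu, 0.001, 0.999), psi)  # keep row complete
    return pd.Series(psi, index=meta.index, name=name)


class TestFitBinLmm:
    def test_recovers_planted_location_effect(self, cohort_meta, rng):
        ests = []
        for i in range(10):
            row = simulate_row(
                cohort_meta, rng, base=0.35, loc_delta=0.30,
                individual_sd=0.02, coverage=1000.0, name=f"b{i}",
            )
            res = fit_bin_lmm(row, cohort_meta)
            ests.append(res.estimate("location"))
        assert abs(np.mean(ests) - 0.30) < 0.05

    def test_constant_row_degenerate(self, cohort_meta):
        row = pd.Series(0.5, index=cohort_meta.index, name="const")
        res = fit_bin_lmm(row, cohort_meta)
        assert (res.results["pvalue"] == 1.0).all()
        assert (res.results["estimate"] == 0.0).all()
        assert res.fallback

    def test_missing_values_rejected(self, cohort_meta):
        row = pd.Series(0.5, index=cohort_meta.index, name="m")
        row.iloc[0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_bin_lmm(row, cohort_meta)

    def test_zero_individual_variance_falls_back_to_ols(self, cohort_meta, rng):
        row = simulate_row(cohort_meta, rng, individual_sd=0.0, name="f")
        res = fit_bin_lmm(row, cohort_meta)
        assert res.fallback  # boundary fit flagged, never silently dropped
        assert np.isfinite(res.results["pvalue"]).all()

    def test_power_monotone_in_effect_size(self, cohort_meta):
        rng = np.random.default_rng(7)
        power = []
        for delta in (0.05, 0.15, 0.30):
            ps = [
                fit_bin_lmm(
                    simulate_row(cohort_meta, rng, base=0.3, loc_delta=delta,
                                 name=f"d{delta}_{i}"),
                    cohort_meta,
                    terms=("location",),
                ).pvalue("location")
                for i in range(25)
            ]
            power.append(np.mean(np.array(ps) < 0.05))
        assert power[0] <= power[1] <= power[2]
        assert power[2] > 0.9

    def test_estimates_correlate_with_planted_deltas(self, cohort_meta):
        # across 200 bins with varying planted dPSI at default coverage,
        # estimated location effects track the truth
        rng = np.random.default_rng(42)
        deltas = rng.uniform(-0.3, 0.3, size=200)
        ests = [
            fit_bin_lmm(
                simulate_row(cohort_meta, rng, base=0.5, loc_delta=d, name=f"e{i}"),
                cohort_meta, terms=("location",),
            ).estimate("location")
            for i, d in enumerate(deltas)
        ]
        assert np.corrcoef(deltas, ests)[0, 1] > 0.9

    def test_wald_and_lrt_agree_on_strong_effect(self, cohort_meta, rng):
        row = simulate_row(cohort_meta, rng, base=0.3, loc_delta=0.3, name="w")
        p_lrt = fit_bin_lmm(row, cohort_meta, test="lrt").pvalue("location")
        p_wald = fit_bin_lmm(row, cohort_meta, test="wald").pvalue("location")
        assert p_lrt < 1e-6 and p_wald < 1e-6


@pytest.fixture(scope="module")
def spliceo_cohort():
    return simulate_cohort(SimConfig(seed=17))


class TestGroupModel:

    def test_planted_spliceopathy_bin_contrasts(self, spliceo_cohort):
        c = spliceo_cohort
        bin_id = c.truth.spliceopathy_bins[0]
        row = c.truth.sample_psi.loc[bin_id]
        res = fit_group_lmm(row, c.meta)
        # spliceopathy samples carry the rectal PSI: far from ileum, near rectum
        assert res.pvalue("spliceopathy_vs_ileum") < 0.01
        assert abs(res.estimate("spliceopathy_vs_rectum")) < abs(
            res.estimate("spliceopathy_vs_ileum")
        )

    def test_non_spliceopathy_bin_contrast_near_zero(self, spliceo_cohort):
        c = spliceo_cohort
        neutral = [
            b for b in c.var_bin_ids
            if b not in set(c.truth.location_effect_bins)
            and b not in set(c.truth.ancestry_effect_bins)
        ][0]
        res = fit_group_lmm(c.truth.sample_psi.loc[neutral], c.meta)
        assert abs(res.estimate("spliceopathy_vs_ileum")) < 0.1

    def test_constant_across_groups_gives_p_one(self, spliceo_cohort):
        row = pd.Series(0.4, index=spliceo_cohort.meta.index, name="c")
        res = fit_group_lmm(row, spliceo_cohort.meta)
        assert res.pvalue("group") == 1.0

    def test_requires_spliceopathy_group(self, cohort_meta):
        meta = cohort_meta.copy()
        meta["group_label"] = "differentiated"
        row = pd.Series(0.4, index=meta.index, name="c")
        with pytest.raises(ValueError, match="spliceopathy"):
            fit_group_lmm(row, meta)


class TestFdr:
    def test_hand_computed_example(self):
        reject, adj = fdr_adjust([0.001, 0.02, 0.9], q=0.05)
        np.testing.assert_allclose(adj, [0.003, 0.03, 0.9])
        assert reject.tolist() == [True, True, False]

    def test_all_ones_nothing_significant(self):
        reject, _ = fdr_adjust([1.0] * 5)
        assert not reject.any()

    def test_single_pvalue(self):
        reject, adj = fdr_adjust([0.04], q=0.05)
        assert reject.tolist() == [True] and adj[0] == pytest.approx(0.04)

    @given(
        pvals=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60),
        q=st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_matches_brute_force_step_up(self, pvals, q):
        reject, adj = fdr_adjust(pvals, q=q)
        want_reject, want_adj = brute_force_bh(pvals, q)
        assert reject.tolist() == want_reject.tolist()
        np.testing.assert_allclose(adj, want_adj, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, np.nan])
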