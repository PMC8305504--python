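"""Outlier detection and characterization of tissue-discordant samples."""

import numpy as np
import pandas as pd
import pytest

from psipath import (
    SimConfig,
    classify_on_sites,
    delta_psi_profile,
    detect_discordant_samples,
    heatmap_cluster,
    quantify_cohort,
    rectal_like_sites,
    simulate_cohort,
    strict_cascade,
)
from psipath.outliers import select_top_location_bins


@pytest.fixture(scope="module")
def spliceo_run():
    c = simulate_cohort(SimConfig(seed=23))
    matrix, _ = quantify_cohort(c)
    filtered, _ = strict_cascade(matrix)
    return c, filtered


class TestDeltaPsiProfile:
    def test_identical_groups_mass_in_first_class(self):
        m = pd.DataFrame(
            np.tile([[0.2], [0.5], [0.9]], (1, 4)),
            index=["b1", "b2", "b3"],
            columns=["a1", "a2", "b1s", "b2s"],
        )
        prof = delta_psi_profile(m, ["a1", "a2"], ["b1s", "b2s"])
        assert prof.proportions[0] == 1.0

    def test_exact_boundary_goes_to_upper_class(self):
        m = pd.DataFrame({"a": [0.50], "b": [0.55]}, index=["b1"])
        prof = delta_psi_profile(m, ["a"], ["b"])
        assert prof.proportions[0] == 0.0
        assert prof.proportions[1] == 1.0  # [0.05, 0.10)

    def test_planted_fraction_lands_above_threshold(self):
        cfg = SimConfig(
            seed=5, n_bins=200, frac_location_bins=0.30, location_delta_psi=0.20,
            frac_ancestry_bins=0.0, ancestry_delta_psi=0.0, individual_sd=0.05,
            n_spliceopathy_individuals=0, frac_spliceopathy_bins=0.0,
        )
        c = simulate_cohort(cfg)
        m, _ = quantify_cohort(c, variable_only=True)
        m = m.dropna()
        il = c.meta.index[c.meta.location == "ileum"].tolist()
        re_ = c.meta.index[c.meta.location == "rectum"].tolist()
        prof = delta_psi_profile(m, il, re_)
        # ~30% of bins carry |dPSI| 0.2 -> mass at/above the 0.15 class
        assert prof.mass_at_or_above(0.15) == pytest.approx(0.30, abs=0.07)

    def test_spliceopathy_profile_dominates_replicate_split(self, spliceo_run):
        c, filtered = spliceo_run
        meta = c.meta
        il = meta.index[
            (meta.location == "ileum") & (meta.group_label != "spliceopathy")
        ].tolist()
        spl = c.truth.spliceopathy_samples
        prof_spl = delta_psi_profile(filtered, spl, il)
        half = len(il) // 2
        prof_split = delta_psi_profile(filtered, il[:half], il[half:])
        assert prof_spl.mass_at_or_above(0.05) > prof_split.mass_at_or_above(0.05)


class TestDetection:
    def test_planted_outliers_flagged_nothing_else(self, spliceo_run):
        c, filtered = spliceo_run
        calls = detect_discordant_samples(filtered, c.meta)
        flagged = set(calls.index[calls["flagged"]])
        assert flagged == set(c.truth.spliceopathy_samples)

    def test_no_planted_outliers_no_flags(self):
        cfg = SimConfig(seed=29, n_bins=150, n_spliceopathy_individuals=0,
                        frac_spliceopathy_bins=0.0)
        c = simulate_cohort(cfg)
        m, _ = quantify_cohort(c)
        f, _ = strict_cascade(m)
        calls = detect_discordant_samples(f, c.meta)
        assert calls["flagged"].sum() == 0

    def test_score_boundary_not_flagged_under_strict_inequality(self, small_meta, rng):
        m = pd.DataFrame(
            rng.normal(0.5, 0.02, size=(40, len(small_meta))).clip(0, 1),
            index=[f"G1:E{i:03d}" for i in range(40)],
            columns=small_meta.index,
        )
        calls = detect_discordant_samples(m, small_meta, threshold=np.inf)
        assert not calls["flagged"].any()

    def test_small_location_errors(self, small_meta, rng):
        meta = small_meta.iloc[:4].copy()  # 2 per tissue < 3
        m = pd.DataFrame(
            rng.uniform(size=(10, 4)), columns=meta.index,
            index=[f"G1:E{i:03d}" for i in range(10)],
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            detect_discordant_samples(m, meta)


class TestRectalLikeSites:
    def test_intersection_semantics(self):
        assert rectal_like_sites({"x", "y", "z"}, {"y", "z", "w"}) == {"y", "z"}
        assert rectal_like_sites({"a"}, {"b"}) == set()
        assert rectal_like_sites({"a"}, {"a", "b"}) == {"a"}


class TestClassifyOnSites:
    def test_outliers_assigned_to_rectum_on_discordant_sites(self, spliceo_run):
        c, filtered = spliceo_run
        sites = [b for b in c.truth.spliceopathy_bins if b in filtered.index]
        assert len(sites) >= 2
        assign = classify_on_sites(
            filtered.loc[sites], c.meta, spliceo_ids=c.truth.spliceopathy_samples
        )
        for sid in c.truth.spliceopathy_samples:
            assert assign[sid] == "rectum"

    def test_differentiated_samples_assigned_own_tissue(self, spliceo_run):
        c, filtered = spliceo_run
        sites = [b for b in c.truth.location_effect_bins if b in filtered.index]
        assign = classify_on_sites(
            filtered.loc[sites], c.meta, spliceo_ids=c.truth.spliceopathy_samples
        )
        normal = c.meta.index[c.meta.group_label != "spliceopathy"]
        acc = (assign[normal] == c.meta.loc[normal, "location"]).mean()
        assert acc >= 0.95

    def test_empty_site_set_rejected(self, spliceo_run):
        c, filtered = spliceo_run
        with pytest.raises(ValueError, match="empty"):
            classify_on_sites(filtered.iloc[:0], c.meta)


class TestHeatmapCluster:
    def test_top_split_is_tissue_split(self, spliceo_run):
        from scipy.cluster.hierarchy import fcluster

        c, filtered = spliceo_run
        bins = [b for b in c.truth.location_effect_bins if b in filtered.index]
        cl = heatmap_cluster(filtered, bins)
        two = fcluster(cl.col_linkage, 2, criterion="maxclust")
        cols = sorted(filtered.columns)
        grouping = pd.Series(two, index=cols)
        normal = [s for s in cols if s not in set(c.truth.spliceopathy_samples)]
        loc = c.meta.loc[normal, "location"]
        # cluster identity agrees with tissue for the differentiated samples
        majority = grouping[normal].groupby(loc).agg(lambda x: x.mode()[0])
        assert majority["ileum"] != majority["rectum"]
        acc = np.mean(
            [grouping[s] == majority[loc[s]] for s in normal]
        )
        assert acc >= 0.95

    def test_duplicate_samples_merge_at_height_zero(self, small_meta, rng):
        vals = rng.uniform(size=(12, len(small_meta)))
        vals[:, 1] = vals[:, 0]
        m = pd.DataFrame(
            vals, index=[f"G1:E{i:03d}" for i in range(12)], columns=small_meta.index
        )
        cl = heatmap_cluster(m, list(m.index))
        assert np.isclose(cl.col_linkage[0, 2], 0.0)

    def test_k_larger_than_available_bins_errors(self):
        results = pd.DataFrame(
            {"bin_id": ["a", "b"], "term": "location", "pvalue": [0.1, 0.2],
             "estimate": [0.1, 0.2]}
        )
        with pytest.raises(ValueError, match="need 50"):
            select_top_location_bins(results, k=50)

    def test_selection_orders_by_p_then_effect_then_id(self):
        results = pd.DataFrame(
            {
                "bin_id": ["a", "b", "c", "d"],
                "term": "location",
                "pvalue": [0.01, 0.01, 0.001, 0.01],
                "estimate": [0.5, -0.9, 0.1, 0.5],
            }
        )
        assert select_top_location_bins(results, k=3) == ["c", "b", "a"]
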