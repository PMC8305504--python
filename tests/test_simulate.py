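"""Generator behavior: planted effects, determinism, sampling model."""

import numpy as np
import pandas as pd
import pytest

from psipath import SimConfig, simulate_cohort, simulate_bin_counts
from psipath.simulate import synthetic_layout, write_cohort


def null_config(seed=0, **kw):
    defaults = dict(
        seed=seed,
        n_bins=60,
        n_individuals=8,
        frac_location_bins=0.0,
        location_delta_psi=0.0,
        frac_ancestry_bins=0.0,
        ancestry_delta_psi=0.0,
        individual_sd=0.0,
        n_spliceopathy_individuals=0,
        frac_spliceopathy_bins=0.0,
        missing_sample_rate=0.0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_rejects_out_of_range_proportions(self):
        with pytest.raises(ValueError):
            SimConfig(missing_sample_rate=1.5)

    def test_rejects_too_many_spliceopathy_individuals(self):
        with pytest.raises(ValueError):
            SimConfig(n_spliceopathy_individuals=34)

    def test_rejects_degenerate_coverage(self):
        with pytest.raises(ValueError):
            SimConfig(coverage_mean=0.0)

    def test_rejects_unbalanced_compartments(self):
        with pytest.raises(ValueError):
            SimConfig(
                compartment_baselines={
                    "ileum": (0.5, 0.5, 0.5),
                    "rectum": (0.4, 0.4, 0.2),
                }
            )

    def test_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown"):
            SimConfig.from_dict({"n_bins": 10, "wibble": 3})


class TestBinCounts:
    def test_psi_one_gives_all_inclusion(self, rng):
        assert simulate_bin_counts(1.0, 100, rng) == (100, 0)

    def test_psi_zero_gives_all_exclusion(self, rng):
        assert simulate_bin_counts(0.0, 50, rng) == (0, 50)

    def test_mean_matches_binomial_clt_bound(self, rng):
        # mean(IR)/coverage within 3 sd of psi at coverage 10^4
        n, cov = 200, 10_000
        irs = np.array([simulate_bin_counts(0.5, cov, rng)[0] for _ in range(n)])
        bound = 3 * np.sqrt(0.25 / cov / n)
        assert abs(irs.mean() / cov - 0.5) < 3 * np.sqrt(0.25 / cov) and abs(
            irs.mean() / cov - 0.5
        ) < max(bound, 0.005)

    def test_rejects_invalid_psi(self, rng):
        with pytest.raises(ValueError):
            simulate_bin_counts(1.2, 10, rng)


class TestPlantedStructure:
    def test_null_model_groups_identical(self):
        c = simulate_cohort(null_config())
        vals = c.truth.true_psi.to_numpy()
        assert np.all(vals == vals[:, [0]])

    def test_effect_bin_counts_forced_by_construction(self):
        cfg = null_config(
            n_bins=100, frac_location_bins=0.3, location_delta_psi=0.2,
            frac_spliceopathy_bins=0.0,
        )
        c = simulate_cohort(cfg)
        assert len(c.truth.location_effect_bins) == round(0.3 * 100)
        assert set(c.truth.location_effect_bins) <= set(c.var_bin_ids)

    def test_location_effect_size_is_exact_at_effect_bins(self):
        cfg = null_config(n_bins=100, frac_location_bins=0.2, location_delta_psi=0.25)
        c = simulate_cohort(cfg)
        t = c.truth.true_psi
        diff = (t["rectum:European"] - t["ileum:European"]).abs()
        on = diff.loc[c.truth.location_effect_bins]
        off = diff.drop(c.truth.location_effect_bins)
        assert np.allclose(on, 0.25)
        assert np.allclose(off, 0.0)

    def test_ancestry_and_location_bins_disjoint(self):
        cfg = null_config(
            n_bins=100, frac_location_bins=0.2, location_delta_psi=0.2,
            frac_ancestry_bins=0.2, ancestry_delta_psi=0.1,
        )
        c = simulate_cohort(cfg)
        assert not set(c.truth.location_effect_bins) & set(c.truth.ancestry_effect_bins)

    def test_spliceopathy_samples_take_rectal_truth_exactly(self):
        cfg = null_config(
            n_individuals=10, n_bins=100,
            frac_location_bins=0.2, location_delta_psi=0.3,
            n_spliceopathy_individuals=2, frac_spliceopathy_bins=0.1,
        )
        c = simulate_cohort(cfg)
        assert c.truth.spliceopathy_samples
        assert set(c.truth.spliceopathy_bins) <= set(c.truth.location_effect_bins)
        meta = c.meta
        for sid in c.truth.spliceopathy_samples:
            assert meta.loc[sid, "location"] == "ileum"
            anc = meta.loc[sid, "ancestry"]
            expected = c.truth.true_psi.loc[c.truth.spliceopathy_bins, f"rectum:{anc}"]
            got = c.truth.sample_psi.loc[c.truth.spliceopathy_bins, sid]
            assert np.array_equal(got.to_numpy(), expected.to_numpy())

    def test_every_individual_keeps_a_sample_per_tissue(self):
        c = simulate_cohort(SimConfig(seed=5, missing_sample_rate=0.4))
        per = c.meta.groupby(["individual_id", "location"]).size()
        assert (per >= 1).all()
        assert per.index.get_level_values("individual_id").nunique() == 34


class TestDeterminism:
    def test_same_seed_identical_truth_and_junctions(self):
        a = simulate_cohort(SimConfig(seed=7, n_bins=50, n_individuals=6))
        b = simulate_cohort(SimConfig(seed=7, n_bins=50, n_individuals=6))
        pd.testing.assert_frame_equal(a.truth.true_psi, b.truth.true_psi)
        pd.testing.assert_frame_equal(a.truth.sample_psi, b.truth.sample_psi)
        assert a.junctions.keys() == b.junctions.keys()
        for sid in a.junctions:
            pd.testing.assert_frame_equal(a.junctions[sid], b.junctions[sid])

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimConfig(seed=7, n_bins=30, n_individuals=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(simulate_cohort(cfg), d1)
        write_cohort(simulate_cohort(cfg), d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()


class TestEmpiricalPsi:
    def test_high_coverage_empirical_psi_matches_truth(self):
        # law of large numbers at coverage >= 1000 over >= 50 bins
        cfg = null_config(n_bins=60, n_individuals=10, coverage_mean=2000.0,
                          coverage_dispersion=50.0)
        c = simulate_cohort(cfg)
        from psipath import quantify_cohort

        m, _ = quantify_cohort(c, variable_only=True)
        est = m.mean(axis=1)
        truth = c.truth.true_psi["ileum:European"]
        dev = (est - truth).abs()
        assert len(dev) >= 50
        assert (dev < 0.01).all()


def test_layout_alternates_anchor_and_variable_bins():
    all_bins, var_ids = synthetic_layout(7)
    assert len(var_ids) == 7
    # gene 1 has 5 variable bins (11 exons), gene 2 the remaining 2 (5 exons)
    genes = {b.gene_id for b in all_bins}
    assert genes == {"SG0001", "SG0002"}
    by_gene = [b for b in all_bins if b.gene_id == "SG0001"]
    assert len(by_gene) == 11
    assert [b.bin_id for b in by_gene[1::2]] == var_ids[:5]
    # uniform 100 bp exons and 200 bp introns
    assert all(b.end - b.start == 99 for b in all_bins)
    gaps = [n.start - p.end - 1 for p, n in zip(by_gene, by_gene[1:])]
    assert set(gaps) == {200}
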