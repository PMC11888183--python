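"""Shift tests, KDE profiles, windowed enrichment, direction calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import gaussian_kde, kstest

from dualscreen import (
    classify_target,
    kde_density_profile,
    mann_whitney_one_sided,
    phenotype_targets,
    pseudotime_shift_test,
    windowed_enrichment,
)
from dualscreen.perturbstats import TargetPhenotype


def enumeration_p_less(x, y):
    """Exact one-sided P(U_x <= observed) by exhaustive rank-split enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum((xi > yj) for xi in x for yj in y)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum((xi > yj) for xi in xs for yj in ys)
        count += u <= u_obs
        total += 1
    return count / total


class TestMannWhitney:
    def test_worked_exact_example(self):
        # {0.1, 0.2} vs {0.8, 0.9}: 1 of C(4,2)=6 splits is as extreme
        _, z, p = mann_whitney_one_sided([0.1, 0.2], [0.8, 0.9], "less")
        assert p == pytest.approx(1 / 6)
        assert z < 0

    def test_swapping_groups_flips_z(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=15), rng.normal(1, 1, size=12)
        _, z_xy, _ = mann_whitney_one_sided(x, y, "less")
        _, z_yx, _ = mann_whitney_one_sided(y, x, "less")
        assert z_xy == pytest.approx(-z_yx)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_one_sided([], [1.0], "less")

    @given(
        st.integers(min_value=1, max_value=6),
        st.integers(min_value=1, max_value=6),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=40, deadline=None)
    def test_equals_exhaustive_enumeration_oracle(self, n1, n2, rand):
        """Exact MW p equals brute-force enumeration for n1+n2 <= 12, no ties."""
        values = rand.sample(range(1000), n1 + n2)
        x = np.array(values[:n1], dtype=float)
        y = np.array(values[n1:], dtype=float)
        _, _, p = mann_whitney_one_sided(x, y, "less")
        assert p == pytest.approx(enumeration_p_less(x, y), abs=1e-12)

    def test_null_p_uniform_over_seeds(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x, y = rng.uniform(size=12), rng.uniform(size=30)
            _, _, p = mann_whitney_one_sided(x, y, "less")
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestShiftTest:
    def test_signed_direction(self):
        pt = pd.Series(
            [0.1, 0.2, 0.8, 0.9], index=["a", "b", "c", "d"], name="pseudotime"
        )
        z, p = pseudotime_shift_test(pt, ["a", "b"], ["c", "d"])
        assert z < 0 and p == pytest.approx(1 / 6)
        z2, _ = pseudotime_shift_test(pt, ["c", "d"], ["a", "b"])
        assert z2 == pytest.approx(-z)


class TestKdeProfile:
    def test_grid_has_40_points_and_nonnegative(self):
        rng = np.random.default_rng(1)
        prof = kde_density_profile(rng.uniform(0.2, 0.8, 100))
        assert len(prof.grid) == 40 and len(prof.densities) == 40
        assert (prof.densities >= 0).all()

    def test_single_point_forced_bandwidth_closed_form(self):
        prof = kde_density_profile([0.5], bandwidth=0.1)
        peak = prof.densities.max()
        # 1/(0.1 sqrt(2 pi)) = 3.989 at x=0.5; the nearest grid point of a
        # 40-point grid sits 0.0128 away, a ~1% attenuation
        assert peak == pytest.approx(1 / (0.1 * np.sqrt(2 * np.pi)), rel=0.02)

    def test_integrates_to_one_away_from_boundaries(self):
        rng = np.random.default_rng(2)
        prof = kde_density_profile(rng.uniform(0.3, 0.7, 500))
        integral = np.trapezoid(prof.densities, prof.grid)
        assert 0.9 <= integral <= 1.01

    def test_matches_scipy_gaussian_kde(self):
        """Cross-check against the reference KDE at Scott's bandwidth."""
        rng = np.random.default_rng(3)
        v = rng.beta(2, 2, size=80)
        prof = kde_density_profile(v)
        ref = gaussian_kde(v, bw_method="scott")(prof.grid)
        np.testing.assert_allclose(prof.densities, ref, rtol=1e-8)

    def test_degenerate_sample_needs_explicit_bandwidth(self):
        with pytest.raises(ValueError, match="bandwidth"):
            kde_density_profile([0.5, 0.5, 0.5])


class TestWindowedEnrichment:
    def test_window_count_for_40_point_grid(self):
        rng = np.random.default_rng(4)
        a = kde_density_profile(rng.uniform(size=50))
        b = kde_density_profile(rng.uniform(size=60))
        p_enr, p_dep = windowed_enrichment(a, b)
        assert len(p_enr) == 31 and len(p_dep) == 31

    def test_identical_profiles_never_significant(self):
        rng = np.random.default_rng(5)
        a = kde_density_profile(rng.uniform(size=50))
        p_enr, p_dep = windowed_enrichment(a, a)
        assert (p_enr >= 0.05).all() and (p_dep >= 0.05).all()

    def test_complete_separation_p(self):
        from dualscreen.perturbstats import DensityProfile

        grid = np.linspace(0, 1, 40)
        hi = DensityProfile(grid, np.linspace(2, 3, 40), 0.1, 10)
        lo = DensityProfile(grid, np.linspace(0.5, 1.4, 40), 0.1, 10)
        p_enr, _ = windowed_enrichment(hi, lo)
        from math import comb

        assert p_enr.min() == pytest.approx(1 / comb(20, 10), rel=1e-9)

    def test_invariant_to_common_offset(self):
        from dualscreen.perturbstats import DensityProfile

        rng = np.random.default_rng(6)
        grid = np.linspace(0, 1, 40)
        a = rng.uniform(1, 2, 40)
        b = rng.uniform(1, 2, 40)
        p1 = windowed_enrichment(DensityProfile(grid, a, 0.1, 5), DensityProfile(grid, b, 0.1, 5))
        p2 = windowed_enrichment(
            DensityProfile(grid, a + 7, 0.1, 5), DensityProfile(grid, b + 7, 0.1, 5)
        )
        np.testing.assert_allclose(p1[0], p2[0])
        np.testing.assert_allclose(p1[1], p2[1])


class TestCellPoolingVariant:
    def test_detects_low_pseudotime_pileup(self):
        from dualscreen.perturbstats import windowed_enrichment_cells

        rng = np.random.default_rng(0)
        target = np.clip(rng.uniform(size=80) - 0.4, 0, 1)
        reference = rng.uniform(size=2000)
        p = windowed_enrichment_cells(target, reference)
        assert len(p) == 31
        assert p[:5].min() < 1e-4      # strong early enrichment
        assert p[-5:].min() > 0.5      # none late


class TestClassification:
    def make_phenotype(self, z, window_low_p, shift_p_adj):
        p_enr = np.ones(31)
        p_enr[2] = window_low_p
        return TargetPhenotype(
            gene="g", n_cells=50, z_shift=z, p_shift=0.001,
            window_p_enriched=p_enr, window_p_depleted=np.ones(31),
            target_profile=None, p_shift_two=min(1.0, shift_p_adj),
            p_shift_two_adj=shift_p_adj,
        )

    def test_conjunction_required(self):
        assert classify_target(self.make_phenotype(-3, 0.001, 0.001)) == "pro_differentiation"
        # significant window but discordant/absent shift evidence -> none
        assert classify_target(self.make_phenotype(+3, 0.001, 0.001)) == "none"
        assert classify_target(self.make_phenotype(-3, 0.001, 0.5)) == "none"
        assert classify_target(self.make_phenotype(-3, 0.5, 0.001)) == "none"

    def test_high_region_maps_to_pro_progenitor(self):
        p_enr = np.ones(31)
        p_enr[29] = 0.001
        ph = TargetPhenotype(
            gene="g", n_cells=50, z_shift=3.0, p_shift=0.999,
            window_p_enriched=p_enr, window_p_depleted=np.ones(31),
            target_profile=None, p_shift_two=0.002, p_shift_two_adj=0.01,
        )
        assert classify_target(ph) == "pro_progenitor"


class TestShiftPowerMonotonicity:
    def test_larger_delta_gives_larger_z(self):
        """|Z| of the shift test grows stochastically with the planted
        latent-time shift |delta| (the generator's truncation model)."""
        mean_abs_z = []
        for delta in (0.0, -0.15, -0.3):
            zs = []
            for seed in range(20):
                rng = np.random.default_rng(100 * seed + int(abs(delta) * 100))
                target = np.clip(rng.uniform(size=60) + delta, 0, 1)
                background = rng.uniform(size=1500)
                pt = pd.Series(
                    np.concatenate([target, background]),
                    index=[f"c{i}" for i in range(1560)],
                )
                z, _ = pseudotime_shift_test(pt, pt.index[:60], pt.index[60:])
                zs.append(abs(z))
            mean_abs_z.append(np.mean(zs))
        assert mean_abs_z[0] < mean_abs_z[1] < mean_abs_z[2]

    def test_null_shift_p_uniform_over_many_genes(self):
        """With no effect, one-sided shift p-values over 500 simulated
        genes are uniform (KS p > 0.01)."""
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(500):
            x, y = rng.uniform(size=40), rng.uniform(size=400)
            _, _, p = mann_whitney_one_sided(x, y, "less")
            ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01


class TestPhenotypeTargets:
    def test_null_calibration_and_structure(self):
        """With no planted effect the shift p-values are uniform and
        (almost) no gene gets a direction call."""
        rng = np.random.default_rng(8)
        n_genes, cells_per_gene = 60, 40
        pt, targets = [], []
        for g in range(n_genes):
            pt.append(rng.uniform(size=cells_per_gene))
            targets += [f"G{g:03d}"] * cells_per_gene
        pseudotimes = pd.Series(
            np.concatenate(pt), index=[f"c{i}" for i in range(n_genes * cells_per_gene)]
        )
        table, phens = phenotype_targets(
            pseudotimes, pd.Series(targets, index=pseudotimes.index)
        )
        assert kstest(table["p_shift"], "uniform").pvalue > 0.01
        assert (table["classification"] == "none").mean() >= 0.95
        ph = next(iter(phens.values()))
        assert len(ph.window_p_enriched) == 31
        assert len(ph.target_profile.densities) == 40

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(9)
        rows = []
        for g in range(20):
            t = rng.uniform(size=60)
            if g == 0:  # held back near t=0
                t = np.clip(t - 0.4, 0, 1)
            rows.append((f"G{g:03d}", t))
        pseudotimes = pd.Series(
            np.concatenate([t for _, t in rows]),
            index=[f"c{i}" for i in range(20 * 60)],
        )
        targets = pd.Series(
            np.repeat([g for g, _ in rows], 60), index=pseudotimes.index
        )
        table, _ = phenotype_targets(pseudotimes, targets)
        assert table.loc["G000", "classification"] == "pro_differentiation"
        assert table.loc["G000", "z_shift"] < -3
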