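"""Nearest-neighbor spacing, bin fractions, density ratios, permutation test,
and contour circularity."""

import math

import numpy as np
import pytest

from gipscape import (
    PointPattern,
    PointProcessSpec,
    bin_fractions,
    circularity,
    compare_conditions,
    density_and_ratio,
    gen_point_pattern,
    nn_distances,
)


def grid_pattern(nx=3, ny=3, spacing=90.0, margin=50.0):
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
    pts = np.c_[xs.ravel(), ys.ravel()] * spacing + margin
    side = spacing * (max(nx, ny) - 1) + 2 * margin
    return PointPattern(points=pts, window=(side, side))


class TestNNDistances:
    def test_two_points(self):
        p = PointPattern(points=[[10.0, 10.0], [70.0, 10.0]], window=(100, 100))
        s = nn_distances(p)
        np.testing.assert_allclose(s.nn_distances_nm, [60.0, 60.0])
        assert s.mean_nn_nm == 60.0

    def test_square_grid_spacing(self):
        """3×3 grid at 90 nm spacing: every pore's nearest neighbor is one
        grid step away, so the mean NN distance is 90 nm."""
        s = nn_distances(grid_pattern(spacing=90.0))
        assert s.mean_nn_nm == pytest.approx(90.0)

    def test_translation_and_rotation_invariance(self, rng):
        pts = rng.uniform(100, 900, size=(40, 2))
        base = np.sort(nn_distances(
            PointPattern(points=pts, window=(1000, 1000))).nn_distances_nm)
        shifted = np.sort(nn_distances(
            PointPattern(points=pts + 42.0, window=(2000, 2000))
        ).nn_distances_nm)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        rotated = (pts - 500) @ R.T + 1000
        rot = np.sort(nn_distances(
            PointPattern(points=rotated, window=(2000, 2000))).nn_distances_nm)
        np.testing.assert_allclose(shifted, base, atol=1e-9)
        np.testing.assert_allclose(rot, base, atol=1e-9)

    def test_border_exclusion_drops_edge_centers(self):
        pts = [[5.0, 50.0], [50.0, 50.0], [95.0, 50.0]]
        p = PointPattern(points=pts, window=(100, 100))
        s = nn_distances(p, border_exclusion_nm=10.0)
        assert len(s.nn_distances_nm) == 1  # only the central point remains

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            nn_distances(PointPattern(points=[[1.0, 1.0]], window=(10, 10)))

    def test_points_outside_window_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            PointPattern(points=[[5.0, 20.0]], window=(10, 10))

    def test_csr_mean_matches_poisson_law(self):
        """Pooled CSR mean NN distance obeys 1/(2√ρ) within 3 SE (periodic
        metric; ρ=100/μm² gives 50 nm)."""
        side = 1000.0 * math.sqrt(2.0)
        all_nn, rep_means = [], []
        for seed in range(100):
            pat = gen_point_pattern(PointProcessSpec(
                window=(side, side), process="csr", intensity=100.0, seed=seed))
            s = nn_distances(pat, edge_correction="torus")
            all_nn.append(s.nn_distances_nm)
            rep_means.append(s.mean_nn_nm)
        pooled = np.concatenate(all_nn)
        se = np.std(rep_means, ddof=1) / math.sqrt(len(rep_means))
        assert abs(pooled.mean() - 50.0) <= 3 * se


class TestBinFractions:
    def test_worked_partition(self):
        fr = bin_fractions(np.array([10.0, 20.0, 40.0, 100.0]), [0.0, 30.0])
        assert fr[(0.0, 30.0)] == 0.5
        assert fr[(30.0, math.inf)] == 0.5

    def test_single_occupied_bin(self):
        fr = bin_fractions(np.array([65.0, 70.0, 80.0]), [0, 30, 60, 90])
        assert fr[(60.0, 90.0)] == 1.0
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, rng):
        d = rng.exponential(50.0, size=500)
        fr = bin_fractions(d, [0, 30, 60, 90, 120])
        assert sum(fr.values()) == pytest.approx(1.0)
        assert all(0 <= v <= 1 for v in fr.values())

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            bin_fractions(np.array([10.0]), [(0.0, 40.0), (30.0, math.inf)])

    def test_gap_or_uncovered_partition_rejected(self):
        with pytest.raises(ValueError):
            bin_fractions(np.array([10.0]), [(0.0, 30.0), (40.0, math.inf)])
        with pytest.raises(ValueError):
            bin_fractions(np.array([10.0]), [(0.0, 30.0)])

    def test_clustering_inflates_short_range_fraction(self):
        """Thomas clustering at tight offspring dispersion puts more NN mass
        in the 0–30 nm bin than CSR at the same intensity (median over
        replicates), the signature of mutant pore aggregation."""
        short_csr, short_thomas = [], []
        for seed in range(40):
            csr = gen_point_pattern(PointProcessSpec(
                process="csr", intensity=50.0, seed=seed))
            tho = gen_point_pattern(PointProcessSpec(
                process="thomas", intensity=50.0, parent_intensity=5.0,
                mean_offspring=10.0, offspring_sd=10.0, seed=seed))
            if csr.n < 2 or tho.n < 2:
                continue
            short_csr.append(
                bin_fractions(nn_distances(csr), [0.0, 30.0])[(0.0, 30.0)])
            short_thomas.append(
                bin_fractions(nn_distances(tho), [0.0, 30.0])[(0.0, 30.0)])
        assert np.median(short_thomas) > np.median(short_csr)


class TestDensityAndRatio:
    def test_worked_density(self):
        side = 1000.0 * math.sqrt(2.0)  # 2 um^2 window
        pts = np.c_[np.linspace(100, side - 100, 9), np.full(9, side / 2)]
        p = PointPattern(points=pts, window=(side, side))
        da, db, ratio = density_and_ratio(p, p)
        assert da == pytest.approx(4.5)
        assert ratio == pytest.approx(1.0)

    def test_generator_consistency(self):
        """CSR at ρ and 1.75ρ: mean measured density ratio within 5% of 1.75."""
        ratios = []
        for seed in range(500):
            a = gen_point_pattern(PointProcessSpec(
                process="csr", intensity=40.0, seed=seed))
            b = gen_point_pattern(PointProcessSpec(
                process="csr", intensity=70.0, seed=10_000 + seed))
            ratios.append(density_and_ratio(a, b)[2])
        assert abs(np.mean(ratios) - 1.75) / 1.75 < 0.05

    def test_empty_pattern_rejected(self):
        p = PointPattern(points=np.empty((0, 2)), window=(10, 10))
        q = PointPattern(points=[[1.0, 1.0]], window=(10, 10))
        with pytest.raises(ValueError):
            density_and_ratio(p, q)


class TestCompareConditions:
    def test_identical_samples_p_one(self):
        a = np.arange(20.0)
        assert compare_conditions(a, a, n_perm=199, seed=0).p_value == 1.0

    def test_deterministic_given_seed(self, rng):
        a, b = rng.normal(90, 10, 50), rng.normal(60, 10, 50)
        r1 = compare_conditions(a, b, n_perm=499, seed=7)
        r2 = compare_conditions(a, b, n_perm=499, seed=7)
        assert r1.p_value == r2.p_value

    def test_p_value_in_unit_interval(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 12)
        p = compare_conditions(a, b, n_perm=199, seed=1).p_value
        assert 0 < p <= 1

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError, match="100"):
            compare_conditions(np.arange(5.0), np.arange(5.0), n_perm=99)

    def test_power_on_regular_vs_clustered(self):
        """Hard-core vs Thomas spacing: the mean-NN contrast mirroring the
        wild-type/mutant comparison is detected at p < 0.001 in nearly every
        replicate."""
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            wt = gen_point_pattern(PointProcessSpec(
                process="hard-core", intensity=50.0, hard_core_distance=60.0,
                seed=seed))
            mut = gen_point_pattern(PointProcessSpec(
                process="thomas", intensity=50.0, parent_intensity=5.0,
                mean_offspring=10.0, offspring_sd=15.0, seed=500 + seed))
            a = nn_distances(wt).nn_distances_nm
            b = nn_distances(mut).nn_distances_nm
            p = compare_conditions(a, b, n_perm=1999, seed=seed).p_value
            hits += p < 0.001
        assert hits >= 0.95 * n_rep


class TestCircularity:
    def test_circle_limit(self):
        theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        verts = np.c_[np.cos(theta), np.sin(theta)] * 500 + 600
        assert circularity(verts) >= 0.999

    def test_square_closed_form(self):
        assert circularity([[0, 0], [100, 0], [100, 100], [0, 100]]) == (
            pytest.approx(math.pi / 4)
        )

    def test_lobulated_star_below_square(self):
        """A 20-point star (alternating radii 1 and 0.4) inflates perimeter at
        fixed area, dropping circularity below the square's π/4 — the
        irregular-nucleus regime."""
        k = 20
        theta = np.linspace(0, 2 * np.pi, k, endpoint=False)
        radius = np.where(np.arange(k) % 2 == 0, 1.0, 0.4)
        verts = np.c_[radius * np.cos(theta), radius * np.sin(theta)] + 2.0
        assert circularity(verts) < math.pi / 4

    def test_self_intersecting_rejected(self):
        bowtie = [[0, 0], [1, 1], [1, 0], [0, 1]]
        with pytest.raises(ValueError):
            circularity(bowtie)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError):
            circularity([[0, 0], [1, 1]])
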