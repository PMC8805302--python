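"""FSC/FSCavg, contoured real-space scores, ensemble combination, half maps."""

import numpy as np
import pytest

from emvalidate.global_fit import (
    EnsembleScores,
    FscCurve,
    FscShell,
    GlobalFitScores,
    ccc,
    combined_scores,
    fsc_avg,
    fsc_curve,
    halfmap_comparison,
    mutual_information,
    overlap,
)
from emvalidate.map_simulation import SimulationParams
from emvalidate.volumetric_io import ContourLevel, DegenerateMapError, DensityGrid

from conftest import noise_grid


def contour(level):
    return ContourLevel(level)


class TestFscCurve:
    def test_self_correlation_is_one_everywhere(self):
        g = noise_grid(0)
        curve = fsc_curve(g, g, n_shells=12)
        assert all(s.fsc == pytest.approx(1.0, abs=1e-12) for s in curve.shells)

    def test_negated_map_gives_minus_one(self):
        g = noise_grid(0)
        curve = fsc_curve(g, g.with_values(-g.values), n_shells=12)
        assert all(s.fsc == pytest.approx(-1.0, abs=1e-12) for s in curve.shells)

    def test_independent_noise_within_null_band(self):
        """|FSC| of independent maps stays within 3/sqrt(n_terms) for at least
        90% of shells across 5 seed pairs (null sd of a correlation of n
        independent coefficients is about 1/sqrt(n))."""
        total, ok = 0, 0
        for seed in range(5):
            a = noise_grid(100 + seed, shape=(48, 48, 48))
            b = noise_grid(200 + seed, shape=(48, 48, 48))
            for shell in fsc_curve(a, b, n_shells=16).shells:
                total += 1
                ok += abs(shell.fsc) < 3.0 / np.sqrt(shell.n_terms)
        assert ok / total >= 0.9

    def test_scale_invariance_and_symmetry(self):
        a = noise_grid(1)
        b = noise_grid(2)
        c_ab = fsc_curve(a, b, n_shells=8)
        c_ba = fsc_curve(b, a, n_shells=8)
        c_scaled = fsc_curve(a.with_values(5.0 * a.values), b, n_shells=8)
        for s1, s2, s3 in zip(c_ab.shells, c_ba.shells, c_scaled.shells):
            assert s1.fsc == pytest.approx(s2.fsc, abs=1e-12)
            assert s1.fsc == pytest.approx(s3.fsc, abs=1e-10)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            fsc_curve(noise_grid(0, shape=(16, 16, 16)), noise_grid(0, shape=(18, 18, 18)))


class TestFscAvg:
    def test_all_ones_average_to_one(self):
        curve = FscCurve(
            [FscShell(20.0, 10.0, 5, 1.0), FscShell(10.0, 5.0, 17, 1.0)], resolution_limit=0.0
        )
        assert fsc_avg(curve) == 1.0

    def test_weighted_mean_identity(self):
        curve = FscCurve(
            [FscShell(20.0, 10.0, 10, 1.0), FscShell(10.0, 5.0, 30, 0.5)], resolution_limit=0.0
        )
        assert fsc_avg(curve) == pytest.approx(0.625)

    def test_resolution_limit_truncates_fine_shells(self):
        curve = FscCurve(
            [FscShell(20.0, 10.0, 10, 1.0), FscShell(10.0, 5.0, 30, 0.5)], resolution_limit=8.0
        )
        assert fsc_avg(curve) == 1.0

    def test_limit_excluding_every_shell_falls_back_to_all(self, caplog):
        curve = FscCurve([FscShell(20.0, 10.0, 10, 0.8)], resolution_limit=25.0)
        with caplog.at_level("WARNING"):
            assert fsc_avg(curve) == pytest.approx(0.8)
        assert any("all shells" in r.message for r in caplog.records)

    def test_average_between_min_and_max_shell(self):
        rng = np.random.default_rng(11)
        f = rng.uniform(-1, 1, 6)
        shells = [
            FscShell(10.0 - i, 9.0 - i, int(rng.integers(1, 50)), float(f[i])) for i in range(6)
        ]
        avg = fsc_avg(FscCurve(shells, resolution_limit=0.0))
        assert f.min() - 1e-12 <= avg <= f.max() + 1e-12


class TestCcc:
    def test_self_is_one(self):
        g = noise_grid(3)
        assert ccc(g, g, contour(0.0), contour(0.0)) == pytest.approx(1.0)

    def test_affine_invariance(self):
        g = noise_grid(3)
        h = g.with_values(2.0 * g.values + 5.0)
        c = contour(0.5)
        c2 = contour(2.0 * 0.5 + 5.0)
        assert ccc(g, h, c, c2) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_decrease_with_noise(self, helix_maps):
        clean = helix_maps[0]
        c = contour(0.05)
        values = []
        for i, sd in enumerate((0.1, 0.3, 0.6)):
            rng = np.random.default_rng(40 + i)
            noisy = clean.with_values(
                clean.values + rng.normal(0, sd * clean.values.max(), clean.shape)
            )
            values.append(ccc(clean, noisy, c, c))
        assert values[0] > values[1] > values[2]

    def test_empty_contour_set_rejected(self):
        g = noise_grid(3)
        with pytest.raises(DegenerateMapError):
            ccc(g, g, contour(1e9), contour(1e9))


class TestMutualInformation:
    def test_self_mi_equals_marginal_entropy(self):
        """MI(g,g) must equal the entropy of g's binned marginal (same
        histogram computed independently)."""
        g = noise_grid(6)
        c = contour(-0.5)
        mi = mutual_information(g, g, c, c, bins=20)
        sel = g.values[g.values >= -0.5]
        counts, _ = np.histogram(sel, bins=np.linspace(sel.min(), sel.max(), 21))
        p = counts / counts.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mi == pytest.approx(entropy, abs=1e-9)

    def test_independent_maps_have_small_mi(self):
        a = noise_grid(7, shape=(64, 64, 64))
        b = noise_grid(8, shape=(64, 64, 64))
        mi = mutual_information(a, b, contour(-10.0), contour(-10.0), bins=20)
        assert 0.0 <= mi <= 0.05

    def test_nonnegative_on_dependent_inputs(self):
        a = noise_grid(9)
        b = a.with_values(np.abs(a.values))
        assert mutual_information(a, b, contour(0.0), contour(0.0)) >= 0.0


def sphere_grid(center, radius=8.0, shape=(40, 40, 40)):
    idx = np.indices(shape, dtype=float)
    r = np.sqrt(sum((idx[k] - center[k]) ** 2 for k in range(3)))
    return DensityGrid((r <= radius).astype(float), (1.0,) * 3)


class TestOverlap:
    def test_identical_maps_give_one(self):
        g = sphere_grid((20, 20, 20))
        assert overlap(g, g, contour(0.5), contour(0.5)) == 1.0

    def test_disjoint_spheres_give_zero(self):
        a = sphere_grid((10, 10, 10), radius=5)
        b = sphere_grid((30, 30, 30), radius=5)
        assert overlap(a, b, contour(0.5), contour(0.5)) == 0.0

    def test_half_shifted_sphere_matches_voxel_counting(self):
        a = sphere_grid((20, 20, 20))
        b = sphere_grid((28, 20, 20))
        got = overlap(a, b, contour(0.5), contour(0.5))
        in_a = a.values >= 0.5
        in_b = b.values >= 0.5
        expected = (in_a & in_b).sum() / min(in_a.sum(), in_b.sum())
        assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        a = sphere_grid((20, 20, 20))
        b = sphere_grid((25, 22, 20), radius=6)
        c = contour(0.5)
        assert overlap(a, b, c, c) == overlap(b, a, c, c)


def _scores(ccc_v, mi_v, ov_v):
    c = ContourLevel(0.0)
    return GlobalFitScores(fsc_avg=0.0, ccc=ccc_v, mi=mi_v, ov=ov_v, contour_model=c, contour_exp=c)


class TestCombinedScores:
    def test_identical_models_all_zero(self):
        ens = combined_scores(EnsembleScores([_scores(0.5, 0.2, 0.9)] * 3))
        assert ens.ccc_ov == [0.0, 0.0, 0.0]
        assert ens.mi_ov == [0.0, 0.0, 0.0]

    def test_degenerate_ov_preserves_ccc_ranking(self):
        ens = combined_scores(
            EnsembleScores([_scores(0.9, 0.1, 1.0), _scores(0.5, 0.1, 1.0), _scores(0.1, 0.1, 1.0)])
        )
        assert np.argsort(ens.ccc_ov)[::-1].tolist() == [0, 1, 2]

    def test_matches_zscore_sum_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            ccc_v, mi_v, ov_v = rng.uniform(0, 1, (3, 4))
            ens = combined_scores(
                EnsembleScores([_scores(c, m, o) for c, m, o in zip(ccc_v, mi_v, ov_v)])
            )

            def z(v):
                v = np.asarray(v)
                return np.zeros_like(v) if v.std() == 0 else (v - v.mean()) / v.std()

            np.testing.assert_allclose(ens.ccc_ov, z(ccc_v) + z(ov_v), atol=1e-12)
            np.testing.assert_allclose(ens.mi_ov, z(mi_v) + z(ov_v), atol=1e-12)
            assert np.argsort(ens.ccc_ov).tolist() == np.argsort(z(ccc_v) + z(ov_v)).tolist()

    def test_fewer_than_three_models_rejected(self):
        with pytest.raises(ValueError, match="three"):
            EnsembleScores([_scores(0.5, 0.2, 0.9)] * 2)

    def test_ranking_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(5)
        ccc_v, mi_v, ov_v = rng.uniform(0, 1, (3, 5))
        base = combined_scores(
            EnsembleScores([_scores(c, m, o) for c, m, o in zip(ccc_v, mi_v, ov_v)])
        )
        scaled = combined_scores(
            EnsembleScores(
                [_scores(3 * c + 1, m, o) for c, m, o in zip(ccc_v, mi_v, ov_v)]
            )
        )
        assert np.argsort(base.ccc_ov).tolist() == np.argsort(scaled.ccc_ov).tolist()


class TestHalfmapComparison:
    def test_identical_maps_give_zero_delta(self, helix_model, helix_maps, sim_params):
        _, _, delta = halfmap_comparison(helix_model, helix_maps[1], helix_maps[1], sim_params)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_overfitting_to_first_map_gives_positive_delta(self, helix_model, helix_maps, sim_params):
        """The model was (by construction) fit to the clean map; adding fresh
        noise to the second copy must lower its FSCavg there."""
        clean = helix_maps[0]
        rng = np.random.default_rng(77)
        other = clean.with_values(
            clean.values + rng.normal(0, 0.3 * clean.values.max(), clean.shape)
        )
        _, _, delta = halfmap_comparison(helix_model, clean, other, sim_params)
        assert delta > 0.0

    def test_swapped_arguments_negate_delta(self, helix_model, helix_maps, sim_params):
        clean, noisy = helix_maps
        _, _, d12 = halfmap_comparison(helix_model, clean, noisy, sim_params)
        _, _, d21 = halfmap_comparison(helix_model, noisy, clean, sim_params)
        assert d12 == pytest.approx(-d21, abs=1e-12)
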