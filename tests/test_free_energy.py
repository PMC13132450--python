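"""WHAM recovery, partitioning descriptors, metadynamics FES and minimax paths."""

import itertools

import numpy as np
import pytest

from gpcrdyn.errors import (
    ConsistencyError,
    DegeneratePathError,
    OverlapError,
    SpecError,
)
from gpcrdyn.free_energy import (
    BOLTZMANN_KCAL,
    FES2D,
    HillsRecord,
    PMFCurve,
    UmbrellaWindow,
    metad_fes,
    min_energy_path,
    pmf_descriptors,
    read_hills,
    read_umbrella_windows,
    wham,
    write_hills,
    write_umbrella_windows,
)
from gpcrdyn.synthetic_data import (
    HillsSpec,
    UmbrellaSpec,
    make_hills,
    sample_umbrella_windows,
)

RT310 = BOLTZMANN_KCAL * 310.0


class TestWham:
    def test_single_unbiased_window_reduces_to_log_histogram(self):
        rng = np.random.default_rng(70)
        samples = rng.normal(0.0, 1.0, size=20_000)
        window = UmbrellaWindow(center=0.0, k_bias=1e-9, samples=samples, temperature=310.0)
        pmf = wham([window], bin_width=0.25)
        hist, edges = np.histogram(samples, bins=np.arange(samples.min(),
                                                           samples.max() + 0.25, 0.25))
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = hist > 0
        expected = -RT310 * np.log(hist[keep].astype(float))
        expected -= expected.min()
        common = np.isin(np.round(pmf.z, 6), np.round(centers[keep], 6))
        np.testing.assert_allclose(pmf.F[common], expected, atol=1e-6)

    def test_flat_pmf_recovered_near_zero(self):
        z = np.arange(-6.0, 6.0 + 1e-9, 0.05)
        spec = UmbrellaSpec(
            pmf_z=tuple(z), pmf_F=tuple(np.zeros_like(z)),
            window_centers=(-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0),
            n_samples_per_window=10_000, seed=71,
        )
        pmf = wham(sample_umbrella_windows(spec), bin_width=0.2)
        span = (pmf.z > -3.0) & (pmf.z < 3.0)
        assert np.abs(pmf.F[span] - pmf.F[span].mean()).max() < 0.1

    def test_invariant_under_sample_permutation(self):
        z = np.arange(-5.0, 5.0 + 1e-9, 0.05)
        spec = UmbrellaSpec(
            pmf_z=tuple(z), pmf_F=tuple(0.5 * np.asarray(z) ** 2 * 0.1),
            window_centers=(-2.0, 0.0, 2.0), n_samples_per_window=2000, seed=72,
        )
        windows = sample_umbrella_windows(spec)
        pmf_a = wham(windows, bin_width=0.2)
        rng = np.random.default_rng(0)
        shuffled = [
            UmbrellaWindow(w.center, w.k_bias, rng.permutation(w.samples), w.temperature)
            for w in windows
        ]
        pmf_b = wham(shuffled, bin_width=0.2)
        np.testing.assert_allclose(pmf_a.F, pmf_b.F, atol=1e-12)

    def test_non_overlapping_windows_detected(self):
        rng = np.random.default_rng(73)
        wins = [
            UmbrellaWindow(0.0, 1.5, rng.normal(0.0, 0.3, 500), 310.0),
            UmbrellaWindow(20.0, 1.5, rng.normal(20.0, 0.3, 500), 310.0),
        ]
        with pytest.raises(OverlapError, match="20"):
            wham(wins, bin_width=0.2)

    def test_window_file_roundtrip(self, tmp_path):
        rng = np.random.default_rng(74)
        wins = [
            UmbrellaWindow(1.0, 1.5, rng.normal(1.0, 0.5, 50), 310.0),
            UmbrellaWindow(2.0, 1.5, rng.normal(2.0, 0.5, 50), 310.0),
        ]
        write_umbrella_windows(wins, tmp_path)
        back = read_umbrella_windows(tmp_path)
        for a, b in zip(wins, back):
            assert a.center == b.center and a.k_bias == b.k_bias
            np.testing.assert_allclose(a.samples, b.samples, atol=1e-6)


class TestDescriptors:
    def test_rt_at_310K_is_0p616(self):
        z = np.linspace(-20, 5, 100)
        desc = pmf_descriptors(PMFCurve(z=z, F=np.zeros_like(z)), 310.0, plateau=(-20, -15))
        assert f"{desc.RT:.3f}" == "0.616"

    def test_flat_pmf_gives_zero_descriptors(self):
        z = np.linspace(-25, 2, 150)
        desc = pmf_descriptors(PMFCurve(z=z, F=np.zeros_like(z)), 310.0, plateau=(-25, -20))
        assert desc.dG_partitioning == pytest.approx(0.0, abs=1e-9)
        assert desc.dG_crossing == pytest.approx(0.0, abs=1e-9)

    def _constructed_curve(self):
        # plateau 0 for z <= -22, single well of depth -5 at z = -15,
        # barrier +6 (absolute) at z = 0
        z = np.linspace(-28, 0, 561)
        F = np.zeros_like(z)
        well = np.abs(z + 15) <= 5
        F[well] = -5.0 * np.cos(np.pi * (z[well] + 15) / 10) ** 2
        rise = z > -10
        F[rise] = 6.0 * np.sin(np.pi * (z[rise] + 10) / 20) ** 2
        return PMFCurve(z=z, F=F)

    def test_constructed_well_read_off(self):
        desc = pmf_descriptors(self._constructed_curve(), 310.0, plateau=(-28, -24))
        assert desc.dG_partitioning == pytest.approx(-5.0, abs=1e-3)
        assert desc.dG_crossing == pytest.approx(11.0, abs=1e-3)
        assert desc.z_min == pytest.approx(-15.0, abs=0.05)
        assert desc.accessible_halfwidth > 0

    def test_invariant_under_constant_shift(self):
        curve = self._constructed_curve()
        shifted = PMFCurve(z=curve.z, F=curve.F + 37.5)
        a = pmf_descriptors(curve, 310.0, plateau=(-28, -24))
        b = pmf_descriptors(shifted, 310.0, plateau=(-28, -24))
        assert a.dG_partitioning == pytest.approx(b.dG_partitioning, abs=1e-12)
        assert a.dG_crossing == pytest.approx(b.dG_crossing, abs=1e-12)
        assert a.z_min == pytest.approx(b.z_min)

    def test_plateau_outside_grid_rejected(self):
        z = np.linspace(-10, 0, 50)
        with pytest.raises(SpecError):
            pmf_descriptors(PMFCurve(z=z, F=np.zeros_like(z)), 310.0, plateau=(5, 10))


class TestMetadFES:
    def test_single_hill_minimum_at_center(self):
        rec = HillsRecord(0.0, 1.0, 90.0, 0.05, 5.0, 1.5, 15.0)
        fes = metad_fes([rec], np.linspace(0.8, 1.2, 81), np.linspace(60, 120, 61))
        i, j = np.unravel_index(np.argmin(fes.F), fes.F.shape)
        assert fes.cv1[i] == pytest.approx(1.0, abs=1e-9)
        assert fes.cv2[j] == pytest.approx(90.0, abs=1e-9)
        assert fes.F.min() == 0.0

    def test_well_tempered_prefactor_15_over_14(self):
        rec = HillsRecord(0.0, 1.0, 90.0, 0.05, 5.0, 1.5, 15.0)
        cv1 = np.linspace(0.8, 1.2, 21)
        cv2 = np.linspace(60, 120, 21)
        fes = metad_fes([rec], cv1, cv2)
        G1, G2 = np.meshgrid(cv1, cv2, indexing="ij")
        V = 1.5 * np.exp(-((G1 - 1) ** 2) / (2 * 0.05**2) - ((G2 - 90) ** 2) / (2 * 5.0**2))
        expected = -(15.0 / 14.0) * V
        expected -= expected.min()
        np.testing.assert_allclose(fes.F, expected, atol=1e-12)

    def test_random_hills_equal_brute_force_sum(self):
        rng = np.random.default_rng(75)
        hills = [
            HillsRecord(float(t), float(rng.uniform(0.5, 2.5)), float(rng.uniform(0, 180)),
                        0.05, 5.0, float(rng.uniform(0.1, 1.5)), 15.0)
            for t in range(25)
        ]
        cv1 = np.linspace(0.4, 2.6, 45)
        cv2 = np.linspace(0, 180, 37)
        fes = metad_fes(hills, cv1, cv2)
        V = np.zeros((45, 37))
        for h in hills:
            for i, a in enumerate(cv1):
                for j, b in enumerate(cv2):
                    V[i, j] += h.height * np.exp(
                        -((a - h.cv1) ** 2) / (2 * h.sigma_cv1**2)
                        - ((b - h.cv2) ** 2) / (2 * h.sigma_cv2**2)
                    )
        expected = -(15.0 / 14.0) * V
        expected -= expected.min()
        np.testing.assert_allclose(fes.F, expected, atol=1e-10)

    def test_mixed_bias_factor_rejected(self):
        hills = [
            HillsRecord(0, 1, 90, 0.05, 5, 1.5, 15.0),
            HillsRecord(1, 1.1, 95, 0.05, 5, 1.5, 10.0),
        ]
        with pytest.raises(ConsistencyError):
            metad_fes(hills, np.linspace(0, 2, 5), np.linspace(0, 180, 5))

    def test_hills_file_roundtrip_and_unit_declaration(self, tmp_path):
        records = make_hills(HillsSpec(cv_path=((1.0, 150.0), (0.8, 120.0), (0.6, 90.0))))
        path = tmp_path / "HILLS"
        write_hills(records, path, height_units="kJ/mol")
        back = read_hills(path, height_units="kJ/mol")
        assert len(back) == 3
        for a, b in zip(records, back):
            assert b.height == pytest.approx(a.height, abs=1e-9)
            assert b.bias_factor == a.bias_factor
        with pytest.raises(ConsistencyError):
            read_hills(path, height_units="kcal/mol")


def _brute_minimax(F, start, end):
    """Independent bottleneck oracle: the minimal level M (over the sorted
    grid values) such that start and end are 8-connected within {F <= M}."""
    n1, n2 = F.shape

    def connected(level):
        if F[start] > level or F[end] > level:
            return False
        seen, stack = {start}, [start]
        while stack:
            i, j = stack.pop()
            if (i, j) == end:
                return True
            for di, dj in itertools.product((-1, 0, 1), repeat=2):
                ni, nj = i + di, j + dj
                if (di or dj) and 0 <= ni < n1 and 0 <= nj < n2:
                    if F[ni, nj] <= level and (ni, nj) not in seen:
                        seen.add((ni, nj))
                        stack.append((ni, nj))
        return False

    for level in np.sort(F.ravel()):
        if connected(level):
            return float(level)
    raise AssertionError("grid is always connected at the max level")


class TestMinEnergyPath:
    def test_flat_2x2_direct_step(self):
        fes = FES2D(cv1=np.array([0.0, 1.0]), cv2=np.array([0.0, 1.0]),
                    F=np.zeros((2, 2)))
        path = min_energy_path(fes, (0, 0), (1, 1))
        assert [p for p, _ in path] == [(0, 0), (1, 1)]

    def test_corridor_hugged_and_bottleneck_matches_brute_force(self):
        rng = np.random.default_rng(76)
        F = rng.uniform(5, 9, size=(5, 5))
        F[:, 0] = rng.uniform(0, 1, size=5)   # low col-0 corridor
        F[0, :] = np.linspace(0, 2, 5)
        fes = FES2D(cv1=np.arange(5.0), cv2=np.arange(5.0), F=F)
        path = min_energy_path(fes, (4, 0), (0, 4))
        got_max = max(v for _, v in path)
        assert got_max == pytest.approx(_brute_minimax(F, (4, 0), (0, 4)), abs=1e-12)
        # the path must use the corridor, not the high interior
        assert all(F[p] <= got_max + 1e-12 for p, _ in path)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(77)
        F = rng.uniform(0, 5, size=(6, 4))
        fes = FES2D(cv1=np.arange(6.0), cv2=np.arange(4.0), F=F)
        fwd = min_energy_path(fes, (0, 0), (5, 3))
        bwd = min_energy_path(fes, (5, 3), (0, 0))
        assert [p for p, _ in fwd] == [p for p, _ in bwd][::-1]

    def test_path_max_bounded_below_by_endpoints(self):
        rng = np.random.default_rng(78)
        F = rng.uniform(0, 3, size=(5, 5))
        fes = FES2D(cv1=np.arange(5.0), cv2=np.arange(5.0), F=F)
        path = min_energy_path(fes, (0, 0), (4, 4))
        assert max(v for _, v in path) >= max(F[0, 0], F[4, 4]) - 1e-12

    def test_degenerate_endpoints_rejected(self):
        fes = FES2D(cv1=np.arange(3.0), cv2=np.arange(3.0), F=np.zeros((3, 3)))
        with pytest.raises(DegeneratePathError):
            min_energy_path(fes, (1, 1), (1, 1))
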