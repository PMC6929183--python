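"""WHAM reconstruction, barrier extraction and the reaction coordinate."""

import numpy as np
import pytest

from isokie.synthetic import ProfileSpec, sample_umbrella_windows
from isokie.thermo import ThermoSettings
from isokie.wham import (
    NoBarrierError,
    PMFProfile,
    ReactionCoordinateSpec,
    UmbrellaWindow,
    WHAMConvergenceError,
    barrier_height,
    reaction_coordinate,
    read_windows_tsv,
    wham,
    write_windows_tsv,
)


class TestReactionCoordinate:
    def geometry(self, r_ch, r_ho):
        return np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r_ch], [0.0, 0.0, r_ch + r_ho]])

    def test_reactant_like_negative(self):
        spec = ReactionCoordinateSpec(donor=(0, 1), acceptor=(1, 2))
        assert reaction_coordinate(self.geometry(1.1, 1.6), spec) == pytest.approx(-0.5)

    def test_symmetric_zero(self):
        spec = ReactionCoordinateSpec()
        assert reaction_coordinate(self.geometry(1.3, 1.3), spec) == pytest.approx(0.0)

    def test_product_like_positive(self):
        spec = ReactionCoordinateSpec()
        assert reaction_coordinate(self.geometry(2.0, 1.0), spec) == pytest.approx(1.0)

    def test_coincident_atoms_rejected(self):
        spec = ReactionCoordinateSpec()
        geom = self.geometry(0.0, 1.0)
        with pytest.raises(ValueError, match="coincident"):
            reaction_coordinate(geom, spec)

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ReactionCoordinateSpec(donor=(0, 1), acceptor=(0, 1))


@pytest.fixture(scope="module")
def th():
    return ThermoSettings(temperature=298.15)


@pytest.fixture(scope="module")
def double_well_windows(th):
    profile = ProfileSpec(
        form="double-well",
        params={"barrier": 6.0, "half_separation": 0.5},
        temperature=th.temperature,
    )
    centers = np.linspace(-0.65, 0.65, 14)
    return profile, sample_umbrella_windows(
        profile, centers, bias_k=150.0, n_per_window=2000, seed=2024
    )


class TestWham:
    def test_single_weak_bias_window_reduces_to_histogram(self, th):
        """As the bias vanishes with one window, WHAM is plain histogramming."""
        rng = np.random.default_rng(5)
        samples = rng.normal(0.0, 0.25, size=4000)
        w = UmbrellaWindow(window_id=0, center=0.0, bias_k=1e-9, samples=samples)
        edges = np.linspace(-1.0, 1.0, 41)
        prof = wham([w], th, bins=edges)
        counts, _ = np.histogram(samples, bins=edges)
        occupied = counts > 0
        p_hist = counts[occupied] / counts.sum()
        p_wham = np.exp(-th.beta * prof.a_kcal)
        p_wham /= p_wham.sum()
        np.testing.assert_allclose(p_wham, p_hist, atol=1e-6)

    def test_flat_profile_single_window_flat_pmf(self, th):
        profile = ProfileSpec(form="table",
                              params={"z": [-5.0, 5.0], "a": [0.0, 0.0]},
                              temperature=th.temperature)
        (w,) = sample_umbrella_windows(profile, [0.0], bias_k=5.0,
                                       n_per_window=20000, seed=1)
        prof = wham([w], th, bins=40)
        # unbiasing the harmonic-window samples must return a flat profile
        # (to within correlated-chain histogram noise; min-shift excluded by
        # looking at the central peak-to-peak spread)
        inner = (prof.z > -0.4) & (prof.z < 0.4)
        assert np.ptp(prof.a_kcal[inner]) < 0.3

    def test_harmonic_profile_recovery(self, th):
        kappa = 20.0
        profile = ProfileSpec(form="harmonic", params={"kappa": kappa},
                              temperature=th.temperature)
        centers = np.linspace(-0.65, 0.65, 14)
        windows = sample_umbrella_windows(profile, centers, bias_k=150.0,
                                          n_per_window=2000, seed=77)
        prof = wham(windows, th)
        pooled = np.concatenate([w.samples for w in windows])
        lo, hi = np.percentile(pooled, [10.0, 90.0])
        m = (prof.z >= lo) & (prof.z <= hi)
        analytic = 0.5 * kappa * prof.z[m] ** 2
        offset = np.mean(prof.a_kcal[m] - analytic)
        rmse = np.sqrt(np.mean((prof.a_kcal[m] - analytic - offset) ** 2))
        assert rmse < 0.1

    def test_window_relabeling_invariance(self, double_well_windows, th):
        _, windows = double_well_windows
        edges = np.linspace(-0.9, 0.9, 61)
        prof1 = wham(windows, th, bins=edges)
        shuffled = [windows[i] for i in np.random.default_rng(0).permutation(len(windows))]
        prof2 = wham(shuffled, th, bins=edges)
        # agreement limited by the 1e-6 kcal/mol F_k convergence threshold
        np.testing.assert_allclose(prof2.a_kcal, prof1.a_kcal, atol=1e-4)

    def test_duplicated_windows_idempotent(self, double_well_windows, th):
        _, windows = double_well_windows
        edges = np.linspace(-0.9, 0.9, 61)
        prof1 = wham(windows, th, bins=edges)
        # duplicating the entire window set must leave the PMF unchanged
        prof2 = wham(list(windows) + list(windows), th, bins=edges)
        np.testing.assert_allclose(prof2.a_kcal, prof1.a_kcal, atol=1e-4)

    def test_mle_matches_iterative(self, double_well_windows, th):
        _, windows = double_well_windows
        edges = np.linspace(-0.9, 0.9, 61)
        prof_it = wham(windows, th, bins=edges)
        prof_ml = wham(windows, th, bins=edges, method="mle")
        np.testing.assert_allclose(prof_ml.a_kcal, prof_it.a_kcal, atol=5e-3)

    def test_max_iter_exhaustion_carries_partial(self, double_well_windows, th):
        _, windows = double_well_windows
        with pytest.raises(WHAMConvergenceError) as err:
            wham(windows, th, tol=1e-12, max_iter=3)
        assert isinstance(err.value.partial, PMFProfile)
        assert not err.value.partial.converged

    def test_non_overlapping_windows_warn(self, th):
        rng = np.random.default_rng(3)
        w1 = UmbrellaWindow(0, -1.0, 50.0, rng.normal(-1.0, 0.02, 500))
        w2 = UmbrellaWindow(1, 1.0, 50.0, rng.normal(1.0, 0.02, 500))
        with pytest.warns(UserWarning, match="ill-conditioned"):
            prof = wham([w1, w2], th, bins=40)
        assert prof.ill_conditioned


class TestBarrier:
    def test_double_well_barrier_recovered(self, double_well_windows, th):
        _, windows = double_well_windows
        prof = wham(windows, th)
        barrier = barrier_height(prof, reactant_range=(-0.7, -0.3))
        assert barrier == pytest.approx(6.0, abs=0.15)

    def test_monotone_profile_has_no_barrier(self):
        z = np.linspace(-1.0, 1.0, 50)
        prof = PMFProfile(
            z=z, a_kcal=10.0 * (z + 1.0), f_k=np.zeros(1),
            counts=np.ones((1, 50)), n_iter=1, residual=0.0, converged=True,
        )
        with pytest.raises(NoBarrierError):
            barrier_height(prof, reactant_range=(-1.0, -0.8))

    def test_gauge_invariance(self, double_well_windows, th):
        _, windows = double_well_windows
        prof = wham(windows, th)
        b1 = barrier_height(prof, (-0.7, -0.3))
        shifted = PMFProfile(
            z=prof.z, a_kcal=prof.a_kcal + 3.7, f_k=prof.f_k,
            counts=prof.counts, n_iter=prof.n_iter, residual=prof.residual,
            converged=prof.converged,
        )
        assert barrier_height(shifted, (-0.7, -0.3)) == pytest.approx(b1, rel=1e-12)


def test_windows_tsv_roundtrip(tmp_path, double_well_windows):
    _, windows = double_well_windows
    path = tmp_path / "windows.tsv"
    write_windows_tsv(path, windows)
    back = read_windows_tsv(path)
    assert len(back) == len(windows)
    np.testing.assert_allclose(back[3].samples, windows[3].samples, rtol=1e-9)
    assert back[3].center == windows[3].center
    assert back[3].bias_k == windows[3].bias_k
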