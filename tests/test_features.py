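"""Feature families against closed forms, brute-force oracles and invariants."""

import math

import numpy as np
import pytest
from scipy import stats

from copbench import CoPTrajectory, extract_all
from copbench.features import (
    CHI2_95_2D,
    compute_diffusion,
    dynamic_features,
    frequency_features,
    positional_features,
    stochastic_features,
)
from copbench.registry import FEATURES, FEATURE_NAMES, features_in_domain, resolve

FS = 100.0


def traj(ml, ap, fs=FS, **kwargs) -> CoPTrajectory:
    return CoPTrajectory(np.asarray(ml, float), np.asarray(ap, float), fs, **kwargs)


def circle(radius=0.4, freq=0.5, duration=16.0, fs=FS) -> CoPTrajectory:
    # integer number of cycles keeps the sample centroid at the center
    t = np.arange(int(duration * fs)) / fs
    w = 2 * np.pi * freq
    return traj(radius * np.cos(w * t), radius * np.sin(w * t), fs)


def sine_traj(amp=0.05, freq=1.0, duration=15.0, fs=FS) -> CoPTrajectory:
    t = np.arange(int(duration * fs)) / fs
    return traj(amp * np.sin(2 * np.pi * freq * t), np.zeros(t.size), fs)


class TestRegistry:
    def test_exactly_72_features(self):
        assert len(FEATURES) == 72
        assert len(set(FEATURE_NAMES)) == 72

    def test_domain_partition(self):
        counts = {d: len(features_in_domain(d)) for d in
                  ("positional", "dynamic", "frequency", "stochastic")}
        assert sum(counts.values()) == 72
        assert counts == {"positional": 15, "dynamic": 16,
                          "frequency": 20, "stochastic": 21}

    def test_aggregated_suffixes_resolve(self):
        spec = resolve("Maximal distance (Radius)—Average")
        assert spec.domain == "positional"
        spec = resolve("Short-term diffusion coefficient AP—Asymmetry")
        assert spec.domain == "stochastic" and spec.axis == "AP"

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            resolve("Sway entropy ML")


class TestPositional:
    def test_circle_geometry(self):
        """A centered circle of radius r: maximal distance r, RMS
        resultant r, per-axis range 2r."""
        r = 0.4
        feats = positional_features(circle(radius=r))
        assert feats["Maximal distance (Radius)"] == pytest.approx(r, rel=1e-3)
        assert feats["Root mean square ML-AP"] == pytest.approx(r, rel=1e-3)
        assert feats["Range ML"] == pytest.approx(2 * r, rel=1e-3)
        assert feats["Range ML-AP"] == pytest.approx(2 * r, rel=1e-3)

    def test_constant_trajectory_zero_dispersion(self):
        feats = positional_features(traj(np.full(100, 0.125), np.full(100, -0.25)))
        for name in ("Mean distance", "Root mean square ML", "Range AP",
                     "Maximal distance (Radius)", "95% confidence ellipse area",
                     "Planar deviation"):
            assert feats[name] == 0.0
        assert math.isnan(feats["Principal sway direction"])

    def test_ellipse_area_matches_closed_form(self, rng):
        """10k isotropic normal points, sigma=0.05: the 95% covariance
        ellipse area is within 5% of chi2_95 * pi * sigma^2."""
        sigma = 0.05
        pts = rng.normal(0, sigma, size=(10_000, 2))
        feats = positional_features(traj(pts[:, 0], pts[:, 1]))
        expected = CHI2_95_2D * math.pi * sigma**2
        assert feats["95% confidence ellipse area"] == pytest.approx(expected, rel=0.05)

    def test_principal_direction_tracks_elongation(self):
        t = np.arange(1000) / FS
        s = 0.2 * np.sin(2 * np.pi * 0.7 * t)
        feats = positional_features(traj(s, s))  # along the 45 degree diagonal
        assert feats["Principal sway direction"] == pytest.approx(45.0, abs=1.0)


class TestDynamic:
    def test_constant_trajectory_zero_velocities(self):
        feats = dynamic_features(traj(np.full(100, 0.1), np.full(100, 0.1)))
        for name in ("Mean Velocity ML", "Mean Velocity AP", "Mean Velocity ML-AP",
                     "Velocity standard deviation ML-AP", "Sway area per second ML-AP",
                     "Mean positive peak velocity ML", "Mean negative peak velocity AP"):
            assert feats[name] == 0.0

    def test_circle_mean_resultant_velocity_is_r_omega(self):
        r, freq = 0.3, 0.5
        feats = dynamic_features(circle(radius=r, freq=freq))
        expected = r * 2 * np.pi * freq
        assert feats["Mean Velocity ML-AP"] == pytest.approx(expected, rel=0.01)
        # rotational mean frequency recovers the traversal frequency
        assert feats["Mean frequency ML-AP"] == pytest.approx(freq, rel=0.01)

    def test_mean_velocity_equals_path_length_over_duration(self, rng):
        """Brute-force path-length oracle on random trajectories."""
        for _ in range(20):
            n = int(rng.integers(50, 300))
            ml = rng.uniform(-0.3, 0.3, n)
            ap = rng.uniform(-0.3, 0.3, n)
            feats = dynamic_features(traj(ml, ap))
            path = sum(
                math.hypot(ml[i + 1] - ml[i], ap[i + 1] - ap[i])
                for i in range(n - 1)
            )
            assert feats["Mean Velocity ML-AP"] == pytest.approx(
                path / ((n - 1) / FS), abs=1e-9
            )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            dynamic_features(traj([0.0, 0.1], [0.0, 0.1]))


class TestFrequency:
    def test_pure_tone_mode_and_bands(self):
        feats = frequency_features(sine_traj(freq=1.0))
        df = FS / 256  # Welch bin width at the default segment length
        assert abs(feats["Mode of Power Spectrum Density ML"] - 1.0) <= df
        assert feats["Energy content 0.5-2 Hz (Power Spectrum Density) ML"] >= 0.95
        assert feats["Energy content below 0.5 Hz (Power Spectrum Density) ML"] <= 0.05

    def test_band_fractions_partition_unity(self, pd_trial):
        feats = frequency_features(pd_trial.left)
        for axis in ("ML", "AP"):
            total = sum(
                feats[f"Energy content {band} (Power Spectrum Density) {axis}"]
                for band in ("below 0.5 Hz", "0.5-2 Hz", "above 2 Hz")
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_power_signal_gives_missing_band_features(self):
        feats = frequency_features(traj(np.full(1000, 0.25), np.full(1000, 0.125)))
        assert feats["Total power (Power Spectrum Density) ML"] == 0.0
        assert math.isnan(feats["Energy content below 0.5 Hz (Power Spectrum Density) ML"])
        assert math.isnan(feats["Mode of Power Spectrum Density AP"])

    def test_white_noise_modes_spread_uniformly(self):
        """Across seeded white-noise runs the PSD argmax lands uniformly
        over the spectrum (flat expected spectrum)."""
        modes = []
        for seed in range(200):
            g = np.random.default_rng(seed)
            x = np.clip(g.normal(0, 0.05, 1024), -0.45, 0.45)
            feats = frequency_features(traj(x, np.zeros(1024), fs=FS))
            modes.append(feats["Mode of Power Spectrum Density ML"])
        _, p = stats.kstest(np.asarray(modes) / (FS / 2), "uniform")
        assert p > 1e-3

    def test_spectral_quantiles_ordered(self, pd_trial):
        feats = frequency_features(pd_trial.left)
        assert feats["50% Power Frequency ML"] <= feats["95% Power Frequency ML"]


class TestStochastic:
    def test_brownian_short_term_diffusion_recovery(self):
        """MSD(dt) = 2 D dt for 1-D Brownian motion; the short-term fit
        recovers D (Monte-Carlo mean over replicates)."""
        d_true = 1e-4
        estimates = []
        for seed in range(30):
            g = np.random.default_rng(seed)
            x = np.cumsum(g.normal(0, math.sqrt(2 * d_true / FS), 1500))
            curve, _, _ = compute_diffusion(x, FS)
            estimates.append(curve.short_fit[0] / 2)
        assert np.mean(estimates) == pytest.approx(d_true, rel=0.15)

    def test_ballistic_scaling_exponent_is_one(self):
        x = 0.01 * np.arange(1500) / FS  # constant velocity
        _, h_short, _ = compute_diffusion(x, FS)
        assert h_short == pytest.approx(1.0, abs=0.05)

    def test_white_noise_scaling_exponent_is_zero(self):
        g = np.random.default_rng(4)
        x = g.normal(0, 0.05, 3000)
        _, h_short, _ = compute_diffusion(x, FS)
        assert abs(h_short) <= 0.1

    def test_critical_point_exists_for_saturating_sway(self, pd_trial):
        feats = stochastic_features(pd_trial.left)
        assert feats["Critical time ML-AP"] > 0
        assert feats["Critical displacement ML-AP"] > 0
        # persistent at short lags, anti-persistent at long lags
        assert feats["Short-term scaling exponent ML"] > feats["Long-term scaling exponent ML"]

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            compute_diffusion(np.zeros(100), FS)


class TestExtractAll:
    def test_vector_has_72_entries_in_registry_order(self, pd_trial):
        fv = extract_all(pd_trial.left)
        assert len(fv) == 72
        assert list(fv.values.index) == list(FEATURE_NAMES)
        assert int(fv.missing.sum()) == 0

    def test_determinism(self, pd_trial):
        a = extract_all(pd_trial.left)
        b = extract_all(pd_trial.left)
        assert a.values.equals(b.values)

    def test_short_trajectory_marks_stochastic_family_missing(self):
        g = np.random.default_rng(0)
        short = traj(g.uniform(-0.1, 0.1, 100), g.uniform(-0.1, 0.1, 100))
        fv = extract_all(short)
        stochastic_names = {s.name for s in features_in_domain("stochastic")}
        assert set(fv.errors) == stochastic_names
        assert fv.values[list(stochastic_names)].isna().all()
        assert not fv.values[[s.name for s in features_in_domain("positional")]].isna().any()


class TestInvariants:
    @staticmethod
    def deterministic_traj(scale=1.0) -> CoPTrajectory:
        t = np.arange(1500) / FS
        ml = scale * (0.04 * np.sin(2 * np.pi * 0.4 * t) + 0.02 * np.sin(2 * np.pi * 1.7 * t))
        ap = scale * (0.05 * np.sin(2 * np.pi * 0.3 * t + 1.0) + 0.015 * np.sin(2 * np.pi * 2.6 * t))
        return traj(ml, ap)

    def test_scale_monotonicity(self):
        """Scaling a centered trajectory by c scales lengths by c, the
        ellipse area by c^2, and leaves spectral fractions and scaling
        exponents unchanged."""
        c = 2.0
        base = extract_all(self.deterministic_traj(1.0)).values
        scaled = extract_all(self.deterministic_traj(c)).values
        linear = ["Mean distance", "Root mean square ML", "Range AP",
                  "Maximal distance (Radius)", "Mean Velocity ML-AP",
                  "Velocity standard deviation AP"]
        for name in linear:
            assert scaled[name] == pytest.approx(c * base[name], rel=1e-6)
        assert scaled["95% confidence ellipse area"] == pytest.approx(
            c**2 * base["95% confidence ellipse area"], rel=1e-6
        )
        invariant = ["Energy content below 0.5 Hz (Power Spectrum Density) ML",
                     "Energy content 0.5-2 Hz (Power Spectrum Density) AP",
                     "Short-term scaling exponent ML",
                     "Long-term scaling exponent AP",
                     "Principal sway direction",
                     "Mean frequency ML-AP"]
        for name in invariant:
            assert scaled[name] == pytest.approx(base[name], rel=1e-6)

    def test_axis_swap_symmetry(self, pd_trial):
        """Swapping the ML and AP channels swaps per-axis features exactly."""
        ml, ap = pd_trial.left.ml, pd_trial.left.ap
        centered_ml = np.clip(ml - ml.mean(), -0.45, 0.42)
        centered_ap = np.clip(ap - ap.mean(), -0.45, 0.42)
        base = extract_all(traj(centered_ml, centered_ap)).values
        swapped = extract_all(traj(centered_ap, centered_ml)).values
        for spec in FEATURES:
            if spec.axis == "ML":
                partner = spec.name.replace(" ML", " AP")
                assert swapped[partner] == base[spec.name]
            elif spec.axis == "AP":
                partner = spec.name.replace(" AP", " ML")
                assert swapped[partner] == base[spec.name]
        # resultant magnitudes are axis-order free
        assert swapped["Root mean square ML-AP"] == pytest.approx(
            base["Root mean square ML-AP"], rel=1e-12
        )

    def test_time_reversal(self, pd_trial):
        fwd = extract_all(pd_trial.left).values
        rev = extract_all(
            traj(pd_trial.left.ml[::-1], pd_trial.left.ap[::-1])
        ).values
        for name in ("Mean distance", "Root mean square AP", "Range ML",
                     "Maximal distance (Radius)", "95% confidence ellipse area",
                     "Mean Velocity ML", "Mean Velocity ML-AP",
                     "Sway area per second ML-AP"):
            assert rev[name] == pytest.approx(fwd[name], rel=1e-9)
        # reversal exchanges signed peak-velocity variants (sign-flipped)
        assert rev["Mean positive peak velocity ML"] == pytest.approx(
            -fwd["Mean negative peak velocity ML"], rel=1e-9
        )
        assert rev["Mean negative peak velocity AP"] == pytest.approx(
            -fwd["Mean positive peak velocity AP"], rel=1e-9
        )

    def test_brute_force_oracles(self, rng):
        """Mean velocity, path length, range and maximal distance agree
        with naive loops to 1e-9 on random trajectories."""
        for _ in range(100):
            n = int(rng.integers(20, 120))
            ml = rng.uniform(-0.3, 0.3, n)
            ap = rng.uniform(-0.3, 0.3, n)
            t = traj(ml, ap)
            pos = positional_features(t)
            dyn = dynamic_features(t)
            cx, cy = ml - ml.mean(), ap - ap.mean()
            max_dist = max(math.hypot(cx[i], cy[i]) for i in range(n))
            rng_ml = max(ml) - min(ml)
            path = sum(math.hypot(ml[i + 1] - ml[i], ap[i + 1] - ap[i])
                       for i in range(n - 1))
            mean_v = sum(abs(ml[i + 1] - ml[i]) * FS for i in range(n - 1)) / (n - 1)
            assert pos["Maximal distance (Radius)"] == pytest.approx(max_dist, abs=1e-9)
            assert pos["Range ML"] == pytest.approx(rng_ml, abs=1e-9)
            assert dyn["Mean Velocity ML-AP"] == pytest.approx(
                path * FS / (n - 1), abs=1e-9
            )
            assert dyn["Mean Velocity ML"] == pytest.approx(mean_v, abs=1e-9)
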