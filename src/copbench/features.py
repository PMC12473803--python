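"""Multi-domain CoP feature extraction: 72 descriptors per foot.

Four families are computed from a single :class:`~copbench.sensor_io.CoPTrajectory`:

positional
    Geometry of the mean-centered CoP cloud: mean/RMS/maximal
    distances, per-axis ranges, the 95% covariance confidence ellipse
    area and the principal sway direction.
dynamic
    Finite-difference velocity descriptors at the sampling rate: mean
    and peak velocities, speed variability, swept sway area per second,
    phase-plane dispersion and velocity-based mean sway frequencies.
frequency
    Welch power-spectral-density descriptors per axis: total power,
    mean/centroidal/mode/quantile frequencies, the high-to-low band
    quotient and energy fractions in the three bands at or below 0.5 Hz,
    0.5–2 Hz and above 2 Hz.
stochastic
    Stabilogram-diffusion analysis: mean squared displacement versus
    lag is fitted linearly in a short-term and a long-term window,
    giving diffusion coefficients, the critical point at the fit
    intersection, log–log scaling exponents and a fractal dimension.

All values stay in the insole's normalized, dimensionless coordinate
system; rates are per second.  A family whose preconditions fail
contributes designated missing values (NaN) rather than aborting the
vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from scipy.stats import chi2

from .registry import FEATURE_NAMES, features_in_domain
from .sensor_io import CoPTrajectory

__all__ = [
    "CHI2_95_2D",
    "WelchParams",
    "SpectralEstimate",
    "DiffusionWindows",
    "DiffusionCurve",
    "FeatureVector",
    "estimate_psd",
    "compute_diffusion",
    "positional_features",
    "dynamic_features",
    "frequency_features",
    "stochastic_features",
    "extract_all",
]

#: 95% quantile of the chi-squared distribution with 2 df, the scale
#: factor of the 95% covariance confidence ellipse.
CHI2_95_2D = float(chi2.ppf(0.95, df=2))  # 5.991...

_BAND_LOW = 0.5   # Hz
_BAND_HIGH = 2.0  # Hz


# ---------------------------------------------------------------------------
# helpers


def _centered(traj: CoPTrajectory) -> tuple[np.ndarray, np.ndarray]:
    return traj.ml - traj.ml.mean(), traj.ap - traj.ap.mean()


def _velocity_mask(traj: CoPTrajectory) -> np.ndarray:
    """Validity of each consecutive difference; bridges across segment
    breaks are excluded."""
    n = len(traj)
    mask = np.ones(n - 1, dtype=bool)
    for b in traj.breaks:
        if 0 < b <= n - 1:
            mask[b - 1] = False
    return mask


def _velocities(traj: CoPTrajectory) -> tuple[np.ndarray, np.ndarray]:
    mask = _velocity_mask(traj)
    vx = np.diff(traj.ml)[mask] * traj.fs
    vy = np.diff(traj.ap)[mask] * traj.fs
    return vx, vy


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Largest inter-sample distance; convex hull with a degenerate
    (collinear/constant) fallback."""
    if points.shape[0] < 2:
        return 0.0
    try:
        hull = points[ConvexHull(points).vertices]
        return float(pdist(hull).max())
    except Exception:
        centered = points - points.mean(axis=0)
        norms = np.linalg.norm(centered, axis=1)
        if norms.max() == 0:
            return 0.0
        direction = centered[int(norms.argmax())] / norms.max()
        proj = centered @ direction
        return float(np.ptp(proj))


def _mean_peaks(v: np.ndarray, sign: int) -> float:
    """Mean of positive local maxima (sign=+1) or negative local minima
    (sign=-1) of a signed velocity series; 0 when none qualify."""
    if v.size < 3:
        return 0.0
    peaks, _ = sps.find_peaks(sign * v)
    qualifying = v[peaks][sign * v[peaks] > 0]
    return float(qualifying.mean()) if qualifying.size else 0.0


# ---------------------------------------------------------------------------
# positional


def positional_features(traj: CoPTrajectory) -> dict[str, float]:
    """Dispersion and geometry of the mean-centered CoP cloud."""
    if len(traj) < 2:
        raise ValueError("positional features require at least 2 samples")
    x, y = _centered(traj)
    r = np.hypot(x, y)
    points = np.column_stack([x, y])

    cov = np.cov(x, y, ddof=1)
    det = max(float(np.linalg.det(cov)), 0.0)
    ellipse_area = CHI2_95_2D * math.pi * math.sqrt(det)

    if np.allclose(cov, 0.0):
        direction = float("nan")  # constant cloud: orientation undefined
    else:
        eigvals, eigvecs = np.linalg.eigh(cov)
        leading = eigvecs[:, int(np.argmax(eigvals))]
        direction = math.degrees(math.atan2(leading[1], leading[0])) % 180.0

    return {
        "Mean distance": float(r.mean()),
        "Mean distance ML": float(np.abs(x).mean()),
        "Mean distance AP": float(np.abs(y).mean()),
        "Root mean square ML": float(np.sqrt(np.mean(x**2))),
        "Root mean square AP": float(np.sqrt(np.mean(y**2))),
        "Root mean square ML-AP": float(np.sqrt(np.mean(r**2))),
        "Maximal distance (Radius)": float(r.max()),
        "Maximal distance ML": float(np.abs(x).max()),
        "Maximal distance AP": float(np.abs(y).max()),
        "Range ML": float(np.ptp(x)),
        "Range AP": float(np.ptp(y)),
        "Range ML-AP": _max_pairwise_distance(points),
        "95% confidence ellipse area": ellipse_area,
        "Principal sway direction": direction,
        "Planar deviation": float(np.sqrt(np.var(x, ddof=1) + np.var(y, ddof=1))),
    }


# ---------------------------------------------------------------------------
# dynamic


def dynamic_features(traj: CoPTrajectory) -> dict[str, float]:
    """Velocity-based descriptors from finite differences at ``fs``."""
    if len(traj) < 3:
        raise ValueError("dynamic features require at least 3 samples")
    x, y = _centered(traj)
    vx, vy = _velocities(traj)
    speed = np.hypot(vx, vy)
    duration_moved = vx.size / traj.fs  # time spanned by the valid differences

    mean_dist = float(np.hypot(x, y).mean())
    mean_dist_ml = float(np.abs(x).mean())
    mean_dist_ap = float(np.abs(y).mean())
    mv_ml = float(np.abs(vx).mean())
    mv_ap = float(np.abs(vy).mean())
    mv_res = float(speed.mean())

    # swept triangle areas of the centered position vector
    mask = _velocity_mask(traj)
    cross = np.abs(x[:-1] * y[1:] - x[1:] * y[:-1])[mask]
    sway_area = float(cross.sum() / 2.0 / duration_moved) if duration_moved else 0.0

    def _mfreq_axis(mv: float, md: float) -> float:
        return mv / (4.0 * math.sqrt(2.0) * md) if md > 0 else float("nan")

    mfreq_res = mv_res / (2.0 * math.pi * mean_dist) if mean_dist > 0 else float("nan")

    return {
        "Mean Velocity ML": mv_ml,
        "Mean Velocity AP": mv_ap,
        "Mean Velocity ML-AP": mv_res,
        "Mean positive peak velocity ML": _mean_peaks(vx, +1),
        "Mean positive peak velocity AP": _mean_peaks(vy, +1),
        "Mean negative peak velocity ML": _mean_peaks(vx, -1),
        "Mean negative peak velocity AP": _mean_peaks(vy, -1),
        "Velocity standard deviation ML": float(np.std(vx, ddof=1)),
        "Velocity standard deviation AP": float(np.std(vy, ddof=1)),
        "Velocity standard deviation ML-AP": float(np.std(speed, ddof=1)),
        "Sway area per second ML-AP": sway_area,
        "Phase plane parameter ML": float(np.sqrt(np.var(x, ddof=1) + np.var(vx, ddof=1))),
        "Phase plane parameter AP": float(np.sqrt(np.var(y, ddof=1) + np.var(vy, ddof=1))),
        "Mean frequency ML": _mfreq_axis(mv_ml, mean_dist_ml),
        "Mean frequency AP": _mfreq_axis(mv_ap, mean_dist_ap),
        "Mean frequency ML-AP": mfreq_res,
    }


# ---------------------------------------------------------------------------
# frequency


@dataclass(frozen=True)
class WelchParams:
    """Welch PSD estimation settings (field defaults for sway analysis)."""

    segment_length: int = 256
    overlap_fraction: float = 0.5
    window: str = "hann"
    detrend: str = "constant"


@dataclass
class SpectralEstimate:
    """One axis' PSD with the parameters that produced it."""

    frequencies: np.ndarray
    power: np.ndarray
    params: WelchParams

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("PSD values must be non-negative")
        if np.any(np.diff(self.frequencies) <= 0) or self.frequencies[0] != 0:
            raise ValueError("frequencies must ascend from 0")


def estimate_psd(x: np.ndarray, fs: float, params: WelchParams | None = None) -> SpectralEstimate:
    """Welch PSD of one axis; segment length is capped at half the series."""
    params = params or WelchParams()
    nperseg = min(params.segment_length, x.size // 2)
    if nperseg < 8:
        raise ValueError("trajectory too short for a PSD segment")
    freqs, power = sps.welch(
        x,
        fs=fs,
        window=params.window,
        nperseg=nperseg,
        noverlap=int(nperseg * params.overlap_fraction),
        detrend=params.detrend,
    )
    return SpectralEstimate(freqs, power, params)


def _axis_spectral_features(spec: SpectralEstimate) -> dict[str, float]:
    f = spec.frequencies
    p = spec.power.copy()
    keep = f > 0  # the DC bin carries no oscillatory information
    f, p = f[keep], p[keep]
    df = float(f[1] - f[0]) if f.size > 1 else 1.0
    bin_power = p * df
    total = float(bin_power.sum())

    nan = float("nan")
    # sway power is O(1e-4) in normalized units^2; anything at the
    # floating-rounding floor is a constant signal, not oscillation
    if total <= 1e-20:
        total = 0.0
    if total == 0.0:
        return {
            "total": 0.0, "mean_f": nan, "centroid_f": nan, "mode_f": nan,
            "f50": nan, "f95": nan, "quotient": nan,
            "frac_low": nan, "frac_mid": nan, "frac_high": nan,
        }

    weights = bin_power / total
    mean_f = float((f * weights).sum())
    centroid_f = float(np.sqrt((f**2 * weights).sum()))
    mode_f = float(f[int(np.argmax(p))])
    cumulative = np.cumsum(weights)
    f50 = float(f[int(np.searchsorted(cumulative, 0.50))])
    f95 = float(f[int(np.searchsorted(cumulative, 0.95))])

    low = float(bin_power[f <= _BAND_LOW].sum())
    mid = float(bin_power[(f > _BAND_LOW) & (f <= _BAND_HIGH)].sum())
    high = float(bin_power[f > _BAND_HIGH].sum())
    quotient = high / low if low > 0 else nan

    return {
        "total": total, "mean_f": mean_f, "centroid_f": centroid_f, "mode_f": mode_f,
        "f50": f50, "f95": f95, "quotient": quotient,
        "frac_low": low / total, "frac_mid": mid / total, "frac_high": high / total,
    }


def frequency_features(
    traj: CoPTrajectory, params: WelchParams | None = None
) -> dict[str, float]:
    """Per-axis Welch PSD descriptors for the ML and AP signals."""
    out: dict[str, float] = {}
    for axis, series in (("ML", traj.ml), ("AP", traj.ap)):
        spec = estimate_psd(series, traj.fs, params)
        vals = _axis_spectral_features(spec)
        out.update({
            f"Total power (Power Spectrum Density) {axis}": vals["total"],
            f"Mean frequency (Power Spectrum Density) {axis}": vals["mean_f"],
            f"Centroidal frequency (Power Spectrum Density) {axis}": vals["centroid_f"],
            f"Mode of Power Spectrum Density {axis}": vals["mode_f"],
            f"50% Power Frequency {axis}": vals["f50"],
            f"95% Power Frequency {axis}": vals["f95"],
            f"Frequency Quotient Power Spectrum Density {axis}": vals["quotient"],
            f"Energy content below 0.5 Hz (Power Spectrum Density) {axis}": vals["frac_low"],
            f"Energy content 0.5-2 Hz (Power Spectrum Density) {axis}": vals["frac_mid"],
            f"Energy content above 2 Hz (Power Spectrum Density) {axis}": vals["frac_high"],
        })
    return out


# ---------------------------------------------------------------------------
# stochastic (stabilogram diffusion)


@dataclass(frozen=True)
class DiffusionWindows:
    """Lag windows (seconds) of the two linear stabilogram-diffusion fits."""

    short: tuple[float, float] = (0.02, 0.3)
    long: tuple[float, float] = (1.0, 2.5)


@dataclass
class DiffusionCurve:
    """Mean squared displacement versus lag with the two linear fits."""

    lags: np.ndarray                 # seconds, ascending
    msd: np.ndarray                  # normalized units^2
    windows: DiffusionWindows
    short_fit: tuple[float, float]   # slope, intercept
    long_fit: tuple[float, float]
    critical_time: float
    critical_displacement: float

    def __post_init__(self) -> None:
        if np.any(self.msd < 0):
            raise ValueError("MSD must be non-negative")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must ascend")


def _msd(series: np.ndarray, max_lag: int) -> np.ndarray:
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        d = series[lag:] - series[:-lag]
        out[lag - 1] = np.mean(d * d)
    return out


def _window_fit(
    lags: np.ndarray, msd: np.ndarray, window: tuple[float, float]
) -> tuple[tuple[float, float], float]:
    """OLS fit of MSD ~ lag in the window plus the half log-log slope."""
    sel = (lags >= window[0]) & (lags <= window[1])
    if sel.sum() < 3:
        raise ValueError(f"diffusion fit window {window} has fewer than 3 lag points")
    slope, intercept = np.polyfit(lags[sel], msd[sel], 1)
    if np.all(msd[sel] > 0):
        h = float(np.polyfit(np.log(lags[sel]), np.log(msd[sel]), 1)[0] / 2.0)
    else:
        h = float("nan")
    return (float(slope), float(intercept)), h


def compute_diffusion(
    series: np.ndarray, fs: float, windows: DiffusionWindows | None = None
) -> tuple[DiffusionCurve, float, float]:
    """Stabilogram-diffusion curve of one series.

    Returns the curve plus the short- and long-window scaling exponents.
    The critical point is the intersection of the two linear fits; it is
    NaN when the fits do not cross at a positive lag (no saturation).
    """
    windows = windows or DiffusionWindows()
    max_lag = int(round(windows.long[1] * fs))
    if series.size <= max_lag + 1:
        raise ValueError(
            "series too short for stabilogram diffusion: needs more samples "
            f"than the long-window lag ({max_lag})"
        )
    lags = np.arange(1, max_lag + 1) / fs
    msd = _msd(np.asarray(series, dtype=float), max_lag)

    short_fit, h_short = _window_fit(lags, msd, windows.short)
    long_fit, h_long = _window_fit(lags, msd, windows.long)

    denom = short_fit[0] - long_fit[0]
    if denom > 0:
        t_c = (long_fit[1] - short_fit[1]) / denom
        d_c = short_fit[0] * t_c + short_fit[1]
        if t_c <= 0:
            t_c = d_c = float("nan")
    else:
        t_c = d_c = float("nan")

    curve = DiffusionCurve(lags, np.maximum(msd, 0.0), windows,
                           short_fit, long_fit, float(t_c), float(d_c))
    return curve, h_short, h_long


def stochastic_features(
    traj: CoPTrajectory, windows: DiffusionWindows | None = None
) -> dict[str, float]:
    """Diffusion coefficients, critical point, scaling exponents and
    fractal dimension per axis and for the planar (resultant) motion.

    The planar diffusion coefficient uses slope/4 (two degrees of
    freedom); per-axis coefficients use slope/2.  The fractal dimension
    is derived from the short-term scaling exponent as ``2 - H``.
    """
    out: dict[str, float] = {}
    x, y = _centered(traj)
    for axis, series, divisor in (("ML", x, 2.0), ("AP", y, 2.0), ("ML-AP", None, 4.0)):
        if series is None:
            # planar MSD is the sum of the per-axis MSDs; fit on the sum
            curve_x, _, _ = compute_diffusion(x, traj.fs, windows)
            curve_y, _, _ = compute_diffusion(y, traj.fs, windows)
            msd = curve_x.msd + curve_y.msd
            lags = curve_x.lags
            w = windows or DiffusionWindows()
            short_fit, h_short = _window_fit(lags, msd, w.short)
            long_fit, h_long = _window_fit(lags, msd, w.long)
            denom = short_fit[0] - long_fit[0]
            if denom > 0:
                t_c = (long_fit[1] - short_fit[1]) / denom
                d_c = short_fit[0] * t_c + short_fit[1]
                if t_c <= 0:
                    t_c = d_c = float("nan")
            else:
                t_c = d_c = float("nan")
        else:
            curve, h_short, h_long = compute_diffusion(series, traj.fs, windows)
            short_fit, long_fit = curve.short_fit, curve.long_fit
            t_c, d_c = curve.critical_time, curve.critical_displacement
        out.update({
            f"Short-term diffusion coefficient {axis}": short_fit[0] / divisor,
            f"Long-term diffusion coefficient {axis}": long_fit[0] / divisor,
            f"Critical time {axis}": t_c,
            f"Critical displacement {axis}": d_c,
            f"Short-term scaling exponent {axis}": h_short,
            f"Long-term scaling exponent {axis}": h_long,
            f"Fractal dimension {axis}": 2.0 - h_short if math.isfinite(h_short) else float("nan"),
        })
    return out


# ---------------------------------------------------------------------------
# assembly


@dataclass
class FeatureVector:
    """The ordered 72-feature mapping for one foot.

    ``values`` is a pandas Series indexed exactly by the registry names
    in registry order; missing entries (family error contracts) are NaN
    and flagged in ``missing``.
    """

    values: pd.Series
    errors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.values.index) != list(FEATURE_NAMES):
            raise ValueError("FeatureVector must carry exactly the 72 registry features in order")
        self.values = self.values.astype(float)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    @property
    def missing(self) -> pd.Series:
        return self.values.isna()


_FAMILY_FUNCS = {
    "positional": positional_features,
    "dynamic": dynamic_features,
    "frequency": frequency_features,
    "stochastic": stochastic_features,
}


def extract_all(traj: CoPTrajectory) -> FeatureVector:
    """Compute all four families and assemble the 72-feature vector.

    A family whose precondition fails (e.g. a series too short for the
    diffusion fit) contributes NaN for its features, with the reason
    recorded per feature in ``errors`` — never a silent drop.
    """
    collected: dict[str, float] = {}
    errors: dict[str, str] = {}
    for domain, func in _FAMILY_FUNCS.items():
        names = [s.name for s in features_in_domain(domain)]
        try:
            vals = func(traj)
        except ValueError as exc:
            for name in names:
                collected[name] = float("nan")
                errors[name] = str(exc)
            continue
        for name in names:
            collected[name] = vals[name]
    series = pd.Series([collected[n] for n in FEATURE_NAMES], index=list(FEATURE_NAMES))
    return FeatureVector(series, errors)
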