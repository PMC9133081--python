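"""Performance metrics and regression analyses for the simulation study.

Localization accuracy is the Euclidean distance between the identified
displacement-area centroid and the true territory centre.  Velocity-profile
fidelity is the zero-lag Pearson correlation between the spike-triggered
averaged profile and the simulated twitch.  The medio-lateral EMG-US
association is quantified with ordinary least squares: a simple regression
of the identified US centroid on the EMG amplitude centroid, and a multiple
regression ``Y = b1 + b2*x1 + b3*x2 + b4*x1*x2`` adding the identification
depth and its interaction with the EMG centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal, stats

from .tvs_sim import TwitchVelocityProfile

__all__ = [
    "RegressionModel",
    "localization_error",
    "profile_correlation",
    "reference_sta_profile",
    "profile_fidelity",
    "simple_regression",
    "multiple_regression",
    "bootstrap_median_ci",
    "summarize_study",
]


def localization_error(
    us_centroid_mm: tuple[float, float], true_center_mm: tuple[float, float]
) -> float:
    """Euclidean distance (mm) between identified centroid and territory centre."""
    dx = us_centroid_mm[0] - true_center_mm[0]
    dd = us_centroid_mm[1] - true_center_mm[1]
    return float(np.hypot(dx, dd))


def profile_correlation(
    profile_mean: np.ndarray,
    twitch: TwitchVelocityProfile,
    profile_lags_s: np.ndarray | None = None,
) -> float:
    """Zero-lag Pearson correlation between an STA profile and the twitch.

    Profiles are aligned at the firing instant: if ``profile_lags_s`` is given
    the segment from lag 0 onward is used, otherwise the profile is assumed to
    start at the firing instant.  Both series are truncated to the common span.
    """
    y = np.asarray(profile_mean, dtype=float)
    if profile_lags_s is not None:
        start = int(np.searchsorted(np.asarray(profile_lags_s), -0.5 / twitch.fps))
        y = y[start:]
    n = min(y.size, twitch.samples.size)
    if n < 3:
        raise ValueError("profiles too short to correlate")
    r, _ = stats.pearsonr(y[:n], twitch.samples[:n])
    return float(r)


def reference_sta_profile(
    spike_times_s: np.ndarray,
    twitch: TwitchVelocityProfile,
    duration_s: float,
    window_s: tuple[float, float] = (-0.025, 0.175),
    highpass_hz: float | None = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated velocity profile of one unit, processed like the identified one.

    The unit's noise-free velocity time course (spike train convolved with the
    twitch) is passed through the same zero-phase high-pass used to condition
    the movie, then spike-triggered averaged over the same window.  At firing
    rates where consecutive twitches overlap, this — not the bare twitch — is
    the profile a perfect identification would recover, so it is the reference
    for the study's profile-fidelity correlations.  Returns ``(mean, lags_s)``.
    """
    fps = twitch.fps
    n = int(round(duration_s * fps))
    idx = np.round(np.asarray(spike_times_s) * fps).astype(int)
    drive = np.zeros(n)
    np.add.at(drive, idx[(idx >= 0) & (idx < n)], 1.0)
    drive = np.convolve(drive, twitch.samples)[:n]
    if highpass_hz is not None:
        sos = signal.butter(2, highpass_hz, btype="highpass", fs=fps, output="sos")
        drive = signal.sosfiltfilt(sos, drive)
    lo = int(round(window_s[0] * fps))
    hi = int(round(window_s[1] * fps))
    usable = idx[(idx + lo >= 0) & (idx + hi < n)]
    if usable.size == 0:
        raise ValueError("no spikes with a full STA window")
    segs = np.stack([drive[k + lo : k + hi + 1] for k in usable])
    return segs.mean(axis=0), np.arange(lo, hi + 1) / fps


def profile_fidelity(identified_mean: np.ndarray, reference_mean: np.ndarray) -> float:
    """Zero-lag Pearson correlation between identified and reference profiles."""
    a = np.asarray(identified_mean, dtype=float)
    b = np.asarray(reference_mean, dtype=float)
    n = min(a.size, b.size)
    r, _ = stats.pearsonr(a[:n], b[:n])
    return float(r)


def simple_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Ordinary least squares of ``y`` on ``x``: (slope, intercept, R**2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(y) == 0.0:  # constant response: flat fit, no variance explained
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass(frozen=True)
class RegressionModel:
    """Fitted ``Y = b1 + b2*x1 + b3*x2 + b4*x1*x2`` with 95% CIs."""

    coef: np.ndarray  # (b1, b2, b3, b4)
    conf_int: np.ndarray  # (4, 2) lower/upper 95% bounds
    r_squared: float
    fitted: np.ndarray
    pvalues: np.ndarray


def multiple_regression(y: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> RegressionModel:
    """OLS of ``y`` (US medio-lateral centroid) on EMG centroid, depth and
    their interaction, with per-coefficient 95% confidence intervals."""
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if y.size < 5:
        raise ValueError("need at least 5 points")
    X = sm.add_constant(np.column_stack([x1, x2, x1 * x2]))
    fit = sm.OLS(y, X).fit()
    return RegressionModel(
        coef=np.asarray(fit.params),
        conf_int=np.asarray(fit.conf_int(alpha=0.05)),
        r_squared=float(fit.rsquared),
        fitted=np.asarray(fit.fittedvalues),
        pvalues=np.asarray(fit.pvalues),
    )


def bootstrap_median_ci(
    values: np.ndarray, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Seeded percentile-bootstrap confidence interval for the median."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    meds = np.median(
        values[rng.integers(0, values.size, size=(n_boot, values.size))], axis=1
    )
    a = (1.0 - level) / 2.0
    return float(np.quantile(meds, a)), float(np.quantile(meds, 1.0 - a))


def plot_study_summary(results: pd.DataFrame, path) -> None:
    """Three-panel study figure: EMG-US scatter, error and cc boxplots by level
    (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matched = results[results["matched"]]
    fig, axes = plt.subplots(3, 1, figsize=(5, 10))
    axes[0].scatter(matched["emg_x_mm"], matched["us_x_mm"], s=8, alpha=0.6)
    axes[0].set_xlabel("EMG centroid x (mm)")
    axes[0].set_ylabel("US centroid x (mm)")
    levels = sorted(matched["level"].unique())
    for ax, col, label in [
        (axes[1], "error_mm", "localization error (mm)"),
        (axes[2], "profile_cc", "profile cc"),
    ]:
        ax.boxplot(
            [matched[matched["level"] == lv][col].dropna() for lv in levels],
            tick_labels=[str(lv) for lv in levels],
        )
        ax.set_xlabel("contraction level")
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def summarize_study(results: pd.DataFrame, anova: bool = True) -> dict:
    """Per-level and pooled summaries of localization errors and profile ccs.

    ``results`` needs columns ``level``, ``matched``, ``error_mm``,
    ``profile_cc``.  Medians are over matched MUs only; unmatched counts are
    reported separately.  A one-way ANOVA across contraction levels is
    attached as a convenience when at least two levels are present.
    """
    matched = results[results["matched"]]
    per_level = (
        matched.groupby("level")
        .agg(
            n_matched=("error_mm", "size"),
            err_min=("error_mm", "min"),
            err_median=("error_mm", "median"),
            err_max=("error_mm", "max"),
            cc_median=("profile_cc", "median"),
        )
        .reset_index()
    )
    out = {
        "per_level": per_level,
        "n_total": int(len(results)),
        "n_matched": int(len(matched)),
        "n_unmatched": int((~results["matched"]).sum()),
        "median_error_mm": float(matched["error_mm"].median()),
        "median_profile_cc": float(matched["profile_cc"].median()),
    }
    levels = matched["level"].unique()
    if anova and levels.size >= 2:
        groups_err = [g["error_mm"].to_numpy() for _, g in matched.groupby("level")]
        groups_cc = [
            g["profile_cc"].dropna().to_numpy() for _, g in matched.groupby("level")
        ]
        f_err, p_err = stats.f_oneway(*groups_err)
        f_cc, p_cc = stats.f_oneway(*groups_cc)
        out["anova_error"] = {"F": float(f_err), "p": float(p_err)}
        out["anova_cc"] = {"F": float(f_cc), "p": float(p_cc)}
    return out
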