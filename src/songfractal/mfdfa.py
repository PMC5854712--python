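"""Multifractal detrended fluctuation analysis (MFDFA).

The analysis estimates how the detrended fluctuation of an integrated
series grows with window size.  For a series ``x`` of length ``N``:

1. integrate the mean-centered series into a random-walk profile
   ``Y(i) = sum_{k<=i} (x_k - <x>)``;
2. tile the profile with non-overlapping windows of length ``s`` from
   both ends (``2*floor(N/s)`` windows in total, so trailing samples are
   not discarded), fit an ordinary least-squares line in each window and
   keep the mean squared residual ``F2(v, s)``;
3. form the q-order fluctuation function
   ``F_q(s) = ( mean_v F2(v,s)^(q/2) )^(1/q)`` — the plain detrended RMS
   for ``q = 2``, emphasising small fluctuations for ``q < 2`` and large
   ones for ``q > 2``;
4. fit ``log F_q(s) ~ h(q) log s`` over a grid of scales; the slope
   ``h(q)`` is the generalized Hurst exponent.

A q-independent ``h`` indicates a monofractal (homogeneous) signal; the
spread ``width = max h(q) - min h(q)`` over the q grid is the scalar
multifractality measure used throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProfileSeries",
    "HQSpectrum",
    "default_scales",
    "default_q_grid",
    "integrate_profile",
    "windowed_residuals",
    "q_fluctuation",
    "hurst_spectrum",
    "spectrum_width",
]


@dataclass(frozen=True)
class ProfileSeries:
    """Integrated (cumulative-sum) profile of a mean-centered series."""

    values: np.ndarray
    source_length: int

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.source_length


@dataclass(frozen=True)
class HQSpectrum:
    """Generalized Hurst exponents h(q) with fit diagnostics.

    Attributes
    ----------
    q : ndarray
        The (strictly positive, increasing) q grid.
    h : ndarray
        OLS slope of log F_q(s) against log s, one per q.
    intercepts, r2 : ndarray
        Per-q log-log fit intercepts and coefficients of determination.
    scales : ndarray
        Window sizes (samples) the fit used.
    """

    q: np.ndarray
    h: np.ndarray
    intercepts: np.ndarray
    r2: np.ndarray
    scales: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def width(self) -> float:
        """Multifractal spectrum width, max h(q) - min h(q)."""
        return float(np.max(self.h) - np.min(self.h))


def default_scales(n: int, n_scales: int = 19, s_min: int = 10,
                   s_max: int | None = None) -> np.ndarray:
    """Log-spaced integer window sizes in [s_min, N/4].

    Log spacing equalizes leverage across the log-log fit; duplicate
    integers arising from rounding are dropped.
    """
    if s_max is None:
        s_max = n // 4
    if s_max < s_min:
        raise ValueError(
            f"series too short for scale range: N={n} gives max scale "
            f"{s_max} < minimum scale {s_min}"
        )
    raw = np.logspace(np.log10(s_min), np.log10(s_max), n_scales)
    scales = np.unique(np.round(raw).astype(int))
    return scales


def default_q_grid(q_min: float = 0.1, q_max: float = 5.0,
                   q_step: float = 0.1) -> np.ndarray:
    """Strictly positive q grid, default 0.1 to 5.0 in steps of 0.1."""
    n = int(round((q_max - q_min) / q_step)) + 1
    qs = q_min + q_step * np.arange(n)
    if qs[0] <= 0:
        raise ValueError("q grid must be strictly positive")
    return qs


def integrate_profile(x) -> ProfileSeries:
    """Cumulative sum of the mean-centered series (random-walk profile)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("input must be a 1-D series of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    y = np.cumsum(x - x.mean())
    return ProfileSeries(values=y, source_length=x.size)


def _window_matrix(y: np.ndarray, s: int) -> np.ndarray:
    """Stack the 2*floor(N/s) forward+backward windows as rows."""
    n = y.size
    n_s = n // s
    fwd = y[: n_s * s].reshape(n_s, s)
    bwd = y[n - n_s * s:].reshape(n_s, s)
    return np.vstack([fwd, bwd])


def windowed_residuals(profile: ProfileSeries | np.ndarray, s: int) -> np.ndarray:
    """Mean squared residual of a linear fit in each window of length s.

    Windows tile the profile from the start and, to use the trailing
    samples when N is not a multiple of s, again from the end: the
    result has 2*floor(N/s) entries.
    """
    y = profile.values if isinstance(profile, ProfileSeries) else np.asarray(profile, float)
    n = y.size
    s = int(s)
    if s < 10 or s > n // 4:
        raise ValueError(f"scale s={s} outside valid range [10, N/4={n // 4}]")
    windows = _window_matrix(y, s)
    t = np.arange(s, dtype=float)
    design = np.column_stack([np.ones(s), t])
    # normal-equations pseudoinverse, computed once per scale; the 2x2
    # system is perfectly conditioned for a linear fit on 0..s-1
    pinv = np.linalg.solve(design.T @ design, design.T)
    resid = windows.T - design @ (pinv @ windows.T)
    return np.mean(resid**2, axis=0)


def q_fluctuation(f2_by_window, q: float) -> float:
    """q-order fluctuation: (mean of F2^(q/2))^(1/q); RMS when q = 2."""
    f2 = np.asarray(f2_by_window, dtype=float)
    if q <= 0:
        raise ValueError("q must be strictly positive")
    if np.any(f2 < 0):
        raise ValueError("squared residuals must be non-negative")
    return float(np.mean(f2 ** (q / 2.0)) ** (1.0 / q))


def hurst_spectrum(x, qs=None, scales=None) -> HQSpectrum:
    """Generalized Hurst exponents h(q) of a series over a scale grid.

    Parameters
    ----------
    x : array-like
        The series to analyse (not yet integrated).
    qs : array-like, optional
        Positive q grid; defaults to 0.1..5.0 step 0.1.
    scales : array-like, optional
        Integer window sizes; defaults to 19 log-spaced scales in
        [10, N/4].

    Raises
    ------
    ValueError
        On constant (zero-variance) input, or when a fluctuation
        function vanishes at some scale so the log-log fit is undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 40:
        raise ValueError("series too short for MFDFA (need N >= 40)")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance series")
    qs = default_q_grid() if qs is None else np.asarray(qs, dtype=float)
    if qs.size < 1 or np.any(qs <= 0) or np.any(np.diff(qs) <= 0):
        raise ValueError("q grid must be strictly positive and increasing")
    if scales is None:
        scales = default_scales(x.size)
    scales = np.asarray(scales, dtype=int)

    profile = integrate_profile(x)
    log_s = np.log(scales.astype(float))
    # F_q(s) for every (q, s) pair from the shared per-scale residuals
    log_fq = np.empty((qs.size, scales.size))
    half_q = qs[:, None] * 0.5
    for j, s in enumerate(scales):
        f2 = windowed_residuals(profile, s)
        # f2^(q/2) via exp(q/2 * log f2); exact zeros map to exp(-inf) = 0
        with np.errstate(divide="ignore"):
            log_f2 = np.log(f2)
        fq = np.mean(np.exp(half_q * log_f2[None, :]), axis=1) ** (1.0 / qs)
        if np.any(fq <= 0):
            raise ValueError(
                "fluctuation function vanished (perfectly detrendable "
                "series); spectrum width is undefined"
            )
        log_fq[:, j] = np.log(fq)

    h = np.empty(qs.size)
    intercepts = np.empty(qs.size)
    r2 = np.empty(qs.size)
    for i in range(qs.size):
        slope, intercept = np.polyfit(log_s, log_fq[i], 1)
        fit = slope * log_s + intercept
        ss_res = np.sum((log_fq[i] - fit) ** 2)
        ss_tot = np.sum((log_fq[i] - log_fq[i].mean()) ** 2)
        h[i] = slope
        intercepts[i] = intercept
        r2[i] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return HQSpectrum(q=qs, h=h, intercepts=intercepts, r2=r2, scales=scales)


def spectrum_width(spectrum: HQSpectrum) -> float:
    """Multifractal spectrum width max h(q) - min h(q) (>= 0)."""
    if spectrum.q.size < 2:
        raise ValueError("need at least two q values for a width")
    return spectrum.width
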