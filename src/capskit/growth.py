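"""Growth-constant (k_G) estimation from complemented-yeast growth curves.

A yeast strain lacking its own sulfate transporters grows on sulfate as
sole sulfur source only through a heterologously expressed transporter.
When growth is limited by substrate uptake, the exponential growth rate
tracks the transporter's influx rate, so the rate–concentration isotherm
is Michaelis–Menten shaped and its half-saturation constant — the growth
constant k_G, the substrate concentration at half-maximal growth rate —
approximates the transporter's apparent k_M without radiotracers.

Pipeline: per concentration, fit A600(t) = A600(t0)·e^(k·t) on an
automatically selected exponential window (linear regression of ln OD on
time); convert k to a growth rate in doubling times per hour,
rate = k/ln 2; fit rate(S) = k_max·S/(k_G + S) by weighted nonlinear
least squares.  k_G is invariant to the rate convention (the 1/ln 2
factor only rescales k_max).

The method is valid only while uptake limits growth; the three checks of
:func:`check_transport_limitation` (flat internal substrate store over
external concentration, faster growth on an organic sulfur source, near
-empty store after growth without substrate) guard that assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ComputationError, ValidationError

LN2 = float(np.log(2.0))


@dataclass
class GrowthCurve:
    """Optical-density time series at one substrate concentration.

    ``od`` has shape (n_times, n_replicates); a 1-D array is promoted to a
    single replicate.
    """

    substrate_conc: float  # µM
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # A600 readings

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim == 1:
            self.od = self.od[:, None]
        if self.times.size < 4:
            raise ValidationError("growth curve needs >= 4 time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if self.od.shape[0] != self.times.size:
            raise ValidationError("od rows must match number of time points")
        if np.any(self.od < 0):
            raise ValidationError("optical densities must be >= 0")
        if self.substrate_conc < 0:
            raise ValidationError("substrate concentration must be >= 0")

    @property
    def n_replicates(self) -> int:
        return self.od.shape[1]


@dataclass
class ExpFit:
    """Exponential-phase fit A600(t) = A0·e^(k·t)."""

    k: float  # h^-1
    A0: float
    window: tuple[int, int]  # [start, stop) indices of the fitted points
    r2: float
    se_k: float


@dataclass
class RateIsotherm:
    """Growth rate (dt^-1, h^-1) versus substrate concentration (µM)."""

    conc: np.ndarray
    rate: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if len({len(self.conc), len(self.rate), len(self.se)}) != 1:
            raise ValidationError("isotherm arrays must have equal length")
        if len(np.unique(self.conc)) != len(self.conc):
            raise ValidationError("one isotherm entry per concentration")
        if np.any(self.rate < 0):
            raise ValidationError("growth rates must be >= 0")


@dataclass
class MMFit:
    """Michaelis–Menten fit of the rate isotherm."""

    k_max: float  # maximal growth rate, dt^-1 h^-1
    k_G: float  # µM, substrate concentration at half-maximal growth rate
    se_kmax: float
    se_kG: float
    rss: float
    n: int

    def predict(self, S):
        S = np.asarray(S, dtype=float)
        return self.k_max * S / (self.k_G + S)


@dataclass
class LimitationReport:
    """Validity checks for the uptake-limited-growth assumption."""

    internal_store_flat: bool
    organic_source_faster: bool | None
    zero_substrate_store_low: bool
    overall_valid: bool
    details: dict = field(default_factory=dict)


def _linfit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS of y on t: slope, intercept, r², slope SE."""
    n = t.size
    tm, ym = t.mean(), y.mean()
    sxx = float(np.sum((t - tm) ** 2))
    sxy = float(np.sum((t - tm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * tm
    resid = y - (intercept + slope * t)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-300 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    se = np.sqrt(ss_res / (n - 2) / sxx) if n > 2 else np.inf
    return slope, intercept, r2, se


def fit_exponential(
    times: Sequence[float] | GrowthCurve,
    od: Sequence[float] | None = None,
    window: tuple[int, int] | None = None,
    min_points: int = 4,
    min_r2: float = 0.98,
    method: str = "loglinear",
) -> ExpFit:
    """Fit A600(t) = A0·e^(k·t) to one replicate's OD trace.

    With no explicit ``window``, the longest contiguous run of >=
    ``min_points`` positive-OD points whose log-linear r² exceeds
    ``min_r2`` is selected (ties at the same length go to the highest
    r²), then endpoints are greedily trimmed while trimming improves r²
    — the trim removes residual lag or plateau points that a long
    exponential span would otherwise mask.  A perfectly flat trace fits
    exactly with k = 0.  ``method='nls'`` refits the selected window by
    direct nonlinear least squares on the exponential form.
    """
    if isinstance(times, GrowthCurve):
        if times.n_replicates != 1:
            raise ValidationError(
                "fit_exponential takes a single replicate; pass times/od arrays"
            )
        times, od = times.times, times.od[:, 0]
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if window is not None:
        lo, hi = window
        if hi - lo < min_points:
            raise ValidationError(f"window {window} shorter than {min_points} points")
        if np.any(y[lo:hi] <= 0):
            raise ValidationError("optical density must be > 0 inside the fit window")
        best = (lo, hi)
    else:
        best = _auto_window(t, y, min_points, min_r2)
        if best is None:
            raise ComputationError(
                "no exponential phase detected: no contiguous window of "
                f">= {min_points} positive-OD points reaches r^2 >= {min_r2}"
            )
        best = _trim_window(t, y, *best, min_points)
    lo, hi = best
    slope, intercept, r2, se = _linfit(t[lo:hi], np.log(y[lo:hi]))
    k, A0 = slope, float(np.exp(intercept))
    if method == "nls":
        popt, _ = optimize.curve_fit(
            lambda tt, a0, kk: a0 * np.exp(kk * tt),
            t[lo:hi], y[lo:hi], p0=[A0, k], maxfev=10000,
        )
        A0, k = float(popt[0]), float(popt[1])
    elif method != "loglinear":
        raise ValidationError(f"unknown method {method!r}")
    return ExpFit(k=float(k), A0=A0, window=(lo, hi), r2=float(r2), se_k=float(se))


def _auto_window(t, y, min_points, min_r2):
    n = t.size
    positive = y > 0
    # longest windows first; first length with any qualifying window wins
    for length in range(n, min_points - 1, -1):
        candidates = []
        for lo in range(0, n - length + 1):
            hi = lo + length
            if not positive[lo:hi].all():
                continue
            _, _, r2, _ = _linfit(t[lo:hi], np.log(y[lo:hi]))
            if r2 >= min_r2:
                candidates.append((r2, lo, hi))
        if candidates:
            _, lo, hi = max(candidates)
            return lo, hi
    return None


def _trim_window(t, y, lo, hi, min_points):
    """Greedily drop an endpoint while doing so improves log-linear r²."""

    def r2(a, b):
        return _linfit(t[a:b], np.log(y[a:b]))[2]

    current = r2(lo, hi)
    while hi - lo > min_points:
        drop_left = (r2(lo + 1, hi), lo + 1, hi)
        drop_right = (r2(lo, hi - 1), lo, hi - 1)
        best = max(drop_left, drop_right)
        if best[0] > current:
            current, lo, hi = best
        else:
            break
    return lo, hi


def growth_rate(fit: ExpFit | float) -> float:
    """Growth rate in doubling times per hour: rate = k / ln 2 = 1/dt.

    A negative k (declining culture) is clamped to rate 0 with a warning.
    """
    k = fit.k if isinstance(fit, ExpFit) else float(fit)
    if k < 0:
        warnings.warn(f"negative exponential rate k={k:.4g}: clamping rate to 0",
                      stacklevel=2)
        return 0.0
    return k / LN2


def doubling_time(fit: ExpFit | float) -> float:
    """Duplication time dt = ln 2 / k (hours); infinite for k <= 0."""
    k = fit.k if isinstance(fit, ExpFit) else float(fit)
    return LN2 / k if k > 0 else np.inf


def hanes_woolf_init(conc: np.ndarray, rate: np.ndarray) -> tuple[float, float]:
    """Initial (k_max, k_G) from the Hanes–Woolf linearization S/v vs S."""
    mask = (rate > 0) & (conc > 0)
    if mask.sum() < 2:
        return float(np.max(rate)), float(np.median(conc[conc > 0]))
    S, v = conc[mask], rate[mask]
    slope, intercept, _, _ = _linfit(S, S / v)
    if slope <= 0:
        return float(np.max(rate)), float(np.median(S))
    k_max = 1.0 / slope
    k_G = max(intercept * k_max, 1e-6)
    return float(k_max), float(k_G)


def fit_mm(
    isotherm: RateIsotherm,
    include_zero: bool = False,
    weighted: bool = True,
) -> MMFit:
    """Weighted nonlinear least-squares fit of rate(S) = k_max·S/(k_G + S).

    Replicate-mean rates enter once per concentration, weighted by the
    inverse variance of the mean when standard errors are available
    (``weighted=True`` and all SEs finite and positive).  The S = 0 point
    is excluded by default: residual growth without substrate reflects
    internal stores, not transport.  Standard errors of the parameters
    come from the linearized covariance of the fit.
    """
    mask = np.ones(len(isotherm.conc), dtype=bool)
    if not include_zero:
        mask &= isotherm.conc > 0
    S = isotherm.conc[mask]
    v = isotherm.rate[mask]
    se = isotherm.se[mask]
    if S.size == 0 or not np.any(v > 0):
        raise ComputationError("cannot fit Michaelis-Menten: no positive rates")
    if S.size < 4:
        warnings.warn(
            f"only {S.size} concentrations in the fit; >= 4 recommended",
            stacklevel=2,
        )
    p0 = hanes_woolf_init(S, v)
    sigma = None
    if weighted and np.all(np.isfinite(se)) and np.all(se > 0):
        sigma = se
    try:
        popt, pcov = optimize.curve_fit(
            lambda s, kmax, kg: kmax * s / (kg + s),
            S, v, p0=p0, sigma=sigma,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ComputationError(
            f"Michaelis-Menten fit did not converge (init k_max={p0[0]:.4g}, "
            f"k_G={p0[1]:.4g}; concentrations {S.tolist()})"
        ) from exc
    k_max, k_G = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    resid = v - k_max * S / (k_G + S)
    fit = MMFit(
        k_max=k_max, k_G=k_G,
        se_kmax=float(perr[0]), se_kG=float(perr[1]),
        rss=float(np.sum(resid**2)), n=int(S.size),
    )
    if k_G < S.min() or k_G > S.max():
        warnings.warn(
            f"k_G = {k_G:.3g} uM lies outside the measured concentration range "
            f"[{S.min():.3g}, {S.max():.3g}]; estimate may be poorly constrained",
            stacklevel=2,
        )
    return fit


def classify_affinity(fit: MMFit, threshold_uM: float = 100.0) -> str:
    """'high' iff k_G <= threshold (µM, boundary inclusive), else 'low'.

    Micromolar k_G marks a high-affinity transporter; sub-millimolar to
    millimolar constants mark the low-affinity class.
    """
    return "high" if fit.k_G <= threshold_uM else "low"


def build_isotherm(
    curves: Sequence[GrowthCurve],
    window: tuple[int, int] | None = None,
    min_points: int = 4,
    min_r2: float = 0.98,
) -> RateIsotherm:
    """Per-concentration growth rates from a set of growth curves.

    Each replicate trace is fitted independently; the isotherm entry is
    the replicate mean rate with its standard error (zero SE for a single
    replicate).  A trace with no detectable exponential phase *and* less
    than half a doubling of net growth over the whole assay (a flat,
    non-growing culture — typical at zero substrate) is assigned rate 0;
    a trace that grows but never looks exponential still raises.
    """
    conc, rate, se = [], [], []
    for curve in curves:
        rates = []
        for j in range(curve.n_replicates):
            try:
                f = fit_exponential(
                    curve.times, curve.od[:, j], window=window,
                    min_points=min_points, min_r2=min_r2,
                )
            except ComputationError:
                y = curve.od[:, j]
                if np.all(y > 0):
                    slope, _, _, _ = _linfit(curve.times, np.log(y))
                    if slope * (curve.times[-1] - curve.times[0]) < LN2 / 2:
                        rates.append(0.0)
                        continue
                raise
            rates.append(growth_rate(f))
        rates = np.asarray(rates)
        conc.append(curve.substrate_conc)
        rate.append(float(rates.mean()))
        se.append(
            float(rates.std(ddof=1) / np.sqrt(rates.size)) if rates.size > 1 else 0.0
        )
    order = np.argsort(conc)
    return RateIsotherm(
        conc=np.asarray(conc)[order],
        rate=np.asarray(rate)[order],
        se=np.asarray(se)[order],
    )


def estimate_kg(
    curves: Sequence[GrowthCurve],
    window: tuple[int, int] | None = None,
    include_zero: bool = False,
    weighted: bool = True,
    threshold_uM: float = 100.0,
) -> tuple[RateIsotherm, MMFit, str]:
    """Full pipeline: growth curves -> rate isotherm -> (k_max, k_G).

    Returns the isotherm, the Michaelis–Menten fit, and the affinity
    class ('high'/'low').
    """
    isotherm = build_isotherm(curves, window=window)
    fit = fit_mm(isotherm, include_zero=include_zero, weighted=weighted)
    return isotherm, fit, classify_affinity(fit, threshold_uM)


def check_transport_limitation(
    store_external_conc: Sequence[float],
    store_values: Sequence[float],
    organic_rate: float | None,
    max_substrate_rate: float,
    zero_substrate_store: float,
    store_threshold: float = 0.05,
    alpha: float = 0.05,
) -> LimitationReport:
    """Run the three validity checks for k_G ≈ k_M.

    1. *internal_store_flat* — the internal substrate store per A600 unit
       shows no significant monotone trend over external concentration
       (Spearman rank test at ``alpha``).  Accumulation would mean
       assimilation, not uptake, limits growth.
    2. *organic_source_faster* — growth on an organic sulfur source beats
       the fastest substrate-fed growth (strictly), showing downstream
       metabolism is not the bottleneck.  ``organic_rate=None`` marks the
       check indeterminate and invalidates the report.
    3. *zero_substrate_store_low* — the store after growth without
       substrate stays below ``store_threshold`` (nmol per A600 unit),
       ruling out a pre-existing internal reserve.
    """
    S = np.asarray(store_external_conc, dtype=float)
    store = np.asarray(store_values, dtype=float)
    if S.size < 3 or S.size != store.size:
        raise ValidationError(
            "internal-store table needs >= 3 matched external concentrations"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input yields nan correlation
        rho, p = stats.spearmanr(S, store)
    flat = not (np.isfinite(p) and p < alpha)
    details = {"spearman_rho": float(rho), "spearman_p": float(p),
               "max_substrate_rate": float(max_substrate_rate),
               "zero_substrate_store": float(zero_substrate_store),
               "store_threshold": float(store_threshold)}
    if organic_rate is None:
        faster: bool | None = None
        details["reason"] = "organic-sulfur-source control missing: indeterminate"
    else:
        faster = bool(organic_rate > max_substrate_rate)
        details["organic_rate"] = float(organic_rate)
    store_low = bool(zero_substrate_store < store_threshold)
    overall = bool(flat and (faster is True) and store_low)
    return LimitationReport(
        internal_store_flat=bool(flat),
        organic_source_faster=faster,
        zero_substrate_store_low=store_low,
        overall_valid=overall,
        details=details,
    )
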