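"""Parameter estimation from measured signal-vs-b curves.

Four fitters mirror the quantities a multi-b liver DWI protocol reports:

* ``fit_mem_two_point``  — closed-form ADC from b = 0 and the highest b
  (ADC2 in the two-b protocol, b = 0/800 s/mm^2 by default);
* ``fit_mem_loglinear``  — ADC from ordinary least squares of ln S on all
  b-values (ADC10 for the 10-b scheme);
* ``fit_ivim_segmented`` — segmented ("asymptotic") IVIM: D from a log-linear
  fit over the high-b points where perfusion has decayed, then D* and f by
  bounded nonlinear least squares with D frozen;
* ``fit_sem``            — bounded nonlinear least squares of the stretched
  exponential, initialized from the log-linear ADC.

All fitters are deterministic: fixed initialization rules and no random
restarts, so the same curve always yields the same estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .signal_models import (
    BiExpParams,
    BValueScheme,
    MonoExpParams,
    StretchedExpParams,
    bem_signal,
    mem_signal,
    sem_signal,
)

__all__ = [
    "SignalCurve",
    "FitConfig",
    "FitResult",
    "fit_mem_two_point",
    "fit_mem_loglinear",
    "fit_ivim_segmented",
    "fit_ivim_free",
    "fit_sem",
    "fit_all_models",
]


@dataclass(frozen=True)
class SignalCurve:
    """A measured signal-attenuation curve: one signal value per b-value."""

    scheme: BValueScheme
    signals: tuple[float, ...]

    def __post_init__(self) -> None:
        sig = tuple(float(s) for s in self.signals)
        if len(sig) != len(self.scheme):
            raise ValueError(
                f"{len(sig)} signals for {len(self.scheme)} b-values"
            )
        if np.any(np.asarray(sig) < 0):
            raise ValueError("signals must be non-negative")
        if not sig[0] > 0:
            raise ValueError("signal at b=0 must be positive")
        object.__setattr__(self, "signals", sig)

    @property
    def b(self) -> np.ndarray:
        return self.scheme.as_array()

    @property
    def s(self) -> np.ndarray:
        return np.asarray(self.signals, dtype=float)


@dataclass(frozen=True)
class FitConfig:
    """Tunable fitting options.

    segmentation_threshold
        b-value (s/mm^2) at and above which the perfusion compartment is
        treated as fully decayed; must be a member of the scheme.  Default
        200: with D* around 33e-3 mm^2/s the pseudo-diffusion term has
        decayed by exp(-6.6) there.
    Bounds are wide enough for liver physiology without clipping reported
    group values; f is capped at 0.5 (higher fractions in parenchyma mean
    vessel contamination, not perfusion).
    """

    segmentation_threshold: float = 200.0
    d_bounds: tuple[float, float] = (0.0, 5e-3)
    dstar_bounds: tuple[float, float] = (3e-3, 500e-3)
    f_bounds: tuple[float, float] = (0.0, 0.5)
    ddc_bounds: tuple[float, float] = (0.0, 5e-3)
    alpha_bounds: tuple[float, float] = (1e-6, 1.0)
    xtol: float = 1e-12
    ftol: float = 1e-12
    max_iterations: int = 1000
    # optional seeded multi-start for the iterative fits: n_starts extra
    # initializations drawn uniformly inside the bounds, best RSS wins.
    # 0 keeps the single deterministic initialization rule.
    n_starts: int = 0
    multistart_seed: int = 0

    def validate_against(self, scheme: BValueScheme) -> None:
        if self.segmentation_threshold not in scheme.values:
            raise ValueError(
                f"segmentation threshold {self.segmentation_threshold} is not "
                f"a member of the b-value scheme {scheme.values}"
            )


@dataclass(frozen=True)
class FitResult:
    """Outcome of one model fit.

    ``flags`` carries non-fatal conditions ("clamped_negative_adc",
    "not_converged", "dstar_at_bound", "alpha_at_bound", ...) so callers can
    filter without exception handling.
    """

    model: str  # MEM2 | MEM10 | BEM | SEM
    params: MonoExpParams | BiExpParams | StretchedExpParams
    rss: float
    converged: bool
    flags: tuple[str, ...] = ()


def fit_mem_two_point(curve: SignalCurve) -> FitResult:
    """Closed-form two-point ADC: ln(S(0)/S(b_max)) / b_max.

    Uses the first (b = 0) and last point of the curve's scheme; with the
    default study scheme that is b = 0 and 800 s/mm^2.  A rising signal
    (S(b_max) > S(0)) would give negative ADC; it is clamped to 0 and
    flagged.
    """
    s0, smax = curve.s[0], curve.s[-1]
    bmax = curve.b[-1]
    if smax <= 0:
        raise ValueError("two-point ADC requires positive signal at the high b-value")
    adc = float(np.log(s0 / smax) / bmax)
    flags: tuple[str, ...] = ()
    if adc < 0:
        adc = 0.0
        flags = ("clamped_negative_adc",)
    params = MonoExpParams(S0=float(s0), ADC=adc)
    fitted = mem_signal(params, np.asarray([0.0, bmax]))
    rss = float(np.sum((np.asarray([s0, smax]) - fitted) ** 2))
    return FitResult("MEM2", params, rss, True, flags)


def _loglinear(b: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """OLS of ln s on b; returns (intercept ln S0, slope)."""
    if np.any(s <= 0):
        raise ValueError("log-linear fit requires strictly positive signals")
    slope, intercept = np.polyfit(b, np.log(s), 1)
    return float(intercept), float(slope)


def fit_mem_loglinear(curve: SignalCurve) -> FitResult:
    """ADC from OLS of ln S on b over the whole scheme (slope = -ADC)."""
    if len(curve.scheme) == 2:
        # OLS through two points is interpolation; identical to the
        # closed-form two-point estimator.
        return replace(fit_mem_two_point(curve), model="MEM10")
    intercept, slope = _loglinear(curve.b, curve.s)
    adc = -slope
    flags: tuple[str, ...] = ()
    if adc < 0:
        adc = 0.0
        flags = ("clamped_negative_adc",)
    params = MonoExpParams(S0=float(np.exp(intercept)), ADC=adc)
    rss = float(np.sum((curve.s - mem_signal(params, curve.b)) ** 2))
    return FitResult("MEM10", params, rss, True, flags)


def _ls_flags(res) -> tuple[bool, tuple[str, ...]]:
    converged = bool(res.success)
    return converged, () if converged else ("not_converged",)


def _best_least_squares(residuals, x0, lo, hi, cfg: FitConfig):
    """Bounded least squares from the rule-based init, optionally repeated
    from ``cfg.n_starts`` seeded random inits inside the bounds."""
    inits = [np.asarray(x0, dtype=float)]
    if cfg.n_starts > 0:
        rng = np.random.default_rng(cfg.multistart_seed)
        lo_a, hi_a = np.asarray(lo, dtype=float), np.asarray(hi, dtype=float)
        span = np.where(np.isfinite(hi_a), hi_a - lo_a, 10.0)
        for _ in range(cfg.n_starts):
            inits.append(lo_a + rng.random(len(lo_a)) * span)
    best = None
    for x in inits:
        res = least_squares(
            residuals, np.clip(x, lo, hi), bounds=(lo, hi),
            xtol=cfg.xtol, ftol=cfg.ftol, gtol=None,
            max_nfev=cfg.max_iterations,
        )
        if best is None or res.cost < best.cost:
            best = res
    return best


def fit_ivim_segmented(curve: SignalCurve, cfg: FitConfig | None = None) -> FitResult:
    """Segmented IVIM fit: D first from high b, then D* and f with D fixed.

    Step 1: log-linear fit of the points with b >= ``segmentation_threshold``
    gives D (and the extrapolated high-b intercept).  Step 2: with D frozen,
    (S0, f, D*) are estimated by bounded nonlinear least squares of the full
    bi-exponential over all b-values.
    """
    cfg = cfg or FitConfig()
    cfg.validate_against(curve.scheme)
    b, s = curve.b, curve.s
    if np.any(s <= 0):
        raise ValueError("IVIM fit requires strictly positive signals")
    high = b >= cfg.segmentation_threshold
    if high.sum() < 2:
        raise ValueError(
            f"need >= 2 b-values at or above {cfg.segmentation_threshold} s/mm^2"
        )

    intercept_hi, slope_hi = _loglinear(b[high], s[high])
    d = float(np.clip(-slope_hi, *cfg.d_bounds))

    # f0 from the intercept gap between the measured b=0 signal and the
    # extrapolated diffusion-only compartment.
    s0_meas = s[0]
    f0 = float(np.clip(1.0 - np.exp(intercept_hi) / s0_meas, *cfg.f_bounds))
    dstar0 = float(np.clip(10.0 * max(d, 1e-4), *cfg.dstar_bounds))

    def residuals(theta: np.ndarray) -> np.ndarray:
        s0, f, dstar = theta
        model = s0 * (f * np.exp(-b * dstar) + (1.0 - f) * np.exp(-b * d))
        return model - s

    lo = [s0_meas * 0.2, cfg.f_bounds[0], cfg.dstar_bounds[0]]
    hi = [s0_meas * 5.0, cfg.f_bounds[1], cfg.dstar_bounds[1]]
    res = _best_least_squares(residuals, [s0_meas, f0, dstar0], lo, hi, cfg)
    s0_fit, f_fit, dstar_fit = map(float, res.x)
    converged, flags = _ls_flags(res)
    if dstar_fit <= cfg.dstar_bounds[0] * (1 + 1e-9) or dstar_fit >= cfg.dstar_bounds[1] * (1 - 1e-9):
        flags += ("dstar_at_bound",)
    # keep D < Dstar identifiable even when the optimizer pins Dstar low
    if dstar_fit <= d:
        dstar_fit = np.nextafter(d, np.inf)
        flags += ("dstar_below_d",)
    params = BiExpParams(S0=s0_fit, D=d, Dstar=dstar_fit, f=f_fit)
    rss = float(np.sum((s - bem_signal(params, b)) ** 2))
    return FitResult("BEM", params, rss, converged, flags)


def fit_ivim_free(curve: SignalCurve, cfg: FitConfig | None = None) -> FitResult:
    """Non-segmented IVIM: simultaneous bounded fit of (S0, D, f, D*).

    Config variant of :func:`fit_ivim_segmented`; less stable at ten points
    (D and f trade off), kept off the default path.  Initialized from the
    segmented fit's step-1 quantities.
    """
    cfg = cfg or FitConfig()
    cfg.validate_against(curve.scheme)
    b, s = curve.b, curve.s
    if np.any(s <= 0):
        raise ValueError("IVIM fit requires strictly positive signals")
    high = b >= cfg.segmentation_threshold
    intercept_hi, slope_hi = _loglinear(b[high], s[high])
    d0 = float(np.clip(-slope_hi, *cfg.d_bounds))
    s0_meas = s[0]
    f0 = float(np.clip(1.0 - np.exp(intercept_hi) / s0_meas, *cfg.f_bounds))
    dstar0 = float(np.clip(10.0 * max(d0, 1e-4), *cfg.dstar_bounds))

    def residuals(theta: np.ndarray) -> np.ndarray:
        s0, d, f, dstar = theta
        return s0 * (f * np.exp(-b * dstar)
                     + (1.0 - f) * np.exp(-b * d)) - s

    lo = [s0_meas * 0.2, cfg.d_bounds[0], cfg.f_bounds[0], cfg.dstar_bounds[0]]
    hi = [s0_meas * 5.0, cfg.d_bounds[1], cfg.f_bounds[1], cfg.dstar_bounds[1]]
    res = _best_least_squares(residuals, [s0_meas, d0, f0, dstar0], lo, hi, cfg)
    s0_fit, d_fit, f_fit, dstar_fit = map(float, res.x)
    converged, flags = _ls_flags(res)
    if dstar_fit <= d_fit:
        dstar_fit = np.nextafter(d_fit, np.inf)
        flags += ("dstar_below_d",)
    params = BiExpParams(S0=s0_fit, D=d_fit, Dstar=dstar_fit, f=f_fit)
    rss = float(np.sum((s - bem_signal(params, b)) ** 2))
    return FitResult("BEM", params, rss, converged, flags)


def fit_sem(curve: SignalCurve, cfg: FitConfig | None = None) -> FitResult:
    """Bounded nonlinear least squares of the stretched-exponential model.

    Initialized from the log-linear ADC (DDC0 = ADC, alpha0 = 0.9); alpha is
    constrained to (0, 1] and flagged when it lands on the boundary (a
    mono-exponential curve legitimately fits with alpha = 1).
    """
    cfg = cfg or FitConfig()
    b, s = curve.b, curve.s
    if np.any(s <= 0):
        raise ValueError("SEM fit requires strictly positive signals")

    adc0 = fit_mem_loglinear(curve).params.ADC
    s0_meas = s[0]

    def residuals(theta: np.ndarray) -> np.ndarray:
        s0, ddc, alpha = theta
        model = s0 * np.exp(-np.power(b * ddc, alpha))
        return model - s

    lo = [s0_meas * 0.2, cfg.ddc_bounds[0], cfg.alpha_bounds[0]]
    hi = [s0_meas * 5.0, cfg.ddc_bounds[1], cfg.alpha_bounds[1]]
    res = _best_least_squares(residuals, [s0_meas, max(adc0, 1e-5), 0.9],
                              lo, hi, cfg)
    s0_fit, ddc_fit, alpha_fit = map(float, res.x)
    converged, flags = _ls_flags(res)
    if alpha_fit >= cfg.alpha_bounds[1] - 1e-9 or alpha_fit <= cfg.alpha_bounds[0] + 1e-9:
        flags += ("alpha_at_bound",)
    alpha_fit = float(np.clip(alpha_fit, np.nextafter(0.0, 1.0), 1.0))
    params = StretchedExpParams(S0=s0_fit, DDC=ddc_fit, alpha=alpha_fit)
    rss = float(np.sum((s - sem_signal(params, b)) ** 2))
    return FitResult("SEM", params, rss, converged, flags)


def fit_all_models(curve: SignalCurve, cfg: FitConfig | None = None) -> dict[str, FitResult]:
    """Run all four fitters on one curve; MEM2 uses b = {0, b_max} only."""
    cfg = cfg or FitConfig()
    two_point = SignalCurve(
        BValueScheme((curve.b[0], curve.b[-1])),
        (curve.signals[0], curve.signals[-1]),
    )
    return {
        "MEM2": fit_mem_two_point(two_point),
        "MEM10": fit_mem_loglinear(curve),
        "BEM": fit_ivim_segmented(curve, cfg),
        "SEM": fit_sem(curve, cfg),
    }
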