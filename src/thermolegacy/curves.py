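"""Sigmoid fitting: asymmetric 5-parameter melting fits (T_d), double-sigmoid
step fits for rigidity unfolding curves, and the transition-selection rule.

The 5-parameter family is the Richards-type asymmetric logistic

    f(T) = y0 + a / (1 + exp(-(T - t0) / b))**c

whose maximum-slope temperature is ``t0 + b*log(c)`` (equal to ``t0`` in the
symmetric ``c = 1`` limit).  T_d is reported at that point; its uncertainty
comes from the fit covariance via the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit


@dataclass(frozen=True)
class MeltingCurve:
    temperature: np.ndarray   # degC, strictly increasing
    signal: np.ndarray        # ellipticity, millidegrees
    out_of_range: bool = False  # set by generators when the true midpoint
                                # lies outside the scan window

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        if t.size < 10:
            raise ValueError("melting curve needs at least 10 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")


@dataclass(frozen=True)
class SigmoidFit:
    params: tuple[float, ...] | None   # (y0, a, t0, b, c)
    td: float | None
    td_sd: float | None
    converged: bool
    rss: float


@dataclass(frozen=True)
class DoubleSigmoidFit:
    transitions: tuple[tuple[float, float], ...]  # (T, |slope|) ordered by T
    rss: float
    converged: bool
    single: bool = False    # only one resolvable step


@dataclass(frozen=True)
class TpChoice:
    tp: float
    slope: float
    rule: str   # largest-slope | second-transition-td-rule | single-transition


def sigmoid5(t, y0, a, t0, b, c):
    # stable form of y0 + a / (1 + exp(-(t - t0)/b))**c
    return y0 + a * np.exp(-c * np.logaddexp(0.0, -(np.asarray(t) - t0) / b))


def _sigmoid4(t, y0, a, t0, b):
    return sigmoid5(t, y0, a, t0, b, 1.0)


def fit_sigmoid5(curve: MeltingCurve, fix_asymmetry: bool = False) -> SigmoidFit:
    """Least-squares 5PL fit with deterministic multi-start initialisation.

    Starts are seeded from five quantiles of the temperature range.  Fits
    that fail, produce an amplitude indistinguishable from the residual
    noise, or put T_d outside the scan window are reported unconverged.
    """
    t = np.asarray(curve.temperature, dtype=float)
    s = np.asarray(curve.signal, dtype=float)
    span = float(np.ptp(s))
    if span == 0.0:
        return SigmoidFit(None, None, None, False, float(np.sum((s - s.mean()) ** 2)))

    trange = float(np.ptp(t))
    a0 = float(s[-1] - s[0])
    y0_0 = float(s[0])
    best = None
    for q in (0.3, 0.4, 0.5, 0.6, 0.7):
        t0_0 = float(t[0] + q * trange)
        if fix_asymmetry:
            p0 = [y0_0, a0, t0_0, trange / 15.0]
            bounds = ([-np.inf, -np.inf, t[0] - 2 * trange, 1e-3],
                      [np.inf, np.inf, t[-1] + 2 * trange, 5 * trange])
            model = _sigmoid4
        else:
            p0 = [y0_0, a0, t0_0, trange / 15.0, 1.0]
            bounds = ([-np.inf, -np.inf, t[0] - 2 * trange, 1e-3, 1e-3],
                      [np.inf, np.inf, t[-1] + 2 * trange, 5 * trange, 50.0])
            model = sigmoid5
        try:
            popt, pcov = curve_fit(model, t, s, p0=p0, bounds=bounds,
                                   maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((s - model(t, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
        if rss < (1e-6 * span) ** 2 * t.size:
            break  # essentially exact; further starts cannot help

    if best is None:
        return SigmoidFit(None, None, None, False, np.inf)
    popt, pcov, rss = best
    if fix_asymmetry:
        popt = np.append(popt, 1.0)
        pcov = np.pad(pcov, ((0, 1), (0, 1)))
    y0, a, t0, b, c = (float(v) for v in popt)

    # amplitude must exceed the residual scale to count as a transition
    rms = np.sqrt(rss / t.size)
    if abs(a) < 4.0 * rms:
        return SigmoidFit(tuple(popt), None, None, False, rss)

    td = t0 + b * np.log(c)
    if not (t[0] - 1e-6 <= td <= t[-1] + 1e-6):
        return SigmoidFit(tuple(popt), None, None, False, rss)

    td_sd = None
    if np.all(np.isfinite(pcov)):
        grad = np.array([0.0, 0.0, 1.0, np.log(c), b / c])
        var = float(grad @ pcov @ grad)
        if var >= 0:
            td_sd = float(np.sqrt(var))
    return SigmoidFit(tuple(float(v) for v in popt), float(td), td_sd,
                      True, rss)


# ---------------------------------------------------------------------------
# double sigmoid (unfolding steps)
# ---------------------------------------------------------------------------

def _double(t, base, a1, t1, w1, a2, t2, w2):
    return base + a1 * expit((t - t1) / w1) + a2 * expit((t - t2) / w2)


def _single(t, base, a1, t1, w1):
    return base + a1 * expit((t - t1) / w1)


def fit_double_sigmoid(t, h) -> DoubleSigmoidFit:
    """Fit a sum of (up to) two logistic steps to an increasing step-like
    series, initialised from the two largest discrete jumps.

    A second step is kept only when its fitted amplitude is resolvable above
    5% of the data range and its centre is separated from the first by more
    than two grid steps; otherwise a single-step fit is returned, flagged.
    """
    t = np.asarray(t, dtype=float)
    h = np.asarray(h, dtype=float)
    if t.size < 15 or h.size != t.size:
        raise ValueError("need at least 15 paired points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    span = float(np.ptp(h))
    if span == 0.0:
        return DoubleSigmoidFit((), 0.0, False)

    dt = float(np.median(np.diff(t)))
    jumps = np.diff(h)
    order = np.argsort(jumps)[::-1]
    i1 = int(order[0])
    i2 = None
    for idx in order[1:]:
        if abs(t[idx] - t[i1]) > 2 * dt and jumps[idx] > 0:
            i2 = int(idx)
            break

    base0 = float(h[0])
    t1_0 = float(0.5 * (t[i1] + t[i1 + 1]))
    lo_t, hi_t = t[0] - np.ptp(t), t[-1] + np.ptp(t)
    w_lo, w_hi = dt / 10.0, float(np.ptp(t))

    single_fit = None
    try:
        p0 = [base0, max(span, 1e-9), t1_0, dt / 2.0]
        popt, _ = curve_fit(_single, t, h, p0=p0,
                            bounds=([-np.inf, 0, lo_t, w_lo],
                                    [np.inf, np.inf, hi_t, w_hi]),
                            maxfev=20000)
        rss = float(np.sum((h - _single(t, *popt)) ** 2))
        single_fit = (popt, rss)
    except (RuntimeError, ValueError):
        pass

    double_fit = None
    if i2 is not None:
        t2_0 = float(0.5 * (t[i2] + t[i2 + 1]))
        a1_0 = max(float(jumps[i1]), 1e-9)
        a2_0 = max(float(jumps[i2]), 1e-9)
        try:
            p0 = [base0, a1_0, t1_0, dt / 2.0, a2_0, t2_0, dt / 2.0]
            popt, _ = curve_fit(_double, t, h, p0=p0,
                                bounds=([-np.inf, 0, lo_t, w_lo, 0, lo_t, w_lo],
                                        [np.inf, np.inf, hi_t, w_hi,
                                         np.inf, hi_t, w_hi]),
                                maxfev=30000)
            rss = float(np.sum((h - _double(t, *popt)) ** 2))
            double_fit = (popt, rss)
        except (RuntimeError, ValueError):
            pass

    if double_fit is not None:
        base, a1, t1, w1, a2, t2, w2 = double_fit[0]
        resolvable = (min(a1, a2) > 0.05 * span and abs(t2 - t1) > 2 * dt)
        if resolvable:
            trans = sorted([(float(t1), float(a1 / (4 * w1))),
                            (float(t2), float(a2 / (4 * w2)))])
            return DoubleSigmoidFit(tuple(trans), double_fit[1], True, False)

    if single_fit is not None:
        base, a1, t1, w1 = single_fit[0]
        if a1 > 0.05 * span:
            trans = ((float(t1), float(a1 / (4 * w1))),)
            return DoubleSigmoidFit(trans, single_fit[1], True, True)
    return DoubleSigmoidFit((), np.inf, False)


TD_RULE_THRESHOLD_C = 50.0


def select_tp(fit: DoubleSigmoidFit, td: float | None = None) -> TpChoice:
    """Pick the phase-transition temperature from a converged step fit.

    Default: the transition with the largest absolute slope.  When a
    denaturation temperature above 50 degC is supplied and two transitions
    exist, the second (higher-T) transition is taken instead.
    """
    if not fit.converged or not fit.transitions:
        raise ValueError("no transitions to select from")
    trans = fit.transitions
    if len(trans) == 1:
        return TpChoice(tp=trans[0][0], slope=trans[0][1],
                        rule="single-transition")
    if td is not None and td > TD_RULE_THRESHOLD_C:
        return TpChoice(tp=trans[-1][0], slope=trans[-1][1],
                        rule="second-transition-td-rule")
    i = int(np.argmax([abs(s) for _, s in trans]))
    return TpChoice(tp=trans[i][0], slope=trans[i][1], rule="largest-slope")
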