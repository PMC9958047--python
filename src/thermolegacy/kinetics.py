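"""Absorbance kinetics to specific activities and thermal activity profiles.

The specific activity of one assay is computed from the initial slope of the
absorbance trace:

    rate [umol/min/mg] = (slope [AU/min] / epsilon) * (1 / path_cm)
                         * 1e6 * volume_L / protein_mg

The initial window is the longest prefix of the trace whose linear fit keeps
R^2 >= 0.98 (minimum 5 points, or the whole trace when shorter).  Negative
slopes are clipped to zero activity and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_EPSILON = 4147.0      # M-1 cm-1 (4-nitrophenol at 348 nm)
DEFAULT_PATH_CM = 0.4
DEFAULT_VOLUME_L = 0.0002


@dataclass(frozen=True)
class RateResult:
    rate: float               # umol min-1 mg-1
    slope: float              # AU/min as fitted
    window_points: int
    clipped: bool             # slope was negative beyond tolerance


@dataclass(frozen=True)
class ThermalProfile:
    temperatures: np.ndarray        # degC, ascending
    rate_mean: np.ndarray
    rate_sd: np.ndarray
    relative_activity: np.ndarray   # percent of the maximum mean rate
    replicate_rates: tuple[tuple[float, ...], ...]  # per temperature
    all_zero: bool


@dataclass(frozen=True)
class ToptResult:
    topt: float
    topt_sd: float | None     # across replicate argmaxes
    method: str               # "argmax"
    tie: bool


def _linfit_r2(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    tm, ym = t.mean(), y.mean()
    sxx = np.sum((t - tm) ** 2)
    slope = np.sum((t - tm) * (y - ym)) / sxx
    resid = y - (ym + slope * (t - tm))
    tss = np.sum((y - ym) ** 2)
    r2 = 1.0 if tss == 0 else 1.0 - np.sum(resid ** 2) / tss
    return float(slope), float(r2)


def initial_rate(time_min, absorbance, *, epsilon: float = DEFAULT_EPSILON,
                 path_cm: float = DEFAULT_PATH_CM,
                 volume_l: float = DEFAULT_VOLUME_L,
                 protein_mg: float, r2_threshold: float = 0.98,
                 min_points: int = 5) -> RateResult:
    """Specific activity from one blank-corrected absorbance trace."""
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(absorbance, dtype=float)
    if t.size < 3 or y.size != t.size:
        raise ValueError("need at least 3 paired time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    for name, val in (("epsilon", epsilon), ("path_cm", path_cm),
                      ("volume_l", volume_l), ("protein_mg", protein_mg)):
        if val <= 0:
            raise ValueError(f"{name} must be positive")

    m = min(min_points, t.size)
    slope, _ = _linfit_r2(t[:m], y[:m])
    window = m
    for end in range(m + 1, t.size + 1):
        s, r2 = _linfit_r2(t[:end], y[:end])
        if r2 < r2_threshold:
            break
        slope, window = s, end

    clipped = slope < -1e-12
    eff_slope = max(slope, 0.0)
    rate = (eff_slope / epsilon) / path_cm * 1e6 * volume_l / protein_mg
    return RateResult(rate=float(rate), slope=float(slope),
                      window_points=window, clipped=clipped)


def build_profile(rates_by_temperature: dict[float, list[float]]
                  ) -> ThermalProfile:
    """Replicate means, SDs and percent-of-maximum relative activities."""
    if len(rates_by_temperature) < 2:
        raise ValueError("need rates at >=2 temperatures to build a profile")
    temps = np.array(sorted(rates_by_temperature), dtype=float)
    reps = tuple(tuple(float(r) for r in rates_by_temperature[t]) for t in temps)
    if any(len(r) == 0 for r in reps):
        raise ValueError("every temperature needs at least one replicate")
    means = np.array([np.mean(r) for r in reps])
    sds = np.array([np.std(r, ddof=1) if len(r) > 1 else 0.0 for r in reps])
    peak = means.max()
    if peak <= 0:
        warnings.warn("all rates are zero; relative activities set to 0")
        rel = np.zeros_like(means)
        return ThermalProfile(temps, means, sds, rel, reps, all_zero=True)
    rel = 100.0 * means / peak
    return ThermalProfile(temps, means, sds, rel, reps, all_zero=False)


def find_topt(profile: ThermalProfile) -> ToptResult:
    """Temperature of maximum mean activity on the tested grid.

    Ties resolve to the lowest temperature (flagged).  The SD is taken
    across per-replicate argmax temperatures when replicate counts agree.
    """
    if profile.all_zero:
        raise ValueError("profile has no activity; T_opt undefined")
    means = profile.rate_mean
    peak = means.max()
    at_peak = np.isclose(means, peak)
    idx = int(np.argmax(at_peak))  # first (lowest T) among ties
    tie = int(at_peak.sum()) > 1

    topt_sd = None
    n_reps = {len(r) for r in profile.replicate_rates}
    if len(n_reps) == 1 and n_reps != {1}:
        k = n_reps.pop()
        per_rep = []
        for j in range(k):
            col = np.array([r[j] for r in profile.replicate_rates])
            per_rep.append(profile.temperatures[int(np.argmax(col))])
        topt_sd = float(np.std(per_rep, ddof=1))
    return ToptResult(topt=float(profile.temperatures[idx]), topt_sd=topt_sd,
                      method="argmax", tie=tie)


def profile_from_assay_frame(frame, *, epsilon: float = DEFAULT_EPSILON,
                             path_cm: float = DEFAULT_PATH_CM,
                             volume_l: float = DEFAULT_VOLUME_L,
                             protein_mg: float) -> ThermalProfile:
    """Build a profile from a tidy assay table with columns
    temperature_C, replicate, time_min, absorbance."""
    rates: dict[float, list[float]] = {}
    for (temp, _rep), grp in frame.groupby(["temperature_C", "replicate"]):
        res = initial_rate(grp["time_min"].to_numpy(),
                           grp["absorbance"].to_numpy(),
                           epsilon=epsilon, path_cm=path_cm,
                           volume_l=volume_l, protein_mg=protein_mg)
        rates.setdefault(float(temp), []).append(res.rate)
    return build_profile(rates)
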