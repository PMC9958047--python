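"""Synthetic input generation with known ground truth.

Every generator draws from ``numpy.random.default_rng`` keyed on the config
seed plus a fixed per-stream tag, so identical configs give byte-identical
outputs, and every generated object carries the true parameter it was built
from so downstream recovery can be tested without real measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .curves import MeltingCurve
from .rigidity.network import Bar, BarType, ConstraintNetwork

# stream tags keep the per-generator RNGs independent of each other
_STREAMS = {
    "sites": 1, "assay": 2, "melt": 3, "network": 4, "logger": 5, "growth": 6,
}


def _rng(cfg: "GenConfig", stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stream], extra])


@dataclass(frozen=True)
class GenConfig:
    seed: int = 0
    n_sites: int = 14
    relation: str = "linear"          # linear | piecewise
    intercept: float = 12.0           # degC of T_opt at MAT = 0
    slope_before: float = 1.0
    slope_after: float = 1.0          # only used for piecewise
    breakpoint: float = 27.7          # degC (MAT axis)
    noise_sd: float = 0.0             # degC on topt_true
    assay_noise_sd: float = 0.0       # absorbance units
    mat_range: tuple[float, float] = (-1.4, 29.5)
    melt_noise_frac: float = 0.0      # noise SD as fraction of amplitude

    def __post_init__(self):
        if self.relation not in ("linear", "piecewise"):
            raise ValueError("relation must be 'linear' or 'piecewise'")
        if self.noise_sd < 0 or self.assay_noise_sd < 0 or self.melt_noise_frac < 0:
            raise ValueError("noise SDs must be non-negative")
        lo, hi = self.mat_range
        if self.relation == "piecewise" and not (lo < self.breakpoint < hi):
            raise ValueError("breakpoint must lie strictly inside mat_range")


@dataclass(frozen=True)
class SiteTruth:
    site_id: str
    MAT: float
    pH: float
    salinity: float
    topt_true: float
    td_true: float
    variability_class: str = "none"


def gen_site_dataset(cfg: GenConfig) -> list[SiteTruth]:
    """Sites with MAT drawn uniformly over ``mat_range`` and topt_true linear
    (or continuous-piecewise) in MAT plus Gaussian noise; pH and salinity are
    drawn independently of the response."""
    rng = _rng(cfg, "sites")
    lo, hi = cfg.mat_range
    mat = np.sort(rng.uniform(lo, hi, cfg.n_sites))
    topt = cfg.intercept + cfg.slope_before * mat
    if cfg.relation == "piecewise":
        topt = topt + (cfg.slope_after - cfg.slope_before) * np.maximum(
            mat - cfg.breakpoint, 0.0)
    topt = topt + rng.normal(0.0, cfg.noise_sd, cfg.n_sites)
    td = topt + 8.0 + rng.normal(0.0, 0.5 * cfg.noise_sd, cfg.n_sites)
    ph = rng.normal(8.0, 0.2, cfg.n_sites)
    sal = rng.normal(38.0, 2.0, cfg.n_sites)
    return [
        SiteTruth(site_id=f"S{i:03d}", MAT=float(mat[i]), pH=float(ph[i]),
                  salinity=float(sal[i]), topt_true=float(max(topt[i], 0.0)),
                  td_true=float(td[i]))
        for i in range(cfg.n_sites)
    ]


def sites_to_frame(sites: list[SiteTruth]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in sites])


# ---------------------------------------------------------------------------
# kinetics plates
# ---------------------------------------------------------------------------

def activity_shape(temp, topt, width_below: float = 14.0,
                   width_above: float = 6.0):
    """Asymmetric thermal performance curve in [0, 1], peaking at ``topt``
    with a sharper decline above the optimum."""
    temp = np.asarray(temp, dtype=float)
    width = np.where(temp <= topt, width_below, width_above)
    return np.exp(-((temp - topt) / width) ** 2)


def gen_assay_plate(site: SiteTruth, temperatures, cfg: GenConfig, *,
                    n_replicates: int = 3, duration_min: float = 180.0,
                    interval_s: float = 30.0,
                    peak_slope: float = 0.02) -> pd.DataFrame:
    """Absorbance kinetics whose initial slope follows the site's thermal
    performance curve; columns site, temperature_C, replicate, time_min,
    absorbance.  True per-temperature slopes are attached as ``attrs``."""
    temperatures = list(temperatures)
    if len(temperatures) < 2:
        raise ValueError("need at least 2 assay temperatures")
    rng = _rng(cfg, "assay", abs(hash(site.site_id)) % (2 ** 31))
    times = np.arange(0.0, duration_min + 1e-9, interval_s / 60.0)
    rows = []
    true_slopes = {}
    for temp in temperatures:
        slope = peak_slope * float(activity_shape(temp, site.topt_true))
        true_slopes[float(temp)] = slope
        for rep in range(n_replicates):
            noise = rng.normal(0.0, cfg.assay_noise_sd, times.size)
            absorb = 0.05 + slope * times + noise
            rows.append(pd.DataFrame({
                "site": site.site_id, "temperature_C": float(temp),
                "replicate": rep, "time_min": times, "absorbance": absorb,
            }))
    frame = pd.concat(rows, ignore_index=True)
    frame.attrs["true_slopes"] = true_slopes
    frame.attrs["topt_true"] = site.topt_true
    return frame


# ---------------------------------------------------------------------------
# melting curves
# ---------------------------------------------------------------------------

def gen_melting_curve(td_true: float, cfg: GenConfig, *,
                      t_start: float = 4.0, t_stop: float = 95.0,
                      n_points: int = 183, amplitude: float = 18.0,
                      baseline: float = -20.0, width: float = 2.5,
                      asymmetry: float = 1.5) -> MeltingCurve:
    """5-parameter sigmoid melting trace with its maximum-slope point at
    ``td_true``; flagged out-of-range when the midpoint leaves the scan."""
    rng = _rng(cfg, "melt", int(abs(td_true) * 1000) % (2 ** 31))
    t = np.linspace(t_start, t_stop, n_points)
    t0 = td_true - width * np.log(asymmetry)
    theta = baseline + amplitude / (1.0 + np.exp(-(t - t0) / width)) ** asymmetry
    if cfg.melt_noise_frac > 0:
        theta = theta + rng.normal(0.0, cfg.melt_noise_frac * abs(amplitude),
                                   n_points)
    return MeltingCurve(temperature=t, signal=theta,
                        out_of_range=not (t_start <= td_true <= t_stop))


# ---------------------------------------------------------------------------
# constraint-network fixtures
# ---------------------------------------------------------------------------

def gen_toy_network(n_bodies: int, planted_ecut: float,
                    cfg: GenConfig) -> ConstraintNetwork:
    """Chain of bodies whose covalent skeleton alone is floppy (rotatable
    5-bar links) and whose hydrogen bonds all carry ``planted_ecut`` energy,
    so the single spanning rigid cluster collapses to singletons as soon as
    the dilution cutoff passes ``planted_ecut``."""
    if n_bodies < 2:
        raise ValueError("need at least 2 bodies")
    if not (-6.0 <= planted_ecut <= -0.1):
        raise ValueError("planted_ecut must lie in [-6.0, -0.1]")
    bars = []
    for i in range(n_bodies - 1):
        bars.append(Bar(i, i + 1, BarType.COVALENT_ROTATABLE))
        bars.append(Bar(i, i + 1, BarType.HBOND, energy=planted_ecut))
    return ConstraintNetwork(n_bodies=n_bodies, bars=tuple(bars),
                             meta={"planted_ecut": planted_ecut})


def gen_two_step_network(n_bodies: int, ecut_low: float, ecut_high: float,
                         cfg: GenConfig) -> ConstraintNetwork:
    """Chain with weak hydrogen bonds on the first half and strong ones on
    the second half: two planted rigidity transitions.  ``ecut_low`` (less
    negative) breaks first, ``ecut_high`` second."""
    if n_bodies < 4:
        raise ValueError("need at least 4 bodies")
    if not (ecut_high < ecut_low <= -0.1):
        raise ValueError("require ecut_high < ecut_low <= -0.1")
    half = n_bodies // 2
    bars = []
    for i in range(n_bodies - 1):
        e = ecut_low if i < half else ecut_high
        bars.append(Bar(i, i + 1, BarType.COVALENT_ROTATABLE))
        bars.append(Bar(i, i + 1, BarType.HBOND, energy=e))
    return ConstraintNetwork(n_bodies=n_bodies, bars=tuple(bars),
                             meta={"planted_ecuts": (ecut_low, ecut_high)})


def gen_random_network(n_bodies: int, cfg: GenConfig, *,
                       stream: int = 0, extra_edges: int | None = None
                       ) -> ConstraintNetwork:
    """Random typed multigraph for oracle cross-checks: a covalent spanning
    tree plus random extra covalent/H-bond/tether edges."""
    if n_bodies < 2:
        raise ValueError("need at least 2 bodies")
    rng = _rng(cfg, "network", stream)
    bars = []
    for v in range(1, n_bodies):
        u = int(rng.integers(0, v))
        btype = BarType.COVALENT_LOCKED if rng.random() < 0.3 \
            else BarType.COVALENT_ROTATABLE
        bars.append(Bar(u, v, btype))
    n_extra = int(rng.integers(0, 2 * n_bodies + 1)) \
        if extra_edges is None else extra_edges
    for _ in range(n_extra):
        u, v = rng.choice(n_bodies, size=2, replace=False)
        u, v = int(min(u, v)), int(max(u, v))
        r = rng.random()
        if r < 0.5:
            e = float(rng.uniform(-6.5, -0.05))
            bars.append(Bar(u, v, BarType.HBOND, energy=round(e, 3)))
        elif r < 0.7:
            bars.append(Bar(u, v, BarType.TETHER))
        elif r < 0.85:
            bars.append(Bar(u, v, BarType.COVALENT_ROTATABLE))
        else:
            bars.append(Bar(u, v, BarType.COVALENT_LOCKED))
    return ConstraintNetwork(n_bodies=n_bodies, bars=tuple(bars),
                             meta={"random_stream": stream})


# ---------------------------------------------------------------------------
# temperature loggers
# ---------------------------------------------------------------------------

#: (seasonal amplitude, diel amplitude) in degC per variability class
LOGGER_AMPLITUDES = {"HTV": (5.2, 1.1), "ITV": (3.6, 0.7), "LTV": (2.7, 0.5)}
LOGGER_MEAN_C = 28.0
LOGGER_INTERVAL_MIN = 30.0


def gen_temperature_log(variability_class: str, months: int, cfg: GenConfig, *,
                        amplitude_scale: float = 1.0,
                        noise_sd: float = 0.15) -> pd.DataFrame:
    """Half-hourly logger series: shared mean, seasonal sinusoid plus diel
    component plus noise, with class-ordered annual ranges
    (HTV > ITV > LTV)."""
    if variability_class not in LOGGER_AMPLITUDES:
        raise ValueError("class must be one of HTV, ITV, LTV")
    rng = _rng(cfg, "logger", _STREAMS["logger"] * 100 +
               list(LOGGER_AMPLITUDES).index(variability_class))
    a_season, a_diel = (amplitude_scale * a
                        for a in LOGGER_AMPLITUDES[variability_class])
    hours = np.arange(0.0, months * 30.44 * 24.0, LOGGER_INTERVAL_MIN / 60.0)
    temp = (LOGGER_MEAN_C
            + a_season * np.sin(2 * np.pi * hours / (365.25 * 24.0))
            + a_diel * np.sin(2 * np.pi * hours / 24.0))
    if noise_sd > 0 and amplitude_scale > 0:
        temp = temp + rng.normal(0.0, noise_sd, hours.size)
    out = pd.DataFrame({"time_h": hours, "temperature_C": temp})
    out.attrs["variability_class"] = variability_class
    out.attrs["true_mean"] = LOGGER_MEAN_C
    return out


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

#: thermal performance of the enriched fraction: (optimum degC, width degC)
GROWTH_TPC = {"HTV": (33.0, 12.0), "ITV": (31.0, 9.0), "LTV": (30.0, 8.0)}
GROWTH_RATE_MAX = 0.3          # per hour at the optimum; slow enough that
                               # 3-h sampling resolves the exponential phase
GROWTH_NO_GROWTH_K = 0.1       # carrying capacity of no-growth wells
GROWTH_RATE_FLOOR = 0.05       # below this true rate the well does not grow


def true_growth_rate(variability_class: str, assay_t: float) -> float:
    opt, width = GROWTH_TPC[variability_class]
    return float(GROWTH_RATE_MAX * np.exp(-((assay_t - opt) / width) ** 2))


def gen_growth_curves(variability_class: str, assay_t: float, cfg: GenConfig, *,
                      n_replicates: int = 3, duration_h: float = 72.0,
                      interval_h: float = 3.0, od0: float = 0.05,
                      carrying_capacity: float = 8.0,
                      noise_sd: float = 0.0) -> pd.DataFrame:
    """Logistic OD600 curves whose rate follows a class-specific thermal
    performance curve (wider for HTV); wells whose true rate falls below
    ``GROWTH_RATE_FLOOR`` stay near a sub-threshold carrying capacity."""
    if variability_class not in GROWTH_TPC:
        raise ValueError("class must be one of HTV, ITV, LTV")
    rng = _rng(cfg, "growth", int(assay_t * 10) +
               1000 * list(GROWTH_TPC).index(variability_class))
    rate = true_growth_rate(variability_class, assay_t)
    k = carrying_capacity if rate >= GROWTH_RATE_FLOOR else GROWTH_NO_GROWTH_K
    times = np.arange(0.0, duration_h + 1e-9, interval_h)
    rows = []
    for rep in range(n_replicates):
        od = k / (1.0 + (k - od0) / od0 * np.exp(-rate * times))
        if noise_sd > 0:
            od = np.maximum(od + rng.normal(0.0, noise_sd, times.size), 1e-4)
        rows.append(pd.DataFrame({
            "variability_class": variability_class, "assay_T": assay_t,
            "replicate": rep, "time_h": times, "od": od,
        }))
    frame = pd.concat(rows, ignore_index=True)
    frame.attrs["true_rate"] = rate
    frame.attrs["grew_truth"] = rate >= GROWTH_RATE_FLOOR
    return frame


def with_seed(cfg: GenConfig, seed: int) -> GenConfig:
    return replace(cfg, seed=seed)
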