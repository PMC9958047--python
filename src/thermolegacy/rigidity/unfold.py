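"""Thermal-unfolding dilution, cluster configuration entropy, the cutoff-to-
temperature mapping, and phase-transition temperature extraction.

The dilution schedule lowers the hydrogen-bond energy cutoff from -0.1 to
-6.0 kcal/mol in 0.1 steps (60 states); each state maps linearly onto a
temperature, 302 K to 420 K in 2 K steps:

    T = -(20 K / (kcal/mol)) * E_cut + 300 K
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .. import curves
from .network import ConstraintNetwork
from .pebble import RigidDecomposition, pebble_game

ECUT_SLOPE_K_PER_KCAL = -20.0
ECUT_INTERCEPT_K = 300.0

SCHEDULE_START = -0.1
SCHEDULE_STOP = -6.0
SCHEDULE_STEP = -0.1


class NoTransitionError(RuntimeError):
    pass


def ecut_to_temperature(e_cut: float) -> float:
    """Linear map from energy cutoff (kcal/mol) to temperature (K)."""
    return ECUT_SLOPE_K_PER_KCAL * e_cut + ECUT_INTERCEPT_K


def default_schedule() -> np.ndarray:
    n = int(round((SCHEDULE_STOP - SCHEDULE_START) / SCHEDULE_STEP)) + 1
    return np.round(np.linspace(SCHEDULE_START, SCHEDULE_STOP, n), 10)


@dataclass(frozen=True)
class UnfoldingTrajectory:
    e_cut: np.ndarray
    temperature_k: np.ndarray
    h_type2: np.ndarray
    largest_fraction: np.ndarray
    decompositions: tuple[RigidDecomposition, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "e_cut": self.e_cut, "T_K": self.temperature_k,
            "H_type2": self.h_type2,
            "largest_fraction": self.largest_fraction,
        })


@dataclass(frozen=True)
class TpResult:
    tp_k: float
    tp_c: float
    transitions: tuple[tuple[float, float], ...]
    rule_applied: str


def cluster_entropy(decomposition: RigidDecomposition) -> float:
    """Cluster configuration entropy with size-squared weighting:
    H = -sum_c w_c ln w_c over clusters c, w_c = s_c^2 / sum s^2.

    Zero for a single spanning cluster; ln k for k equal clusters."""
    sizes = np.asarray(decomposition.cluster_sizes, dtype=float)
    w = sizes ** 2
    w = w / w.sum()
    w = w[w > 0]
    return float(-(w * np.log(w)).sum())


def dilute(network: ConstraintNetwork,
           schedule: np.ndarray | None = None) -> UnfoldingTrajectory:
    """Run the dilution: at each cutoff remove hydrogen-bond class bars with
    energy above the cutoff (covalent bars and tethers are schedule-exempt),
    recompute the rigid decomposition, and attach T and H_type2."""
    if schedule is None:
        schedule = default_schedule()
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("empty dilution schedule")
    decomps, hs, fracs = [], [], []
    for e in schedule:
        d = pebble_game(network, float(e))
        decomps.append(d)
        hs.append(cluster_entropy(d))
        fracs.append(d.largest_fraction)
    return UnfoldingTrajectory(
        e_cut=schedule,
        temperature_k=np.array([ecut_to_temperature(e) for e in schedule]),
        h_type2=np.array(hs),
        largest_fraction=np.array(fracs),
        decompositions=tuple(decomps),
    )


def compute_tp(trajectory: UnfoldingTrajectory,
               td_c: float | None = None) -> TpResult:
    """Phase-transition temperature from the entropy-vs-temperature curve:
    a double-sigmoid step fit followed by the transition-selection rule
    (largest slope, or the second transition when T_d > 50 degC)."""
    h = trajectory.h_type2
    if float(np.ptp(h)) <= 1e-12:
        raise NoTransitionError("H_type2 is flat; no phase transition")
    fit = curves.fit_double_sigmoid(trajectory.temperature_k, h)
    if not fit.converged:
        raise NoTransitionError("step fit did not converge")
    choice = curves.select_tp(fit, td=td_c)
    return TpResult(tp_k=choice.tp, tp_c=choice.tp - 273.15,
                    transitions=fit.transitions, rule_applied=choice.rule)


def aggregate_replicates(tp_values) -> tuple[float, float | None]:
    """Mean and SEM (SD/sqrt(n)) over replicate T_p values; SEM is None for
    a single replicate."""
    vals = np.asarray(list(tp_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicates")
    mean = float(vals.mean())
    if vals.size == 1:
        return mean, None
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size))
    return mean, sem
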