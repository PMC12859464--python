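"""Steady-state observables: population of site |1>, steady time tau_sd,
steady probability P_sd, and parameter sweeps.

P1(t) = (1 + nz(t))/2.  The steady probability is the mean of P1 over the
final window of the run (default last 20%), accepted only if the window is
quasi-stationary (max - min < 2 tol); the steady time is the earliest time
after which P1 stays within tol of P_sd.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .redfield import BlochTrajectory

__all__ = [
    "SteadyStateMetrics",
    "population_state1",
    "steady_metrics",
    "sweep",
]


@dataclass
class SteadyStateMetrics:
    tau_sd: float  # np.nan if not reached
    P_sd: float
    tol: float
    window: float

    @property
    def reached(self) -> bool:
        return np.isfinite(self.tau_sd)


def population_state1(traj: BlochTrajectory) -> np.ndarray:
    """P1(t) = (1 + nz)/2, the population of the Bloch north pole |1>."""
    return 0.5 * (1.0 + traj.n_av[:, 2])


def steady_metrics(
    P1: np.ndarray, times: np.ndarray, tol: float = 0.01, window: float = 0.2
) -> SteadyStateMetrics:
    """Stabilization time and level of a population series.

    Returns a not-reached marker (tau_sd = nan) when the final window is
    not quasi-stationary, e.g. for undamped oscillations or unfinished
    relaxation; no exception is raised.
    """
    P1 = np.asarray(P1, dtype=float)
    times = np.asarray(times, dtype=float)
    nwin = max(2, int(np.ceil(window * len(P1))))
    tail = P1[-nwin:]
    p_sd = float(tail.mean())
    if tail.max() - tail.min() >= 2.0 * tol:
        return SteadyStateMetrics(np.nan, p_sd, tol, window)
    dev = np.abs(P1 - p_sd)
    # suffix maximum: tau_sd is the earliest time after which the band holds
    suffix = np.maximum.accumulate(dev[::-1])[::-1]
    idx = np.argmax(suffix <= tol)
    if suffix[idx] > tol:
        return SteadyStateMetrics(np.nan, p_sd, tol, window)
    return SteadyStateMetrics(float(times[idx]), p_sd, tol, window)


def sweep(
    config,
    axis: str,
    values,
    method: str = "heom",
    auto_extend: int = 2,
) -> pd.DataFrame:
    """Run the selected propagator per axis value and tabulate tau_sd, P_sd.

    axis:
      "gk"       -- overall coupling strength gk = c * lam (transition)
      "Delta_gk" -- gk(1) - gk(2) with gk(1) = c1 * lam held fixed (local)
      "T"        -- bath temperature
      "lam"      -- bath coupling strength at fixed c
    Failed cells are recorded with reached = False and the sweep continues.
    If the tail is not stationary the horizon is doubled up to
    ``auto_extend`` times.
    """
    from .iohub import run_propagation  # local import to avoid a cycle

    rows = []
    for v in values:
        tau, psd, reached, err = np.nan, np.nan, False, ""
        try:
            cfg = _apply_axis(config, axis, float(v))
            for attempt in range(auto_extend + 1):
                traj = run_propagation(cfg, method=method)
                m = steady_metrics(
                    population_state1(traj),
                    traj.times,
                    tol=cfg.numerics.tol,
                    window=cfg.numerics.window,
                )
                if m.reached or attempt == auto_extend:
                    tau, psd, reached = m.tau_sd, m.P_sd, m.reached
                    break
                cfg = cfg.model_copy(deep=True)
                cfg.numerics.t_final *= 2.0
        except Exception as e:  # record and continue
            err = str(e)
        rows.append(
            {"axis_value": float(v), "tau_sd": tau, "P_sd": psd, "reached": reached, "error": err}
        )
    return pd.DataFrame(rows)


def _apply_axis(config, axis: str, value: float):
    cfg = config.model_copy(deep=True)
    if axis == "gk":
        if cfg.coupling.kind != "transition":
            raise ValueError("axis 'gk' applies to transition coupling")
        cfg.coupling.c = value / cfg.bath.lam
    elif axis == "Delta_gk":
        if cfg.coupling.kind != "asymmetric_local":
            raise ValueError("axis 'Delta_gk' applies to asymmetric_local coupling")
        # gk(2) = gk(1) - Delta_gk with gk(1) = c1 lam fixed
        cfg.coupling.c2 = cfg.coupling.c1 - value / cfg.bath.lam
        cfg.coupling.r = None
    elif axis == "T":
        cfg.bath.T = value
    elif axis == "lam":
        cfg.bath.lam = value
    else:
        raise ValueError(f"unknown sweep axis {axis!r}")
    return cfg
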