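"""Enthalpy/entropy decomposition of basin free-energy differences.

Over a replica ladder dG(T) is assumed linear (constant heat capacity over
the fitted window): dG(T) = dH - T dS.  Ordinary least squares of dG on T
gives dH as the intercept and dS as minus the slope; TdS is reported at a
reference temperature (default 305 K, the production temperature).  A
range-robustness refit flags curvature that the linear model would hide.

All fitted quantities are in kcal/mol (kcal/mol/K for dS).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fes import BasinSpec, convergence_profile


@dataclass
class ThermoFit:
    """Result of the linear dG(T) regression."""

    delta_h: float                 # kcal/mol (intercept)
    delta_s: float                 # kcal/mol/K (-slope)
    t_ref: float                   # K
    t_delta_s: float               # T_ref * delta_s, kcal/mol
    r_squared: float
    stderr_slope: float | None
    stderr_intercept: float | None
    points: list[tuple[float, float]] = field(default_factory=list)

    def delta_g(self, temperature: float) -> float:
        """The fitted line dG(T) = dH - T dS."""
        return self.delta_h - temperature * self.delta_s


def fit_enthalpy_entropy(points, t_ref: float = 305.0) -> ThermoFit:
    """OLS of dG against T; dH = intercept, dS = -slope.

    ``points`` are (temperature K, dG kcal/mol) pairs.  Two points give the
    exact interpolating line with uncertainties reported as unavailable
    (None); three or more give standard errors from the residuals.
    """
    pts = [(float(t), float(g)) for t, g in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 (T, dG) points")
    ts = np.array([p[0] for p in pts])
    gs = np.array([p[1] for p in pts])
    if np.unique(ts).size < 2:
        raise ValueError("temperatures must not be identical")
    res = stats.linregress(ts, gs)
    if len(pts) == 2:
        se_s = se_i = None
        r2 = 1.0
    else:
        se_s = float(res.stderr)
        se_i = float(res.intercept_stderr)
        r2 = float(res.rvalue ** 2)
    return ThermoFit(delta_h=float(res.intercept),
                     delta_s=float(-res.slope),
                     t_ref=t_ref,
                     t_delta_s=float(-res.slope * t_ref),
                     r_squared=r2,
                     stderr_slope=se_s, stderr_intercept=se_i,
                     points=pts)


@dataclass
class ReplicaDeltaG:
    """One replica's basin dG with its convergence verdict."""

    temperature: float
    delta_g: float        # kcal/mol
    stderr: float         # kcal/mol, checkpoint spread of the mean
    converged: bool


def delta_g_vs_temperature(hills_list, cv_series_list, times_list,
                           axes, basin_a: BasinSpec, basin_b: BasinSpec,
                           temperatures=None,
                           interval: float | None = None,
                           average_fraction: float = 0.5,
                           ) -> list[ReplicaDeltaG]:
    """One (T, dG) point per replica from that replica's own hill log.

    Each replica's dG is the mean of the bias-integration dG(t) series over
    the final ``average_fraction`` of the run (time-averaging suppresses the
    residual oscillation of the converged well-tempered bias); the standard
    error is the checkpoint spread.  Unconverged replicas are flagged but
    still returned.
    """
    out = []
    for i, hills in enumerate(hills_list):
        t_end = float(np.asarray(times_list[i])[-1])
        dt = interval if interval is not None else t_end / 10.0
        rep = convergence_profile(hills, cv_series_list[i], times_list[i],
                                  axes, basin_a, basin_b, interval=dt)
        n = len(rep.times)
        k0 = int(np.floor(n * (1.0 - average_fraction)))
        tail = rep.dg_bias[k0:]
        tail = tail[np.isfinite(tail)]
        temp = (temperatures[i] if temperatures is not None
                else hills.temperature)
        if tail.size == 0:
            out.append(ReplicaDeltaG(temp, np.nan, np.nan, False))
            continue
        out.append(ReplicaDeltaG(
            temperature=float(temp),
            delta_g=float(tail.mean()),
            stderr=float(tail.std(ddof=1) / np.sqrt(tail.size))
            if tail.size > 1 else np.nan,
            converged=rep.converged))
    return out


@dataclass
class RobustnessEntry:
    label: str
    fit: ThermoFit


@dataclass
class RobustnessReport:
    entries: list[RobustnessEntry]
    stable: bool
    max_dh_spread: float
    threshold: float


def range_robustness(points, subranges=None) -> RobustnessReport:
    """Refit dH/dS on temperature subranges; flag instability.

    ``subranges`` are (t_lo, t_hi) windows (default: full range, drop the
    hottest point, drop the coldest point).  The estimate is declared
    unstable when dH varies across subranges by more than twice the largest
    fit standard error — the signature of curvature in dG(T).
    """
    pts = sorted((float(t), float(g)) for t, g in points)
    ts = [p[0] for p in pts]
    if subranges is None:
        subranges = [(ts[0], ts[-1]), (ts[0], ts[-2]), (ts[1], ts[-1])]
    entries = []
    for lo, hi in subranges:
        sub = [p for p in pts if lo <= p[0] <= hi]
        if len(sub) < 2:
            raise ValueError(
                f"subrange ({lo}, {hi}) keeps fewer than 2 points")
        entries.append(RobustnessEntry(label=f"{lo:g}-{hi:g}K",
                                       fit=fit_enthalpy_entropy(sub)))
    dhs = [e.fit.delta_h for e in entries]
    errs = [e.fit.stderr_intercept for e in entries
            if e.fit.stderr_intercept is not None]
    spread = float(max(dhs) - min(dhs))
    # absolute floor so numerically exact fits are never flagged
    thr = max(2.0 * max(errs), 1e-9) if errs else np.inf
    return RobustnessReport(entries=entries, stable=bool(spread <= thr),
                            max_dh_spread=spread, threshold=thr)
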