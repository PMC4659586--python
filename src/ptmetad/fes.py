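"""Free-energy surface reconstruction from metadynamics output.

Two independent estimators are provided and cross-checked against each other
as a convergence diagnostic:

* bias integration — at convergence the well-tempered bias satisfies
  ``V(s) = -(1 - 1/gamma) F(s)`` up to a constant, so
  ``F(s) = -gamma/(gamma-1) V(s, t_end)``;
* time-independent reweighting — each frame is weighted by
  ``exp(beta [V(s(t), t) - c(t)])`` where the offset
  ``c(t) = (1/beta) ln [ int exp(g b V) ds / int exp(b V /(gamma-1) ... ) ]``
  makes the weights time-independent; the weighted histogram on any target
  CV grid (also CVs that were never biased, e.g. path variables) gives
  ``F = -k_B T ln p``.

Unsampled grid nodes carry ``+inf`` and are excluded from basin sums, never
imputed.  Basin free-energy differences are reported in kcal/mol.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .hills import HillsLog, _hill_on_grid, evaluate_bias_on_grid
from .units import KB, kj_to_kcal


@dataclass
class FreeEnergySurface:
    """Gridded free energy over 1-2 CVs, min-shifted to zero.

    ``values`` are per grid node (node-centred axes); unsampled nodes are
    ``+inf``.  Units are kJ/mol unless converted with :meth:`in_units`.
    """

    axes: tuple[np.ndarray, ...]
    values: np.ndarray
    temperature: float
    estimator: str
    names: tuple[str, ...] = ()
    units: str = "kJ/mol"

    def __post_init__(self):
        self.axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(len(a) for a in self.axes):
            raise ValueError("values shape must match the axes")
        if not self.names:
            self.names = tuple(f"cv{i+1}" for i in range(len(self.axes)))
        finite = np.isfinite(self.values)
        if not finite.any():
            raise ValueError("free energy surface has no sampled nodes")
        self.values = self.values - self.values[finite].min()

    @property
    def sampled(self) -> np.ndarray:
        return np.isfinite(self.values)

    def in_units(self, units: str) -> "FreeEnergySurface":
        if units == self.units:
            return self
        if {self.units, units} != {"kJ/mol", "kcal/mol"}:
            raise ValueError(f"unsupported unit conversion to {units}")
        f = 1 / 4.184 if units == "kcal/mol" else 4.184
        return FreeEnergySurface(self.axes, self.values * f, self.temperature,
                                 self.estimator, self.names, units)


@dataclass
class BasinSpec:
    """Named rectangular basin: closed interval per CV axis index."""

    name: str
    bounds: dict[int, tuple[float, float]]

    def mask(self, axes: tuple[np.ndarray, ...]) -> np.ndarray:
        m = np.ones(tuple(len(a) for a in axes), dtype=bool)
        for dim, (lo, hi) in self.bounds.items():
            ax = axes[dim]
            sel = (ax >= lo) & (ax <= hi)
            shape = [1] * len(axes)
            shape[dim] = len(ax)
            m &= sel.reshape(shape)
        if not m.any():
            raise ValueError(
                f"basin '{self.name}' does not intersect the grid")
        return m


def basins_from_ground_truth(potential) -> dict[str, BasinSpec]:
    """BasinSpecs from a model potential's recorded basin rectangles."""
    out = {}
    for name, bounds in potential.ground_truth.get("basins", {}).items():
        out[name] = BasinSpec(name=name, bounds=dict(bounds))
    return out


# ---------------------------------------------------------------------------
# estimator 1: bias integration
# ---------------------------------------------------------------------------

def fes_from_bias(hills: HillsLog, axes, gamma: float | None = None,
                  temperature: float | None = None,
                  up_to_time: float | None = None) -> FreeEnergySurface:
    """F(s) = -(gamma/(gamma-1)) V(s, t_end), min-shifted to zero."""
    gamma = hills.bias_factor if gamma is None else gamma
    if gamma <= 1:
        raise ValueError(f"bias factor must be > 1, got {gamma}")
    temperature = hills.temperature if temperature is None else temperature
    axes = tuple(np.asarray(a, dtype=float) for a in axes)
    v = evaluate_bias_on_grid(hills, list(axes), up_to_time=up_to_time)
    f = -(gamma / (gamma - 1.0)) * v
    return FreeEnergySurface(axes=axes, values=f, temperature=temperature,
                             estimator="bias_integration",
                             names=hills.cv_names)


# ---------------------------------------------------------------------------
# estimator 2: time-independent reweighting
# ---------------------------------------------------------------------------

def rct_series(hills: HillsLog, axes, gamma: float | None = None,
               temperature: float | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Reweighting offset c(t) after each hill deposition.

    c(t) = (1/beta) ln[ int exp(g beta V) / int exp(beta V / (gamma-1)) ]
    with g = gamma/(gamma-1), evaluated on the grid by log-sum-exp.  The
    returned times are the hill times; c = 0 before the first hill.
    """
    gamma = hills.bias_factor if gamma is None else gamma
    if gamma <= 1:
        raise ValueError(f"bias factor must be > 1, got {gamma}")
    temperature = hills.temperature if temperature is None else temperature
    axes = [np.asarray(a, dtype=float) for a in axes]
    if any(len(a) == 0 for a in axes) or not axes:
        raise ValueError("empty reconstruction grid")
    b = 1.0 / (KB * temperature)
    g = gamma / (gamma - 1.0)
    # trapezoidal quadrature weights (the constant cell volume cancels)
    wts = np.ones(len(axes[0]))
    wts[[0, -1]] = 0.5
    for a in axes[1:]:
        w1 = np.ones(len(a))
        w1[[0, -1]] = 0.5
        wts = np.multiply.outer(wts, w1)
    v = np.zeros(tuple(len(a) for a in axes))
    cs = np.empty(hills.n_hills)
    for i in range(hills.n_hills):
        v += _hill_on_grid(axes, hills.centers[i], hills.widths[i],
                           hills.heights[i], hills.periods)
        cs[i] = (logsumexp(g * b * v, b=wts)
                 - logsumexp(b * v / (gamma - 1.0), b=wts)) / b
    return hills.times.copy(), cs


def rct_offset(hills: HillsLog, axes, time: float,
               gamma: float | None = None,
               temperature: float | None = None) -> float:
    """The offset c(t) at a single time (0 before any hill)."""
    times, cs = rct_series(hills, axes, gamma=gamma, temperature=temperature)
    n = int(np.searchsorted(times, time, side="right"))
    return 0.0 if n == 0 else float(cs[n - 1])


def frame_bias(hills: HillsLog, cv_series: np.ndarray,
               times: np.ndarray) -> np.ndarray:
    """V(s(t), t): the bias acting on each frame at its own time."""
    cv_series = np.atleast_2d(np.asarray(cv_series, dtype=float))
    times = np.asarray(times, dtype=float)
    n_frames = cv_series.shape[0]
    v = np.zeros(n_frames)
    for i in range(hills.n_hills):
        i0 = int(np.searchsorted(times, hills.times[i], side="left"))
        if i0 >= n_frames:
            break
        d = cv_series[i0:] - hills.centers[i]
        for k, p in enumerate(hills.periods):
            if p is not None:
                d[:, k] -= p * np.round(d[:, k] / p)
        arg = (d * d / (2.0 * hills.widths[i] ** 2)).sum(axis=1)
        v[i0:] += hills.heights[i] * np.exp(-arg)
    return v


def frame_log_weights(hills: HillsLog, cv_series: np.ndarray,
                      times: np.ndarray, axes,
                      temperature: float | None = None,
                      extra_log_weight: np.ndarray | None = None
                      ) -> np.ndarray:
    """log w(t) = beta [V(s(t), t) - c(t)] (+ optional extra terms, e.g. a
    frozen well-tempered-ensemble bias)."""
    temperature = hills.temperature if temperature is None else temperature
    b = 1.0 / (KB * temperature)
    v = frame_bias(hills, cv_series, times)
    if hills.n_hills == 0:
        c = np.zeros_like(v)
    else:
        ht, cs = rct_series(hills, axes, temperature=temperature)
        idx = np.searchsorted(ht, np.asarray(times, dtype=float),
                              side="right")
        c = np.where(idx > 0, cs[np.maximum(idx - 1, 0)], 0.0)
    lw = b * (v - c)
    if extra_log_weight is not None:
        lw = lw + np.asarray(extra_log_weight, dtype=float)
    return lw


def reweight_fes(cv_series: np.ndarray, times: np.ndarray, hills: HillsLog,
                 target_series: np.ndarray, target_axes,
                 temperature: float | None = None,
                 extra_log_weight: np.ndarray | None = None,
                 target_names: tuple[str, ...] = (),
                 up_to_time: float | None = None,
                 equilibration_time: float = 0.0) -> FreeEnergySurface:
    """Weighted-histogram free energy on an arbitrary target CV grid.

    ``cv_series`` are the biased CVs at the saved frames (used to evaluate
    the bias on each frame); ``target_series`` are the CVs the surface is
    resolved over, which may be entirely different (e.g. path variables).
    With no hills the estimator reduces to a plain histogram.
    """
    cv_series = np.atleast_2d(np.asarray(cv_series, dtype=float))
    target = np.asarray(target_series, dtype=float)
    if target.ndim == 1:
        target = target[:, None]
    times = np.asarray(times, dtype=float)
    if cv_series.shape[0] != target.shape[0]:
        raise ValueError("biased and target CV series must share frames")
    if cv_series.shape[0] != times.shape[0]:
        raise ValueError("every frame needs a bias value and a time stamp")
    temperature = hills.temperature if temperature is None else temperature
    axes_b = [np.linspace(hills.centers[:, k].min() - 4 * hills.widths[0, k],
                          hills.centers[:, k].max() + 4 * hills.widths[0, k],
                          201) for k in range(hills.n_cvs)] \
        if hills.n_hills else [np.linspace(-1, 1, 3)] * cv_series.shape[1]
    lw = frame_log_weights(hills, cv_series, times, axes_b,
                           temperature=temperature,
                           extra_log_weight=extra_log_weight)
    keep = times >= equilibration_time
    if up_to_time is not None:
        keep &= times <= up_to_time
    target_axes = tuple(np.asarray(a, dtype=float) for a in target_axes)
    edges = []
    for a in target_axes:
        step = a[1] - a[0]
        edges.append(np.concatenate([a - step / 2, [a[-1] + step / 2]]))
    w = np.exp(lw[keep] - lw[keep].max())
    hist, _ = np.histogramdd(target[keep], bins=edges, weights=w)
    with np.errstate(divide="ignore"):
        f = -KB * temperature * np.log(hist)
    f[hist == 0] = np.inf
    return FreeEnergySurface(axes=target_axes, values=f,
                             temperature=temperature, estimator="reweight",
                             names=target_names or None or tuple(
                                 f"cv{i+1}" for i in range(len(target_axes))))


# ---------------------------------------------------------------------------
# basin thermodynamics and convergence diagnostics
# ---------------------------------------------------------------------------

def basin_delta_g(fes: FreeEnergySurface, basin_a: BasinSpec,
                  basin_b: BasinSpec,
                  temperature: float | None = None) -> float:
    """dG = G_a - G_b = -k_B T ln(Z_a / Z_b), in kcal/mol.

    Z sums Boltzmann weights of sampled grid nodes inside each basin (the
    constant cell volume cancels).
    """
    temperature = fes.temperature if temperature is None else temperature
    f = fes.in_units("kJ/mol").values
    b = 1.0 / (KB * temperature)
    out = []
    for basin in (basin_a, basin_b):
        m = basin.mask(fes.axes) & np.isfinite(f)
        if not m.any():
            raise ValueError(
                f"basin '{basin.name}' contains no sampled grid nodes")
        out.append(logsumexp(-b * f[m]))
    return kj_to_kcal(-KB * temperature * (out[0] - out[1]))


@dataclass
class ConvergenceReport:
    """dG(t) under both estimators plus the declared convergence verdict."""

    times: np.ndarray
    dg_bias: np.ndarray          # kcal/mol
    dg_reweight: np.ndarray      # kcal/mol
    converged: bool
    spread_bias: float
    spread_reweight: float
    agreement: float
    band: float
    agree_tol: float
    n_last: int


def convergence_profile(hills: HillsLog, cv_series: np.ndarray,
                        times: np.ndarray, axes, basin_a: BasinSpec,
                        basin_b: BasinSpec, interval: float,
                        temperature: float | None = None,
                        target_series: np.ndarray | None = None,
                        band: float = 0.3, agree_tol: float = 0.3,
                        n_last: int = 3) -> ConvergenceReport:
    """dG recomputed at interval endpoints from both estimators.

    The run is declared converged when the last ``n_last`` checkpoints of
    each series lie within ``band`` kcal/mol and the estimators agree within
    ``agree_tol`` kcal/mol at the end.
    """
    times = np.asarray(times, dtype=float)
    t_end = times[-1]
    if t_end < 2 * interval:
        raise ValueError("run shorter than two convergence intervals")
    temperature = hills.temperature if temperature is None else temperature
    cps = np.arange(interval, t_end, interval)
    if cps[-1] < t_end:
        cps = np.concatenate([cps, [t_end]])
    target = cv_series if target_series is None else target_series
    dg_b = np.full(len(cps), np.nan)
    dg_r = np.full(len(cps), np.nan)
    for i, cp in enumerate(cps):
        try:
            fb = fes_from_bias(hills, axes, temperature=temperature,
                               up_to_time=cp)
            dg_b[i] = basin_delta_g(fb, basin_a, basin_b, temperature)
        except ValueError:
            pass
        try:
            fr = reweight_fes(cv_series, times, hills, target, axes,
                              temperature=temperature, up_to_time=cp)
            dg_r[i] = basin_delta_g(fr, basin_a, basin_b, temperature)
        except ValueError:
            pass
    last_b = dg_b[-n_last:]
    last_r = dg_r[-n_last:]
    spread_b = float(np.nanmax(last_b) - np.nanmin(last_b)) \
        if np.isfinite(last_b).all() else np.inf
    spread_r = float(np.nanmax(last_r) - np.nanmin(last_r)) \
        if np.isfinite(last_r).all() else np.inf
    agreement = (abs(float(dg_b[-1] - dg_r[-1]))
                 if np.isfinite(dg_b[-1]) and np.isfinite(dg_r[-1])
                 else np.inf)
    converged = (spread_b < band and spread_r < band
                 and agreement < agree_tol)
    return ConvergenceReport(times=cps, dg_bias=dg_b, dg_reweight=dg_r,
                             converged=bool(converged),
                             spread_bias=spread_b, spread_reweight=spread_r,
                             agreement=agreement, band=band,
                             agree_tol=agree_tol, n_last=n_last)


def count_basin_visits(series: np.ndarray, basins: list[BasinSpec],
                       axes_dims: list[int] | None = None) -> dict[str, int]:
    """How often the trajectory (re-)enters each basin.

    ``series`` is (n_frames, n_cvs); a visit to basin b is counted whenever
    the last-known basin changes to b (the first basin counts as one visit).
    Frames in no basin keep the last-known label.  Mirrors the free-diffusion
    check that a converged run must visit every basin several times.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    counts = {b.name: 0 for b in basins}
    current = None
    for row in series:
        label = None
        for b in basins:
            ok = all(lo <= row[d] <= hi for d, (lo, hi) in b.bounds.items())
            if ok:
                label = b.name
                break
        if label is not None and label != current:
            counts[label] += 1
            current = label
    return counts
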