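"""Well-tempered metadynamics: hill bookkeeping and bias evaluation.

The bias is a sum of Gaussians deposited along the trajectory in CV space.
In well-tempered mode each new hill is scaled by ``exp(-V/(k_B dT))`` with
``dT = (gamma - 1) T``, so the bias converges to ``-(1 - 1/gamma) F``.
Heights are stored as deposited (already scaled), the common HILLS-file
convention.

During dynamics the bias force comes from a grid cache (each deposition adds
its Gaussian to value and gradient grids; forces are linearly interpolated).
Deposited heights and all logged/exchanged bias energies use exact direct
summation over the hill list, so the bias is exactly reproducible from the
log alone.
"""
from __future__ import annotations

from dataclasses import dataclass

import math
import numpy as np

from .sampling import Bias
from .cvs import PotentialEnergyCV
from .units import KB


@dataclass
class MetadParams:
    """Well-tempered metadynamics parameters.

    Defaults follow common practice for conformational sampling: initial hill
    height 2.0 kJ/mol, one deposition per 2000 steps, bias factor 5.
    """

    height: float = 2.0                 # w0, kJ/mol
    widths: tuple[float, ...] = (0.3,)  # one sigma per CV, CV units
    deposition_stride: int = 2000       # steps between hills
    bias_factor: float = 5.0            # gamma > 1
    temperature: float = 305.0          # K

    def __post_init__(self):
        self.widths = tuple(float(w) for w in np.atleast_1d(self.widths))
        if self.bias_factor <= 1:
            raise ValueError(
                f"bias_factor must be > 1, got {self.bias_factor}")
        if any(w <= 0 for w in self.widths):
            raise ValueError(f"widths must be positive, got {self.widths}")
        if self.height < 0:
            raise ValueError(f"height must be >= 0, got {self.height}")
        if self.deposition_stride < 1:
            raise ValueError("deposition_stride must be >= 1")

    @property
    def delta_t(self) -> float:
        """Well-tempered boost temperature dT = (gamma - 1) T, in K."""
        return (self.bias_factor - 1.0) * self.temperature


def next_hill_height(params: MetadParams, current_bias_at_center: float
                     ) -> float:
    """Well-tempered height w = w0 exp(-V/(k_B dT)).

    As ``bias_factor`` grows the rule tends to standard metadynamics
    (constant w0).
    """
    if not math.isfinite(params.delta_t) or params.delta_t <= 0:
        return params.height
    return params.height * math.exp(
        -current_bias_at_center / (KB * params.delta_t))


@dataclass
class HillsLog:
    """Record of deposited Gaussians (times ps, centers/widths CV units,
    heights kJ/mol) plus well-tempered metadata."""

    times: np.ndarray
    centers: np.ndarray
    widths: np.ndarray
    heights: np.ndarray
    bias_factor: float
    temperature: float
    cv_names: tuple[str, ...] = ()
    periods: tuple[float | None, ...] = ()

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        n = self.times.shape[0]
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if n:
            self.centers = self.centers.reshape(n, -1)
            self.widths = self.widths.reshape(n, -1)
        else:
            d = (self.centers.shape[-1] if self.centers.ndim > 1
                 else max(len(self.cv_names), 1))
            self.centers = self.centers.reshape(0, d)
            self.widths = self.widths.reshape(0, d)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("hill times must be strictly increasing")
        if np.any(self.heights <= 0):
            raise ValueError("hill heights must be strictly positive")
        d = self.centers.shape[1] if self.times.size else len(self.cv_names)
        if not self.cv_names:
            self.cv_names = tuple(f"cv{i+1}" for i in range(d))
        if not self.periods:
            self.periods = (None,) * len(self.cv_names)

    @property
    def n_hills(self) -> int:
        return self.times.shape[0]

    @property
    def n_cvs(self) -> int:
        return len(self.cv_names)

    def __eq__(self, other):
        if not isinstance(other, HillsLog):
            return NotImplemented
        return (np.array_equal(self.times, other.times)
                and np.array_equal(self.centers, other.centers)
                and np.array_equal(self.widths, other.widths)
                and np.array_equal(self.heights, other.heights)
                and self.bias_factor == other.bias_factor
                and self.temperature == other.temperature
                and self.cv_names == other.cv_names
                and self.periods == other.periods)


def _wrapped_delta(dx: np.ndarray, periods) -> np.ndarray:
    for k, p in enumerate(periods):
        if p is not None:
            dx[..., k] -= p * np.round(dx[..., k] / p)
    return dx


def evaluate_bias(hills: HillsLog, point: np.ndarray,
                  up_to_time: float | None = None) -> float | np.ndarray:
    """Direct-summation bias V(point) from hills with time <= up_to_time.

    ``point`` may be a single CV vector ``(d,)`` or a batch ``(N, d)``.
    """
    pt = np.asarray(point, dtype=float)
    scalar = pt.ndim == 1
    pts = pt[None, :] if scalar else pt
    if pts.shape[1] != hills.n_cvs:
        raise ValueError(
            f"point has {pts.shape[1]} CVs, hills carry {hills.n_cvs}")
    n = hills.n_hills
    if up_to_time is not None:
        n = int(np.searchsorted(hills.times, up_to_time, side="right"))
    if n == 0:
        out = np.zeros(pts.shape[0])
        return float(out[0]) if scalar else out
    c = hills.centers[:n]
    s = hills.widths[:n]
    h = hills.heights[:n]
    out = np.empty(pts.shape[0])
    block = max(1, int(2e6 // max(n, 1)))
    for i0 in range(0, pts.shape[0], block):
        d = pts[i0:i0 + block, None, :] - c[None, :, :]
        d = _wrapped_delta(d, hills.periods)
        arg = (d * d / (2.0 * s[None, :, :] ** 2)).sum(axis=-1)
        out[i0:i0 + block] = (h[None, :] * np.exp(-arg)).sum(axis=1)
    return float(out[0]) if scalar else out


def evaluate_bias_on_grid(hills: HillsLog, axes: list[np.ndarray],
                          up_to_time: float | None = None) -> np.ndarray:
    """Bias evaluated on a tensor grid (separable Gaussians, fast path)."""
    n = hills.n_hills
    if up_to_time is not None:
        n = int(np.searchsorted(hills.times, up_to_time, side="right"))
    shape = tuple(len(a) for a in axes)
    v = np.zeros(shape)
    for i in range(n):
        v += _hill_on_grid(axes, hills.centers[i], hills.widths[i],
                           hills.heights[i], hills.periods)
    return v


def _hill_on_grid(axes, center, widths, height, periods):
    gs = []
    for k, ax in enumerate(axes):
        d = ax - center[k]
        if periods[k] is not None:
            d = d - periods[k] * np.round(d / periods[k])
        gs.append(np.exp(-d * d / (2.0 * widths[k] ** 2)))
    if len(axes) == 1:
        return height * gs[0]
    if len(axes) == 2:
        return height * np.multiply.outer(gs[0], gs[1])
    out = gs[0]
    for g in gs[1:]:
        out = np.multiply.outer(out, g)
    return height * out


class BiasGrid:
    """Uniform grid cache of the bias and its CV-space gradient.

    Depositions add separable Gaussian contributions to value and gradient
    arrays; lookups use multilinear interpolation with edge clamping.
    Supports 1 or 2 CV dimensions (the biased-CV count used in practice).
    """

    def __init__(self, mins, maxs, bins, periods=None):
        self.mins = np.atleast_1d(np.asarray(mins, dtype=float))
        self.maxs = np.atleast_1d(np.asarray(maxs, dtype=float))
        bins = np.atleast_1d(np.asarray(bins, dtype=int))
        if bins.size == 1:
            bins = np.repeat(bins, self.mins.size)
        self.dim = self.mins.size
        if self.dim > 2:
            raise ValueError("BiasGrid supports at most 2 CV dimensions")
        self.axes = [np.linspace(self.mins[k], self.maxs[k], bins[k])
                     for k in range(self.dim)]
        self.steps = np.array([a[1] - a[0] for a in self.axes])
        self.periods = tuple(periods) if periods else (None,) * self.dim
        shape = tuple(bins)
        self.values = np.zeros(shape)
        self.grads = np.zeros((self.dim,) + shape)

    def add_hill(self, center, widths, height):
        gs, dgs = [], []
        for k, ax in enumerate(self.axes):
            d = ax - center[k]
            if self.periods[k] is not None:
                d = d - self.periods[k] * np.round(d / self.periods[k])
            g = np.exp(-d * d / (2.0 * widths[k] ** 2))
            gs.append(g)
            dgs.append(-d / widths[k] ** 2 * g)
        if self.dim == 1:
            self.values += height * gs[0]
            self.grads[0] += height * dgs[0]
        else:
            self.values += height * np.multiply.outer(gs[0], gs[1])
            self.grads[0] += height * np.multiply.outer(dgs[0], gs[1])
            self.grads[1] += height * np.multiply.outer(gs[0], dgs[1])

    def _locate(self, point):
        idx, frac = [], []
        for k in range(self.dim):
            t = (point[k] - self.mins[k]) / self.steps[k]
            i = int(np.clip(np.floor(t), 0, len(self.axes[k]) - 2))
            idx.append(i)
            frac.append(np.clip(t - i, 0.0, 1.0))
        return idx, frac

    def _interp(self, arr, idx, frac):
        if self.dim == 1:
            i, f = idx[0], frac[0]
            return (1 - f) * arr[i] + f * arr[i + 1]
        i, j = idx
        fx, fy = frac
        return ((1 - fx) * (1 - fy) * arr[i, j] + fx * (1 - fy) * arr[i + 1, j]
                + (1 - fx) * fy * arr[i, j + 1] + fx * fy * arr[i + 1, j + 1])

    def lookup(self, point):
        """(value, gradient) of the cached bias at a CV point."""
        idx, frac = self._locate(point)
        v = self._interp(self.values, idx, frac)
        g = np.array([self._interp(self.grads[k], idx, frac)
                      for k in range(self.dim)])
        return v, g


class MetadBias(Bias):
    """Live well-tempered metadynamics bias over a set of biasable CVs.

    ``start_after_step``/``freeze_after_step`` bracket the deposition window
    (used for the grow-then-freeze well-tempered-ensemble protocol).  With
    ``params.height == 0`` the bias is identically zero and the trajectory
    matches an unbiased run with the same seed.
    """

    def __init__(self, cvs, params: MetadParams, timestep: float,
                 grid_min, grid_max, grid_bins=201, periods=None,
                 start_after_step: int = 0,
                 freeze_after_step: int | None = None):
        self.cvs = list(cvs)
        if len(params.widths) != len(self.cvs):
            raise ValueError("need one Gaussian width per CV")
        self.params = params
        self.timestep = float(timestep)
        self.grid = BiasGrid(grid_min, grid_max, grid_bins, periods=periods)
        if self.grid.dim != len(self.cvs):
            raise ValueError("grid dimensionality must match the CV count")
        self.start_after_step = int(start_after_step)
        self.freeze_after_step = freeze_after_step
        # fast path: biases acting directly on coordinates
        from .cvs import CoordinateCV
        self._coord_indices = ([cv.index for cv in self.cvs]
                               if all(isinstance(cv, CoordinateCV)
                                      for cv in self.cvs) else None)
        self._times: list[float] = []
        self._centers: list[np.ndarray] = []
        self._heights: list[float] = []

    # -- CV evaluation (reusing the integrator's energy/gradient when the
    #    CV is the potential energy itself, i.e. the well-tempered ensemble)
    def _cv_values(self, x, u=None):
        return np.array([u if (isinstance(cv, PotentialEnergyCV)
                               and u is not None) else cv.value(x)
                         for cv in self.cvs])

    def force_gradient(self, x, step, u, grad_u):
        if self.params.height == 0 or not self._times:
            return np.zeros_like(np.asarray(x, dtype=float))
        if self._coord_indices is not None:
            s = x[self._coord_indices]
            _, dvds = self.grid.lookup(s)
            g = np.zeros_like(x)
            g[self._coord_indices] = dvds
            return g
        s = self._cv_values(x, u)
        _, dvds = self.grid.lookup(s)
        g = np.zeros_like(np.asarray(x, dtype=float))
        for k, cv in enumerate(self.cvs):
            if dvds[k] == 0.0:
                continue
            cg = (grad_u if (isinstance(cv, PotentialEnergyCV)
                             and grad_u is not None) else cv.gradient(x))
            g = g + dvds[k] * cg
        return g

    def post_step(self, x, step, u):
        if self.params.height == 0:
            return
        if step <= self.start_after_step:
            return
        if self.freeze_after_step is not None and step > self.freeze_after_step:
            return
        if step % self.params.deposition_stride != 0:
            return
        s = self._cv_values(x, u)
        v = self.bias_at(s)
        w = next_hill_height(self.params, v)
        self._times.append(step * self.timestep)
        self._centers.append(s.copy())
        self._heights.append(w)
        self.grid.add_hill(s, self.params.widths, w)

    def bias_at(self, s) -> float:
        """Exact direct-summation bias at a CV point (all deposited hills)."""
        if not self._times:
            return 0.0
        return float(evaluate_bias(self.hills_log(), np.asarray(s, float)))

    def energy(self, x, step, u=None) -> float:
        if not self._times:
            return 0.0
        return self.bias_at(self._cv_values(x, u))

    def hills_log(self) -> HillsLog:
        n = len(self._times)
        d = len(self.cvs)
        return HillsLog(
            times=np.array(self._times),
            centers=(np.array(self._centers) if n else np.empty((0, d))),
            widths=np.tile(self.params.widths, (n, 1)),
            heights=np.array(self._heights),
            bias_factor=self.params.bias_factor,
            temperature=self.params.temperature,
            cv_names=tuple(getattr(cv, "name", f"cv{i+1}")
                           for i, cv in enumerate(self.cvs)),
            periods=self.grid.periods)


class CompositeBias(Bias):
    """Sum of independent biases (e.g. CV metadynamics + WTE energy bias)."""

    def __init__(self, *biases: Bias):
        self.biases = [b for b in biases if b is not None]

    def force_gradient(self, x, step, u, grad_u):
        g = np.zeros_like(np.asarray(x, dtype=float))
        for b in self.biases:
            g = g + b.force_gradient(x, step, u, grad_u)
        return g

    def post_step(self, x, step, u):
        for b in self.biases:
            b.post_step(x, step, u)

    def energy(self, x, step, u=None):
        return sum(b.energy(x, step, u=u) for b in self.biases)
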