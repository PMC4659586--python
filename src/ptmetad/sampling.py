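"""Langevin dynamics and parallel-tempering replica exchange.

The integrator is the BAOAB splitting of underdamped Langevin dynamics,
chosen for its configurational accuracy at large timesteps.  A time-dependent
bias (metadynamics, well-tempered-ensemble) can be attached; the bias
contributes a force every step and may update itself (deposit hills) after
each step.  Replica exchange follows the standard alternating even/odd
adjacent-pair schedule with Metropolis acceptance including per-replica bias
terms.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .potentials import ModelPotential
from .trajectory import Trajectory
from .units import KB


@dataclass
class SamplerConfig:
    """Langevin run parameters (temperature K, friction 1/ps, timestep ps)."""

    temperature: float
    n_steps: int
    seed: int
    friction: float = 1.0
    timestep: float = 0.01
    save_stride: int = 100
    mass: float = 1.0
    x0: np.ndarray | None = None

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError(f"timestep must be positive, got {self.timestep}")
        if self.friction <= 0:
            raise ValueError(f"friction must be positive, got {self.friction}")
        if self.save_stride < 1:
            raise ValueError(
                f"save_stride must be >= 1, got {self.save_stride}")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


class Bias:
    """Interface for time-dependent biases coupled to the integrator."""

    def force_gradient(self, x: np.ndarray, step: int, u: float,
                       grad_u: np.ndarray) -> np.ndarray:
        """Gradient of the bias energy w.r.t. coordinates at this step."""
        raise NotImplementedError

    def post_step(self, x: np.ndarray, step: int, u: float) -> None:
        """Hook called after each completed step (e.g. hill deposition)."""

    def energy(self, x: np.ndarray, step: int, u: float | None = None) -> float:
        """Exact bias energy at the current time (direct summation)."""
        raise NotImplementedError


class LangevinIntegrator:
    """Resumable BAOAB integrator on a model potential.

    Frames (positions + exactly recomputable potential energies) are recorded
    every ``save_stride`` steps, including the initial state.  The random
    stream is a ``numpy.random.Generator`` so successive ``run`` calls are
    equivalent to one long call.
    """

    def __init__(self, potential: ModelPotential, config: SamplerConfig,
                 bias: Bias | None = None,
                 rng: np.random.Generator | None = None):
        self.potential = potential
        self.config = config
        self.bias = bias
        self.rng = rng if rng is not None else _replica_rngs(config.seed, 1)[0][0]
        d = potential.dimension
        if config.x0 is not None:
            x0 = np.asarray(config.x0, dtype=float)
            if x0.shape != (d,):
                raise ValueError(
                    f"x0 has shape {x0.shape}, potential dimension is {d}")
            self.x = x0.copy()
        elif potential.ground_truth.get("minima"):
            self.x = np.asarray(potential.ground_truth["minima"][0],
                                dtype=float).copy()
        else:
            self.x = 0.5 * (potential.domain[0] + potential.domain[1])
        dt, g, m, T = (config.timestep, config.friction, config.mass,
                       config.temperature)
        self._c1 = math.exp(-g * dt)
        self._c2 = math.sqrt(KB * T / m * (1.0 - self._c1 ** 2))
        vscale = math.sqrt(KB * T / m) if T > 0 else 0.0
        self.v = vscale * self.rng.standard_normal(d)
        self.step = 0
        u = float(potential.energy(self.x))
        gu = potential.gradient(self.x)
        gb = (bias.force_gradient(self.x, 0, u, gu)
              if bias is not None else 0.0)
        self._f = -(gu + gb)
        self._frames = [self.x.copy()]
        self._energies = [u]

    def run(self, n_steps: int) -> None:
        pot, cfg, bias = self.potential, self.config, self.bias
        dt, m = cfg.timestep, cfg.mass
        half = 0.5 * dt
        c1, c2 = self._c1, self._c2
        noise = self.rng.standard_normal((n_steps, pot.dimension))
        x, v, f = self.x, self.v, self._f
        for i in range(n_steps):
            v = v + half * f / m
            x = x + half * v
            v = c1 * v + c2 * noise[i]
            x = x + half * v
            u = float(pot.energy(x))
            if not math.isfinite(u):
                raise RuntimeError(
                    f"non-finite potential energy at step {self.step + 1}")
            gu = pot.gradient(x)
            if bias is not None:
                f = -(gu + bias.force_gradient(x, self.step + 1, u, gu))
            else:
                f = -gu
            v = v + half * f / m
            self.step += 1
            if bias is not None:
                bias.post_step(x, self.step, u)
            if self.step % cfg.save_stride == 0:
                self._frames.append(x.copy())
                self._energies.append(u)
        self.x, self.v, self._f = x, v, f

    def set_state(self, x: np.ndarray, v: np.ndarray) -> None:
        """Replace coordinates/velocities (replica exchange); refresh force."""
        self.x = np.asarray(x, dtype=float).copy()
        self.v = np.asarray(v, dtype=float).copy()
        u = float(self.potential.energy(self.x))
        gu = self.potential.gradient(self.x)
        if self.bias is not None:
            gb = self.bias.force_gradient(self.x, self.step, u, gu)
            self._f = -(gu + gb)
        else:
            self._f = -gu

    def trajectory(self) -> Trajectory:
        return Trajectory(
            positions=np.array(self._frames),
            dt_ps=self.config.timestep * self.config.save_stride,
            temperature=self.config.temperature,
            energies=np.array(self._energies),
            meta={"config": self.config})


def run_langevin(potential: ModelPotential, config: SamplerConfig,
                 bias: Bias | None = None) -> Trajectory:
    """Single-temperature BAOAB Langevin run; deterministic given the seed."""
    integ = LangevinIntegrator(potential, config, bias=bias)
    integ.run(config.n_steps)
    return integ.trajectory()


# ---------------------------------------------------------------------------
# replica exchange
# ---------------------------------------------------------------------------

def _replica_rngs(seed: int, n: int):
    """Per-replica random streams plus a separate exchange-decision stream.

    Child ``k`` of a SeedSequence depends only on ``(seed, k)``, so replica 0
    of an n-replica ensemble shares its stream with a single-replica run at
    the same master seed.
    """
    children = np.random.SeedSequence(seed).spawn(n)
    rngs = [np.random.default_rng(c) for c in children]
    exchange = np.random.default_rng(np.random.SeedSequence([seed, 0xE5C]))
    return rngs, exchange


def exchange_log_ratio(beta_i: float, beta_j: float, u_i: float, u_j: float,
                       v_i_si: float = 0.0, v_i_sj: float = 0.0,
                       v_j_sj: float = 0.0, v_j_si: float = 0.0) -> float:
    """Metropolis log-ratio for swapping configurations between replicas.

    ``v_a_sb`` is replica a's bias evaluated at replica b's CV position.
    Detailed balance for the product ensemble gives
    ``(beta_i - beta_j)(U_i - U_j) + beta_i [V_i(s_i) - V_i(s_j)]
    + beta_j [V_j(s_j) - V_j(s_i)]``.
    """
    return ((beta_i - beta_j) * (u_i - u_j)
            + beta_i * (v_i_si - v_i_sj) + beta_j * (v_j_sj - v_j_si))


def attempt_exchange(rep_i: LangevinIntegrator, rep_j: LangevinIntegrator,
                     rng: np.random.Generator) -> bool:
    """Attempt a configuration swap between two replicas (Metropolis).

    Each replica's bias (if any) is evaluated exactly at both replicas'
    current coordinates.  On acceptance, coordinates are swapped and
    velocities rescaled by sqrt(T_new/T_old).
    """
    if rep_i.potential is not rep_j.potential:
        raise ValueError("replicas must share the same potential")
    ti, tj = rep_i.config.temperature, rep_j.config.temperature
    bi, bj = 1.0 / (KB * ti), 1.0 / (KB * tj)
    u_i = float(rep_i.potential.energy(rep_i.x))
    u_j = float(rep_j.potential.energy(rep_j.x))
    kw = {}
    if rep_i.bias is not None:
        kw["v_i_si"] = rep_i.bias.energy(rep_i.x, rep_i.step, u=u_i)
        kw["v_i_sj"] = rep_i.bias.energy(rep_j.x, rep_i.step, u=u_j)
    if rep_j.bias is not None:
        kw["v_j_sj"] = rep_j.bias.energy(rep_j.x, rep_j.step, u=u_j)
        kw["v_j_si"] = rep_j.bias.energy(rep_i.x, rep_j.step, u=u_i)
    delta = exchange_log_ratio(bi, bj, u_i, u_j, **kw)
    accepted = bool(delta >= 0.0 or rng.random() < math.exp(delta))
    if accepted:
        xi, vi = rep_i.x.copy(), rep_i.v.copy()
        xj, vj = rep_j.x.copy(), rep_j.v.copy()
        si = math.sqrt(ti / tj) if tj > 0 else 1.0
        sj = math.sqrt(tj / ti) if ti > 0 else 1.0
        rep_i.set_state(xj, vj * si)
        rep_j.set_state(xi, vi * sj)
    return accepted


@dataclass
class ReplicaEnsemble:
    """Result of a parallel-tempering run."""

    temperatures: tuple[float, ...]
    trajectories: list[Trajectory]
    exchange_log: list[tuple[int, tuple[int, int], bool]]
    exchange_interval: int
    biases: list[Bias | None] = field(default_factory=list)

    def acceptance_by_pair(self) -> dict[tuple[int, int], float]:
        """Accepted fraction of attempted swaps per adjacent pair."""
        att: dict[tuple[int, int], list[int]] = {}
        for _, pair, ok in self.exchange_log:
            att.setdefault(pair, []).append(int(ok))
        return {p: float(np.mean(v)) for p, v in sorted(att.items())}


def run_parallel_tempering(potential: ModelPotential,
                           temperatures,
                           config: SamplerConfig,
                           biases: list[Bias | None] | None = None,
                           exchange_interval: int = 500) -> ReplicaEnsemble:
    """Parallel tempering: independent Langevin streams + periodic swaps.

    ``config.temperature`` is ignored; each replica runs at its ladder
    temperature with its own counter-based random substream, so the ensemble
    is reproducible from the single master seed.  Exchange attempts sweep
    alternating even/odd adjacent pairs every ``exchange_interval`` steps.
    With a single temperature the run is identical to :func:`run_langevin`.
    """
    temps = tuple(float(t) for t in temperatures)
    if any(b >= a for a, b in zip(temps[1:], temps[:-1])):
        raise ValueError("temperatures must be strictly increasing")
    n = len(temps)
    biases = biases if biases is not None else [None] * n
    if len(biases) != n:
        raise ValueError("need one bias entry per replica")
    rngs, xrng = _replica_rngs(config.seed, n)
    reps = [LangevinIntegrator(potential,
                               replace(config, temperature=t),
                               bias=b, rng=r)
            for t, b, r in zip(temps, biases, rngs)]
    log: list[tuple[int, tuple[int, int], bool]] = []
    n_chunks, rest = divmod(config.n_steps, exchange_interval)
    for c in range(n_chunks):
        for r in reps:
            r.run(exchange_interval)
        if n > 1:
            start = c % 2
            for k in range(start, n - 1, 2):
                ok = attempt_exchange(reps[k], reps[k + 1], xrng)
                log.append((reps[0].step, (k, k + 1), ok))
    if rest:
        for r in reps:
            r.run(rest)
    return ReplicaEnsemble(
        temperatures=temps,
        trajectories=[r.trajectory() for r in reps],
        exchange_log=log,
        exchange_interval=exchange_interval,
        biases=list(biases))
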