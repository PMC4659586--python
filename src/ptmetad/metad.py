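"""Metadynamics production runs: single-replica WT-metaD and PTmetaD(-WTE).

These drivers couple the Langevin engine to live metadynamics biases and
return everything downstream reconstruction needs: trajectories, CV series
evaluated at the saved frames, and the per-replica hill logs.  In the
parallel-tempering variant each replica deposits and keeps its own hills
(no bias exchange), which is what makes per-temperature free-energy surfaces
— and hence the dG(T) enthalpy/entropy fit — reconstructable.

The optional well-tempered ensemble (WTE) adds a metadynamics bias on the
potential energy itself, grown during a preliminary phase and then held
fixed; it broadens the energy distributions and so boosts replica-exchange
acceptance without extra replicas.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cvs import CoordinateCV, DihedralSimilarityCV, PotentialEnergyCV
from .hills import CompositeBias, HillsLog, MetadBias, MetadParams
from .potentials import ModelPotential
from .sampling import ReplicaEnsemble, SamplerConfig, run_langevin
from .trajectory import Trajectory


def cv_values(cvs, positions: np.ndarray) -> np.ndarray:
    """Evaluate a CV list on saved frames -> (n_frames, n_cvs)."""
    cols = []
    for cv in cvs:
        if hasattr(cv, "values"):
            cols.append(np.asarray(cv.values(positions), dtype=float))
        else:
            cols.append(np.array([cv.value(x) for x in positions]))
    return np.stack(cols, axis=1)


def default_grid_bounds(potential: ModelPotential, cvs):
    """Bias-grid bounds inferred per CV (coordinate domain or CV range)."""
    lo, hi = [], []
    for cv in cvs:
        if isinstance(cv, CoordinateCV):
            lo.append(potential.domain[0][cv.index])
            hi.append(potential.domain[1][cv.index])
        elif isinstance(cv, DihedralSimilarityCV):
            lo.append(-0.2)
            hi.append(cv.n_dihedrals + 0.2)
        else:
            raise ValueError(
                f"cannot infer grid bounds for {type(cv).__name__}; "
                "pass grid_bounds explicitly")
    return np.array(lo), np.array(hi)


@dataclass
class WtmetadResult:
    """Trajectory + CV series + hill log of a well-tempered metaD run."""

    trajectory: Trajectory
    cv_series: np.ndarray
    hills: HillsLog
    bias: MetadBias


def run_wtmetad(potential: ModelPotential, cvs, params: MetadParams,
                config: SamplerConfig, grid_bounds=None,
                grid_bins: int = 201, periods=None) -> WtmetadResult:
    """Well-tempered metadynamics on a model potential.

    A hill is deposited every ``params.deposition_stride`` steps at the
    current CV values with the well-tempered height; the bias force uses the
    grid cache, while logged heights/energies are exact direct sums.  With
    ``params.height == 0`` the trajectory equals the unbiased run with the
    same seed.
    """
    if grid_bounds is None:
        grid_bounds = default_grid_bounds(potential, cvs)
    bias = MetadBias(cvs, params, timestep=config.timestep,
                     grid_min=grid_bounds[0], grid_max=grid_bounds[1],
                     grid_bins=grid_bins, periods=periods)
    traj = run_langevin(potential, config, bias=bias)
    series = cv_values(cvs, traj.positions)
    return WtmetadResult(trajectory=traj, cv_series=series,
                         hills=bias.hills_log(), bias=bias)


@dataclass
class PtmetadResult:
    """Per-replica output of a PTmetaD(-WTE) run."""

    ensemble: ReplicaEnsemble
    cv_series: list[np.ndarray]
    hills: list[HillsLog]
    wte_hills: list[HillsLog] | None = None

    @property
    def temperatures(self):
        return self.ensemble.temperatures


def run_ptmetad(potential: ModelPotential, cvs, params: MetadParams,
                temperatures, config: SamplerConfig,
                wte_params: MetadParams | None = None,
                wte_grow_steps: int | None = None,
                wte_energy_range: tuple[float, float] | None = None,
                exchange_interval: int = 500,
                grid_bounds=None, grid_bins: int = 201,
                periods=None) -> PtmetadResult:
    """Parallel-tempering well-tempered metadynamics, optionally in the WTE.

    Each replica deposits an independent hill log at its own temperature
    (``params.temperature`` is overridden per replica, which sets each
    replica's well-tempered dT).  Exchange acceptance includes every
    replica's bias evaluated at both swap partners' coordinates.

    With ``wte_params`` set, a metadynamics bias on the potential energy is
    grown for ``wte_grow_steps`` (default: first 20% of the run) while CV
    hills are withheld; the energy bias is then frozen and CV deposition
    starts.  ``wte_energy_range`` bounds the energy grid.
    """
    temps = tuple(float(t) for t in temperatures)
    if grid_bounds is None:
        grid_bounds = default_grid_bounds(potential, cvs)
    start_cv = 0
    wte_biases: list[MetadBias | None] = [None] * len(temps)
    if wte_params is not None:
        if wte_energy_range is None:
            raise ValueError("wte_energy_range is required with wte_params")
        if wte_grow_steps is None:
            wte_grow_steps = config.n_steps // 5
        start_cv = wte_grow_steps
    biases = []
    cv_biases = []
    for k, t in enumerate(temps):
        p = MetadParams(height=params.height, widths=params.widths,
                        deposition_stride=params.deposition_stride,
                        bias_factor=params.bias_factor, temperature=t)
        mb = MetadBias(cvs, p, timestep=config.timestep,
                       grid_min=grid_bounds[0], grid_max=grid_bounds[1],
                       grid_bins=grid_bins, periods=periods,
                       start_after_step=start_cv)
        cv_biases.append(mb)
        if wte_params is not None:
            wp = MetadParams(height=wte_params.height,
                             widths=wte_params.widths,
                             deposition_stride=wte_params.deposition_stride,
                             bias_factor=wte_params.bias_factor,
                             temperature=t)
            wb = MetadBias([PotentialEnergyCV(potential)], wp,
                           timestep=config.timestep,
                           grid_min=[wte_energy_range[0]],
                           grid_max=[wte_energy_range[1]],
                           grid_bins=grid_bins,
                           freeze_after_step=wte_grow_steps)
            wte_biases[k] = wb
            biases.append(CompositeBias(mb, wb))
        else:
            biases.append(mb)
    from .sampling import run_parallel_tempering
    ens = run_parallel_tempering(potential, temps, config, biases=biases,
                                 exchange_interval=exchange_interval)
    series = [cv_values(cvs, tr.positions) for tr in ens.trajectories]
    return PtmetadResult(
        ensemble=ens,
        cv_series=series,
        hills=[b.hills_log() for b in cv_biases],
        wte_hills=([b.hills_log() if b is not None and b._times else None
                    for b in wte_biases] if wte_params is not None else None))
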