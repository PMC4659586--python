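"""Sub-microsecond flexibility analysis: windowed RMSF and PCA projection.

RMSF is computed in non-overlapping time windows (after discarding an
equilibration segment) so that slow drifts do not inflate the fast
fluctuations; within each window every frame is superposed on the window
mean (iterative Kabsch alignment) and the per-atom root-mean-square
deviation from that mean is averaged over windows.

PCA diagonalises the covariance of the aligned selected coordinates; other
trajectories can be projected onto a reference mode set, and the explored
area in the first two components (convex-hull area) summarises how much
conformational space a trajectory diffuses over — a rigidified system
explores a strictly smaller area.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull

from .cvs import superpose
from .trajectory import Trajectory


def _align_to_mean(frames: np.ndarray, selection: np.ndarray,
                   tol: float = 1e-11, max_passes: int = 30
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superpose frames on their mean structure.

    Frames are first superposed on the first frame (which makes the whole
    procedure exactly covariant under per-frame rigid motions, up to one
    global gauge rotation); each subsequent pass aligns every frame to the
    current mean and recomputes it, stopping when the mean moves by less
    than ``tol`` (typically two or three passes).
    """
    from .cvs import kabsch_rotation
    aligned = np.array([superpose(f, frames[0], selection) for f in frames])
    mean = aligned.mean(axis=0)
    for _ in range(max_passes):
        aligned = np.array([superpose(f, mean, selection) for f in aligned])
        new_mean = aligned.mean(axis=0)
        # remove the residual gauge rotation of the ensemble (weakly
        # determined for quasi-degenerate shapes) before testing convergence
        cm = new_mean[selection].mean(axis=0)
        cr = mean[selection].mean(axis=0)
        rot = kabsch_rotation(new_mean[selection] - cm,
                              mean[selection] - cr)
        aligned = (aligned - cm) @ rot + cr
        new_mean = (new_mean - cm) @ rot + cr
        shift = float(np.max(np.abs(new_mean - mean)))
        mean = new_mean
        if shift < tol:
            break
    return aligned, mean


@dataclass
class RmsfProfile:
    """Per-atom RMSF (Angstrom) averaged over non-overlapping windows."""

    per_atom_rmsf: np.ndarray
    window_length: float      # ns
    discard: float            # ns
    n_windows: int
    selection: np.ndarray

    def region_average(self, region: Sequence[int]) -> float:
        """Unweighted mean RMSF over a region (must lie in the selection)."""
        region = np.asarray(list(region), dtype=int)
        sel_index = {a: i for i, a in enumerate(self.selection)}
        missing = [a for a in region if a not in sel_index]
        if missing or region.size == 0:
            raise ValueError(
                "region must be a non-empty subset of the RMSF selection")
        return float(self.per_atom_rmsf[[sel_index[a] for a in region]].mean())


def windowed_rmsf(traj: Trajectory, selection: Sequence[int] | None = None,
                  window_length: float = 30.0, discard: float = 100.0
                  ) -> RmsfProfile:
    """RMSF averaged over non-overlapping windows of ``window_length`` ns.

    The first ``discard`` ns are dropped; trailing frames not filling a
    whole window are dropped.  Within each window frames are aligned to the
    window mean on ``selection`` before the per-atom deviation is taken.
    """
    pos = traj.positions
    if pos.ndim != 3:
        raise ValueError("windowed_rmsf needs Cartesian (frames, atoms, 3)")
    selection = (np.arange(pos.shape[1]) if selection is None
                 else np.asarray(list(selection), dtype=int))
    if selection.size == 0:
        raise ValueError("selection must be non-empty")
    spacing_ns = traj.dt_ps / 1000.0
    duration = traj.duration_ns
    n_windows = int(np.floor((duration - discard) / window_length))
    if n_windows < 1:
        raise ValueError(
            f"trajectory too short: {duration:g} ns with {discard:g} ns "
            f"discard yields n_windows={max(n_windows, 0)}")
    frames_per_window = int(round(window_length / spacing_ns))
    start = int(round(discard / spacing_ns))
    profiles = []
    for w in range(n_windows):
        chunk = pos[start + w * frames_per_window:
                    start + (w + 1) * frames_per_window]
        aligned, mean = _align_to_mean(chunk, selection)
        d = aligned[:, selection] - mean[selection]
        profiles.append(np.sqrt((d * d).sum(axis=2).mean(axis=0)))
    return RmsfProfile(per_atom_rmsf=np.mean(profiles, axis=0),
                       window_length=window_length, discard=discard,
                       n_windows=n_windows, selection=selection)


def region_average(profile: RmsfProfile, region: Sequence[int]) -> float:
    """Mean RMSF over a residue region (functional spelling)."""
    return profile.region_average(region)


@dataclass
class PcaModes:
    """Principal modes of the aligned coordinate covariance.

    ``eigenvectors`` rows are orthonormal 3N-dimensional directions over the
    selection, ordered by decreasing variance ``eigenvalues`` (A^2).
    """

    mean_structure: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    selection: np.ndarray


def pca_modes(traj: Trajectory, selection: Sequence[int] | None = None
              ) -> PcaModes:
    """Eigendecomposition of the 3N x 3N covariance of aligned coordinates."""
    pos = traj.positions
    if pos.ndim != 3:
        raise ValueError("pca_modes needs Cartesian (frames, atoms, 3)")
    selection = (np.arange(pos.shape[1]) if selection is None
                 else np.asarray(list(selection), dtype=int))
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    aligned, mean = _align_to_mean(pos, selection)
    x = (aligned[:, selection] - mean[selection]).reshape(pos.shape[0], -1)
    if np.max(np.abs(x)) < 1e-10:
        raise ValueError("degenerate trajectory: all frames identical")
    # SVD of the centred data matrix; eigenvalues of the covariance are s^2/n
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s ** 2 / x.shape[0]
    return PcaModes(mean_structure=mean, eigenvectors=vt,
                    eigenvalues=eigvals, selection=selection)


@dataclass
class ModeProjection:
    """Trajectory projected on reference modes, with the explored-area
    (convex hull over the first two components) diffusion summary."""

    coordinates: np.ndarray     # (n_frames, k)
    hull_area: float            # A^2 over components 1-2 (nan if k < 2)

    @property
    def variances(self) -> np.ndarray:
        return self.coordinates.var(axis=0)


def project_onto_modes(traj: Trajectory, modes: PcaModes, k: int = 2,
                       atom_map: Sequence[int] | None = None
                       ) -> ModeProjection:
    """Project frames onto the first ``k`` reference eigenvectors.

    Each frame is superposed on the reference mean structure (cross-system
    projections supply ``atom_map`` to map this trajectory's atoms onto the
    reference selection; equal atom counts are required).
    """
    pos = traj.positions
    sel = modes.selection if atom_map is None else np.asarray(
        list(atom_map), dtype=int)
    if sel.size != modes.selection.size:
        raise ValueError(
            f"atom count mismatch: trajectory selection has {sel.size}, "
            f"modes expect {modes.selection.size}")
    coords = np.empty((pos.shape[0], k))
    basis = modes.eigenvectors[:k]
    for i, f in enumerate(pos):
        al = superpose(f[sel], modes.mean_structure[modes.selection],
                       np.arange(sel.size))
        x = (al - modes.mean_structure[modes.selection]).ravel()
        coords[i] = basis @ x
    area = np.nan
    if k >= 2 and pos.shape[0] >= 3:
        try:
            area = float(ConvexHull(coords[:, :2]).volume)
        except Exception:
            area = 0.0
    return ModeProjection(coordinates=coords, hull_area=area)
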