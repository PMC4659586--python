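"""Analytic model potentials with quadrature ground truth.

These toy systems mirror the statistical structure of kinase conformational
landscapes — two metastable basins separated by a barrier, basin asymmetry
(enthalpy), basin-width ratios (entropy), a periodic multi-dihedral flip, and
a two-channel (un-)binding topology — while remaining cheap enough that exact
basin free energies are available by numerical quadrature.  Every potential
carries its oracle in ``ground_truth`` so downstream estimators can be tested
against known answers.

Energies are in kJ/mol, coordinates in Angstrom (or radians for dihedral
systems), temperatures in K.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate
from scipy.special import expit

from .trajectory import Trajectory
from .units import KB


@dataclass
class ModelPotential:
    """Analytic energy/gradient on 1-3 coordinates plus oracle metadata.

    ``energy`` maps arrays of shape ``(..., dimension)`` to energies of shape
    ``(...,)``; ``gradient`` maps the same input to ``(..., dimension)``.
    ``ground_truth`` holds basin definitions and quadrature oracles (see the
    individual factory functions).
    """

    dimension: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    domain: tuple[np.ndarray, np.ndarray]
    periodic: tuple[bool, ...] = ()
    ground_truth: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        lo, hi = self.domain
        lo = np.atleast_1d(np.asarray(lo, dtype=float))
        hi = np.atleast_1d(np.asarray(hi, dtype=float))
        if lo.shape != (self.dimension,) or hi.shape != (self.dimension,):
            raise ValueError("domain bounds must match the potential dimension")
        self.domain = (lo, hi)
        if not self.periodic:
            self.periodic = (False,) * self.dimension


def finite_difference_gradient(pot: ModelPotential, x: np.ndarray,
                               h: float = 1e-5) -> np.ndarray:
    """Central finite difference of the energy; used to cross-check gradients."""
    x = np.asarray(x, dtype=float)
    g = np.empty_like(x)
    for k in range(x.shape[-1]):
        dp = x.copy()
        dm = x.copy()
        dp[..., k] += h
        dm[..., k] -= h
        g[..., k] = (pot.energy(dp) - pot.energy(dm)) / (2 * h)
    return g


# ---------------------------------------------------------------------------
# 1D double well
# ---------------------------------------------------------------------------

def _basin_delta_f_1d(energy_x: Callable[[np.ndarray], np.ndarray],
                      lo: float, sep: float, hi: float,
                      temperature: float) -> float:
    """Exact F[right] - F[left] by adaptive quadrature of Boltzmann weights."""
    b = 1.0 / (KB * temperature)

    def boltz(x):
        return np.exp(-b * energy_x(np.asarray(x)[..., None]))

    za, _ = integrate.quad(boltz, lo, sep, limit=400)
    zb, _ = integrate.quad(boltz, sep, hi, limit=400)
    return -KB * temperature * np.log(zb / za)


DEFAULT_TEMPERATURES = (305.0, 328.75, 352.5, 376.25, 400.0)


def make_double_well(barrier_height: float, delta_e: float = 0.0,
                     temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
                     ) -> ModelPotential:
    """Quartic 1D double well ``U(x) = h (x^2 - 1)^2 + (dE/2) x``.

    ``barrier_height`` h sets the barrier between the minima near x = -1 and
    x = +1; ``delta_e`` tilts the two basins, the left one ("in") being lower
    for positive ``delta_e``.  The ground truth carries the separatrix (the
    barrier maximum), basin intervals, and the quadrature basin free-energy
    difference F[out] - F[in] per listed temperature.
    """
    if barrier_height <= 0:
        raise ValueError(
            f"barrier_height must be positive, got {barrier_height}")
    h, de = float(barrier_height), float(delta_e)

    def energy(v):
        x = np.asarray(v, dtype=float)[..., 0]
        return h * (x * x - 1.0) ** 2 + 0.5 * de * x

    def gradient(v):
        x = np.asarray(v, dtype=float)[..., 0]
        return (4.0 * h * x * (x * x - 1.0) + 0.5 * de)[..., None]

    # separatrix: the middle (local-max) root of U'(x) = 4h x^3 - 4h x + de/2
    roots = np.roots([4 * h, 0.0, -4 * h, 0.5 * de])
    real = np.sort(roots[np.abs(roots.imag) < 1e-10].real)
    sep = float(real[len(real) // 2]) if len(real) == 3 else 0.0
    lo, hi = -2.5, 2.5

    pot = ModelPotential(
        dimension=1, energy=energy, gradient=gradient,
        domain=(np.array([lo]), np.array([hi])), name="double_well")
    delta_f = {T: _basin_delta_f_1d(energy, lo, sep, hi, T)
               for T in temperatures}
    pot.ground_truth = {
        "separatrix": sep,
        "basins": {"in": {0: (lo, sep)}, "out": {0: (sep, hi)}},
        "basin_order": ("in", "out"),
        "minima": [np.array([-1.0]), np.array([1.0])],
        "delta_f": lambda T: _basin_delta_f_1d(energy, lo, sep, hi, T),
        "delta_f_table": delta_f,
    }
    return pot


# ---------------------------------------------------------------------------
# entropy pair: two harmonic basins with different curvatures
# ---------------------------------------------------------------------------

@dataclass
class TwoBasinSpec:
    """Two locally-harmonic basins with a prescribed enthalpy/entropy split.

    ``delta_e`` offsets the second basin's minimum (the enthalpic difference);
    ``width_ratio`` is the curvature ratio k2/k1, giving an analytic entropy
    difference dS = -(k_B/2) ln(width_ratio) in the harmonic limit.
    """

    barrier_height: float = 20.0
    delta_e: float = 8.368          # 2 kcal/mol
    width_ratio: float = 4.0
    basin_centers: tuple[float, float] = (-1.0, 1.0)
    curvature: float = 20.0         # kJ/mol/A^2 of the first (wide) basin
    smoothing: float = 1.0          # kJ/mol soft-min scale joining the basins

    def __post_init__(self):
        if self.barrier_height <= 0:
            raise ValueError(
                f"barrier_height must be positive, got {self.barrier_height}")
        if self.width_ratio <= 0:
            raise ValueError(
                f"width_ratio must be positive, got {self.width_ratio}")
        if self.curvature <= 0:
            raise ValueError(f"curvature must be positive, got {self.curvature}")
        if not self.basin_centers[0] < self.basin_centers[1]:
            raise ValueError("basin_centers must be increasing")


def make_entropy_pair(spec: TwoBasinSpec | None = None, **kw) -> ModelPotential:
    """1D two-basin potential with analytic enthalpy/entropy ground truth.

    The two parabolas ``k/2 (x-c1)^2`` and ``k r/2 (x-c2)^2 + dE`` are joined
    by a smooth soft-min; a narrow Gaussian bump at the crossing adjusts the
    barrier to ``spec.barrier_height``.  In the harmonic limit
    dH = dE and dS = -(k_B/2) ln r exactly; the quadrature oracle in
    ``ground_truth`` gives the exact values for the actual potential.
    """
    spec = spec or TwoBasinSpec(**kw)
    k1 = spec.curvature
    k2 = spec.curvature * spec.width_ratio
    c1, c2 = spec.basin_centers
    de, al = spec.delta_e, spec.smoothing

    def parts(x):
        u1 = 0.5 * k1 * (x - c1) ** 2
        u2 = 0.5 * k2 * (x - c2) ** 2 + de
        return u1, u2

    def softmin_energy(x):
        u1, u2 = parts(x)
        return -al * np.logaddexp(-u1 / al, -u2 / al)

    # place the barrier bump at the soft-min crossing maximum
    grid = np.linspace(c1, c2, 4001)
    ug = softmin_energy(grid)
    xb = float(grid[np.argmax(ug)])
    amp = spec.barrier_height - float(np.max(ug))
    wb = (c2 - c1) / 16.0   # narrow so basin harmonicity is preserved

    def energy(v):
        x = np.asarray(v, dtype=float)[..., 0]
        return softmin_energy(x) + amp * np.exp(-(x - xb) ** 2 / (2 * wb * wb))

    def gradient(v):
        x = np.asarray(v, dtype=float)[..., 0]
        u1, u2 = parts(x)
        w1 = expit((u2 - u1) / al)   # weight of basin 1
        du = w1 * k1 * (x - c1) + (1.0 - w1) * k2 * (x - c2)
        du = du - amp * (x - xb) / (wb * wb) * np.exp(
            -(x - xb) ** 2 / (2 * wb * wb))
        return du[..., None]

    lo = c1 - 4.0
    hi = c2 + 4.0
    pot = ModelPotential(
        dimension=1, energy=energy, gradient=gradient,
        domain=(np.array([lo]), np.array([hi])), name="entropy_pair")

    # separatrix of the full potential (bump shifts it slightly)
    fine = np.linspace(c1, c2, 8001)
    sep = float(fine[np.argmax(energy(fine[:, None]))])
    pot.ground_truth = {
        "separatrix": sep,
        "basins": {"wide": {0: (lo, sep)}, "narrow": {0: (sep, hi)}},
        "basin_order": ("wide", "narrow"),
        "minima": [np.array([c1]), np.array([c2])],
        "delta_f": lambda T: _basin_delta_f_1d(energy, lo, sep, hi, T),
        "delta_h_harmonic": de,
        "delta_s_harmonic": -0.5 * KB * np.log(spec.width_ratio),
        "spec": spec,
    }
    return pot


# ---------------------------------------------------------------------------
# toy multi-dihedral flip chain
# ---------------------------------------------------------------------------

def _wrap_angle(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


def make_dihedral_flip_system(n_dihedrals: int,
                              ref_in: Sequence[float],
                              ref_out: Sequence[float],
                              coupling: float = 0.0,
                              well_depth: float = 10.0,
                              asymmetry: float = 0.0) -> ModelPotential:
    """Periodic potential with two metastable states at ``ref_in``/``ref_out``.

    Per dihedral, ``u_i = (1 - cos(t - in_i)) (1 - cos(t - out_i))`` vanishes
    with zero gradient at both references, so both reference states are exact
    stationary points.  ``coupling`` adds pairwise terms ``c u_i u_j`` (also
    stationary at the pure states) and ``asymmetry`` lifts the "out" state by
    the stated total energy (exactly so for antipodal references).

    Ground truth (for ``n_dihedrals`` <= 3) is computed on a dense periodic
    grid: basin populations split by the dihedral-similarity value
    ``f = sum_i (1 + cos(t_i - in_i))/2`` at threshold n/2.
    """
    ref_in = np.atleast_1d(np.asarray(ref_in, dtype=float))
    ref_out = np.atleast_1d(np.asarray(ref_out, dtype=float))
    n = int(n_dihedrals)
    if n < 1:
        raise ValueError(f"n_dihedrals must be >= 1, got {n}")
    if ref_in.shape != (n,) or ref_out.shape != (n,):
        raise ValueError("reference angle lists must have length n_dihedrals")
    if np.any(np.abs(_wrap_angle(ref_in - ref_out)) < 1e-9):
        raise ValueError("ref_in and ref_out must differ for every dihedral")
    A, c, asym = float(well_depth), float(coupling), float(asymmetry)

    def _u(theta):
        return ((1.0 - np.cos(theta - ref_in))
                * (1.0 - np.cos(theta - ref_out)))

    def energy(v):
        th = np.asarray(v, dtype=float)
        u = _u(th)
        e = A * u.sum(axis=-1)
        if asym != 0.0:
            e = e + (asym / n) * (((1.0 - np.cos(th - ref_in)) / 2.0) ** 2
                                  ).sum(axis=-1)
        if c != 0.0 and n > 1:
            s1 = u.sum(axis=-1)
            s2 = (u * u).sum(axis=-1)
            e = e + c * 0.5 * (s1 * s1 - s2)
        return e

    def gradient(v):
        th = np.asarray(v, dtype=float)
        sin_in = np.sin(th - ref_in)
        sin_out = np.sin(th - ref_out)
        cos_in = np.cos(th - ref_in)
        cos_out = np.cos(th - ref_out)
        u = (1.0 - cos_in) * (1.0 - cos_out)
        du = sin_in * (1.0 - cos_out) + (1.0 - cos_in) * sin_out
        g = A * du
        if asym != 0.0:
            g = g + (asym / n) * (1.0 - cos_in) * sin_in / 2.0
        if c != 0.0 and n > 1:
            s1 = u.sum(axis=-1, keepdims=True)
            g = g + c * du * (s1 - u)
        return g

    pot = ModelPotential(
        dimension=n, energy=energy, gradient=gradient,
        domain=(np.full(n, -np.pi), np.full(n, np.pi)),
        periodic=(True,) * n, name="dihedral_flip")

    gt: dict = {
        "minima": [ref_in.copy(), ref_out.copy()],
        "ref_in": ref_in.copy(), "ref_out": ref_out.copy(),
        "basin_order": ("in", "out"),
        "similarity_threshold": n / 2.0,
    }
    if n <= 3:
        npts = 121 if n == 3 else 721
        axes = [np.linspace(-np.pi, np.pi, npts, endpoint=False)
                for _ in range(n)]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        ug = energy(mesh)
        fg = ((1.0 + np.cos(mesh - ref_in)) / 2.0).sum(axis=-1)
        mask_in = fg > n / 2.0

        def delta_f(T, _ug=ug, _mask=mask_in):
            w = np.exp(-(_ug - _ug.min()) / (KB * T))
            return -KB * T * np.log(w[~_mask].sum() / w[_mask].sum())

        gt["delta_f"] = delta_f
    pot.ground_truth = gt
    return pot


# ---------------------------------------------------------------------------
# two-channel binding topology
# ---------------------------------------------------------------------------

def make_two_channel_binding_potential(depth_bound: float = 20.0,
                                       depth_external: float = 8.0,
                                       barrier_1: float = 15.0,
                                       barrier_2: float = 18.0,
                                       ring_radius: float = 3.0,
                                       ring_width: float = 0.35,
                                       wall_height: float = 60.0,
                                       notch_width: float = 0.3,
                                       channel_angles: tuple[float, float] = (0.0, np.pi),
                                       ) -> ModelPotential:
    """2D toy (un-)binding landscape: deep bound pose, external pose, two exits.

    A circular barrier ridge of height ``wall_height`` at ``ring_radius``
    separates the inner region from an unbound plateau (U = 0); two Gaussian
    notches in the ridge at ``channel_angles`` lower it to ``barrier_1`` and
    ``barrier_2``, forming the exit channels.  A deep Gaussian well at the
    origin is the crystallographic pose and a shallower well on the channel-1
    axis is the external pose.  ``barrier_2 = inf`` removes the second channel
    (a single-exit topology).  A quartic wall confines the plateau.
    """
    for nm, val in [("depth_bound", depth_bound),
                    ("depth_external", depth_external),
                    ("barrier_1", barrier_1), ("barrier_2", barrier_2)]:
        if not val > 0:
            raise ValueError(f"{nm} must be positive, got {val}")
    r0, sr = ring_radius, ring_width
    hw, sphi = wall_height, notch_width
    phi1, phi2 = channel_angles
    sb, se = 0.5, 0.35
    ext = np.array([r0 - 1.3, 0.0])
    rc, ck = r0 + 1.5, 10.0
    notches = [(phi1, barrier_1)]
    if np.isfinite(barrier_2):
        notches.append((phi2, barrier_2))

    def ridge_height(phi):
        h = np.full_like(phi, hw, dtype=float)
        for pc, b in notches:
            h = h - (hw - b) * np.exp(-_wrap_angle(phi - pc) ** 2
                                      / (2 * sphi * sphi))
        return h

    def ridge_height_dphi(phi):
        d = np.zeros_like(phi, dtype=float)
        for pc, b in notches:
            dphi = _wrap_angle(phi - pc)
            d = d + (hw - b) * dphi / (sphi * sphi) * np.exp(
                -dphi * dphi / (2 * sphi * sphi))
        return d

    def energy(v):
        xy = np.asarray(v, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        r = np.hypot(x, y)
        phi = np.arctan2(y, x)
        e = ridge_height(phi) * np.exp(-(r - r0) ** 2 / (2 * sr * sr))
        e = e - depth_bound * np.exp(-(x * x + y * y) / (2 * sb * sb))
        dx, dy = x - ext[0], y - ext[1]
        e = e - depth_external * np.exp(-(dx * dx + dy * dy) / (2 * se * se))
        e = e + ck * np.maximum(r - rc, 0.0) ** 4
        return e

    def gradient(v):
        xy = np.asarray(v, dtype=float)
        x, y = xy[..., 0], xy[..., 1]
        r = np.hypot(x, y)
        safe = np.maximum(r, 1e-12)
        phi = np.arctan2(y, x)
        g = np.zeros(np.broadcast(x, y).shape + (2,), dtype=float)
        # ridge term
        gr = np.exp(-(r - r0) ** 2 / (2 * sr * sr))
        dgr = -(r - r0) / (sr * sr) * gr
        h = ridge_height(phi)
        dh = ridge_height_dphi(phi)
        gx = dh * (-y / safe ** 2) * gr + h * dgr * (x / safe)
        gy = dh * (x / safe ** 2) * gr + h * dgr * (y / safe)
        near0 = r < 1e-8   # ridge factor is ~exp(-r0^2/2sr^2) ~ 0 there
        gx = np.where(near0, 0.0, gx)
        gy = np.where(near0, 0.0, gy)
        g[..., 0] += gx
        g[..., 1] += gy
        # bound well
        wb = np.exp(-(x * x + y * y) / (2 * sb * sb))
        g[..., 0] += depth_bound * wb * x / (sb * sb)
        g[..., 1] += depth_bound * wb * y / (sb * sb)
        # external well
        dx, dy = x - ext[0], y - ext[1]
        we = np.exp(-(dx * dx + dy * dy) / (2 * se * se))
        g[..., 0] += depth_external * we * dx / (se * se)
        g[..., 1] += depth_external * we * dy / (se * se)
        # confining wall
        over = np.maximum(r - rc, 0.0)
        coef = 4.0 * ck * over ** 3 / safe
        g[..., 0] += coef * x
        g[..., 1] += coef * y
        return g

    half = rc + 0.8
    pot = ModelPotential(
        dimension=2, energy=energy, gradient=gradient,
        domain=(np.array([-half, -half]), np.array([half, half])),
        name="two_channel_binding")

    basins = {
        "bound": {0: (-0.9, 0.9), 1: (-0.9, 0.9)},
        "external": {0: (ext[0] - 0.7, ext[0] + 0.7),
                     1: (ext[1] - 0.7, ext[1] + 0.7)},
    }
    ax = np.linspace(-half, half, 601)
    mesh = np.stack(np.meshgrid(ax, ax, indexing="ij"), axis=-1)
    ug = energy(mesh)

    def _mask(b):
        mx = (mesh[..., 0] >= b[0][0]) & (mesh[..., 0] <= b[0][1])
        my = (mesh[..., 1] >= b[1][0]) & (mesh[..., 1] <= b[1][1])
        return mx & my

    masks = {k: _mask(v) for k, v in basins.items()}

    def delta_f(T, a="bound", b="external", _ug=ug, _m=masks):
        w = np.exp(-(_ug - _ug.min()) / (KB * T))
        return -KB * T * np.log(w[_m[b]].sum() / w[_m[a]].sum())

    pot.ground_truth = {
        "basins": basins,
        "basin_order": ("bound", "external"),
        "minima": [np.zeros(2), ext.copy()],
        "delta_f": delta_f,
        "external_center": ext.copy(),
        "channel_angles": tuple(pc for pc, _ in notches),
        "barriers": tuple(b for _, b in notches),
        "ring_radius": r0,
    }
    return pot


def channel_saddle_heights(pot: ModelPotential,
                           phi_halfwidth: float = 0.6,
                           n_phi: int = 241, n_r: int = 801) -> list[float]:
    """Saddle height of each exit channel by a min-over-angle/max-over-radius
    grid search along the barrier ridge (plateau reference U = 0)."""
    gt = pot.ground_truth
    r0 = gt["ring_radius"]
    rs = np.linspace(1.2, r0 + 1.2, n_r)
    out = []
    for pc in gt["channel_angles"]:
        phis = pc + np.linspace(-phi_halfwidth, phi_halfwidth, n_phi)
        pts = np.empty((n_phi, n_r, 2))
        pts[..., 0] = np.cos(phis)[:, None] * rs[None, :]
        pts[..., 1] = np.sin(phis)[:, None] * rs[None, :]
        u = pot.energy(pts)
        out.append(float(u.max(axis=1).min()))
    return out


# ---------------------------------------------------------------------------
# Gaussian-fluctuation pseudo-protein trajectories
# ---------------------------------------------------------------------------

@dataclass
class Mode:
    """A collective displacement direction with a sinusoidal drive.

    ``direction`` has shape (n_atoms, 3) and is normalised at construction;
    the driven coefficient is ``amplitude * sin(2 pi cycles t / n_frames)``,
    whose variance over full cycles is ``amplitude^2 / 2``.
    """

    direction: np.ndarray
    amplitude: float
    cycles: int = 7
    phase: float = 0.0

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("mode direction must be non-zero")
        self.direction = d / nrm


def chain_mean_structure(n_atoms: int) -> np.ndarray:
    """Helical CA-like mean geometry (rise 1.5 A, radius 2.3 A, 100 deg/res).

    A helix (rather than a straight chain) keeps rotational superposition
    well-conditioned: no rigid rotation leaves the structure near-invariant.
    """
    t = np.arange(n_atoms)
    ang = np.deg2rad(100.0) * t
    return np.stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * t], axis=1)


def _rigid_basis(mean: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6 x 3N) of rigid translations/rotations at mean."""
    n = mean.shape[0]
    com = mean.mean(axis=0)
    fields = []
    for k in range(3):
        d = np.zeros((n, 3))
        d[:, k] = 1.0
        fields.append(d.ravel())
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        fields.append(np.cross(e, mean - com).ravel())
    q, _ = np.linalg.qr(np.stack(fields, axis=1))
    return q.T


def collective_mode(n_atoms: int, atom_indices: Sequence[int],
                    amplitude: float, axis: int = 0, cycles: int = 7,
                    remove_rigid: bool = True) -> Mode:
    """Collective mode displacing the given atoms along one Cartesian axis.

    With ``remove_rigid`` (default) the direction is orthogonalised against
    the rigid-body translations/rotations of the chain mean structure, so
    superposition-based analyses can recover the planted mode exactly.
    """
    d = np.zeros((n_atoms, 3))
    d[np.asarray(atom_indices, dtype=int), axis] = 1.0
    if remove_rigid:
        basis = _rigid_basis(chain_mean_structure(n_atoms))
        flat = d.ravel() - basis.T @ (basis @ d.ravel())
        d = flat.reshape(n_atoms, 3)
    return Mode(direction=d, amplitude=amplitude, cycles=cycles)


@dataclass
class FluctuationTrajectorySpec:
    """Pseudo-protein trajectory: isotropic Gaussian noise + planted modes."""

    n_atoms: int
    per_atom_sigma: float | np.ndarray = 0.5   # Angstrom
    mode_vectors: list[Mode] = field(default_factory=list)
    n_frames: int = 2000
    frame_spacing: float = 0.1                 # ns between frames
    seed: int = 0

    def __post_init__(self):
        if self.n_atoms < 1:
            raise ValueError(f"n_atoms must be >= 1, got {self.n_atoms}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.seed is None:
            raise ValueError("seed must be provided")


def make_fluctuation_trajectory(spec: FluctuationTrajectorySpec) -> Trajectory:
    """Synthetic Cartesian trajectory with known RMSF and principal modes.

    Atoms sit on a helical CA-like chain; each frame adds independent isotropic
    Gaussian displacements of scale ``per_atom_sigma`` (expected RMSF
    sqrt(3) sigma) plus the driven collective modes.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    mean = chain_mean_structure(spec.n_atoms)
    sig = np.broadcast_to(np.asarray(spec.per_atom_sigma, dtype=float),
                          (spec.n_atoms,))
    pos = mean[None] + rng.standard_normal(
        (spec.n_frames, spec.n_atoms, 3)) * sig[None, :, None]
    t = np.arange(spec.n_frames)
    for m in spec.mode_vectors:
        coef = m.amplitude * np.sin(
            2 * np.pi * m.cycles * t / spec.n_frames + m.phase)
        pos = pos + coef[:, None, None] * m.direction[None]
    return Trajectory(positions=pos, dt_ps=spec.frame_spacing * 1000.0,
                      meta={"spec": spec, "mean": mean})
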