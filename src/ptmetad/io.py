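"""File formats: HILLS/COLVAR dialect, FES tables, config, trajectories.

HILLS and COLVAR files follow the whitespace-separated PLUMED dialect with a
leading ``#! FIELDS ...`` header; floats are written at 17 significant
digits so read(write(x)) round-trips exactly.  Raw files carry kJ/mol, ps
and Angstrom; reports are in kcal/mol.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fes import FreeEnergySurface
from .hills import HillsLog


def _fmt(x: float) -> str:
    return f"{x:.17g}"


# ---------------------------------------------------------------------------
# HILLS
# ---------------------------------------------------------------------------

def write_hills(log: HillsLog, path) -> None:
    """Write a hill log in the HILLS dialect.

    Columns: time, one center per CV, one sigma per CV, height, biasf.
    Heights are stored as deposited (well-tempered-scaled).
    """
    path = Path(path)
    names = list(log.cv_names)
    cols = (["time"] + names + [f"sigma_{n}" for n in names]
            + ["height", "biasf"])
    lines = ["#! FIELDS " + " ".join(cols)]
    lines.append(f"#! SET temperature {_fmt(log.temperature)}")
    for k, p in enumerate(log.periods):
        if p is not None:
            lines.append(f"#! SET period_{names[k]} {_fmt(p)}")
    for i in range(log.n_hills):
        row = ([_fmt(log.times[i])]
               + [_fmt(c) for c in log.centers[i]]
               + [_fmt(w) for w in log.widths[i]]
               + [_fmt(log.heights[i]), _fmt(log.bias_factor)])
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_hills(path) -> HillsLog:
    """Parse a HILLS file; errors carry the offending line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise ValueError(f"{path}:1: missing '#! FIELDS' header")
    fields = lines[0].split()[2:]
    if (len(fields) < 4 or fields[0] != "time" or fields[-1] != "biasf"
            or fields[-2] != "height"):
        raise ValueError(f"{path}:1: malformed HILLS header: {fields}")
    body = fields[1:-2]
    n_sigma = sum(1 for f in body if f.startswith("sigma_"))
    names = body[:len(body) - n_sigma]
    if len(names) != n_sigma or any(
            body[len(names) + k] != f"sigma_{names[k]}"
            for k in range(n_sigma)):
        raise ValueError(
            f"{path}:1: CV and sigma column counts do not match")
    d = len(names)
    temperature = np.nan
    periods: list[float | None] = [None] * d
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#! SET"):
            _, _, key, val = s.split(None, 3)
            if key == "temperature":
                temperature = float(val)
            elif key.startswith("period_"):
                periods[names.index(key[len("period_"):])] = float(val)
            continue
        if s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) != 1 + 2 * d + 2:
            raise ValueError(
                f"{path}:{ln}: expected {1 + 2 * d + 2} columns, "
                f"got {len(parts)}")
        rows.append([float(p) for p in parts])
    arr = np.array(rows) if rows else np.empty((0, 1 + 2 * d + 2))
    times = arr[:, 0]
    if times.size and np.any(np.diff(times) <= 0):
        bad = int(np.argmax(np.diff(times) <= 0)) + 1
        raise ValueError(f"{path}: non-monotone time at data row {bad + 1}")
    return HillsLog(times=times, centers=arr[:, 1:1 + d],
                    widths=arr[:, 1 + d:1 + 2 * d], heights=arr[:, 1 + 2 * d],
                    bias_factor=float(arr[0, -1]) if rows else np.nan,
                    temperature=temperature, cv_names=tuple(names),
                    periods=tuple(periods))


# ---------------------------------------------------------------------------
# COLVAR
# ---------------------------------------------------------------------------

@dataclass
class ColvarTable:
    """Time series of named CV values (times in ps)."""

    names: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float).reshape(
            self.times.shape[0], -1)
        if self.values.shape[1] != len(self.names):
            raise ValueError("one column per CV name required")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("COLVAR times must be non-decreasing")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def __eq__(self, other):
        if not isinstance(other, ColvarTable):
            return NotImplemented
        return (self.names == other.names
                and np.array_equal(self.times, other.times)
                and np.array_equal(self.values, other.values))


def write_colvar(table: ColvarTable, path) -> None:
    path = Path(path)
    lines = ["#! FIELDS time " + " ".join(table.names)]
    for i in range(table.times.shape[0]):
        lines.append(" ".join([_fmt(table.times[i])]
                              + [_fmt(v) for v in table.values[i]]))
    path.write_text("\n".join(lines) + "\n")


def read_colvar(path) -> ColvarTable:
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise ValueError(f"{path}:1: missing '#! FIELDS' header")
    fields = lines[0].split()[2:]
    if not fields or fields[0] != "time":
        raise ValueError(f"{path}:1: first COLVAR field must be 'time'")
    names = tuple(fields[1:])
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) != 1 + len(names):
            raise ValueError(
                f"{path}:{ln}: expected {1 + len(names)} columns, "
                f"got {len(parts)}")
        rows.append([float(p) for p in parts])
    arr = np.array(rows) if rows else np.empty((0, 1 + len(names)))
    times = arr[:, 0]
    if times.size and np.any(np.diff(times) < 0):
        bad = int(np.argmax(np.diff(times) < 0)) + 1
        raise ValueError(f"{path}: decreasing time at data row {bad + 1}")
    return ColvarTable(names=names, times=times, values=arr[:, 1:],
                       provenance={"path": str(path),
                                   "header_sha1": hashlib.sha1(
                                       lines[0].encode()).hexdigest()})


# ---------------------------------------------------------------------------
# FES tables
# ---------------------------------------------------------------------------

def write_fes(fes: FreeEnergySurface, path) -> None:
    """Plain-text grid table: node coordinates + free energy per row."""
    path = Path(path)
    lines = [f"# free energy surface ({fes.units}); unsampled nodes are inf",
             f"# temperature_K {_fmt(fes.temperature)}",
             f"# estimator {fes.estimator}",
             "# shape " + " ".join(str(len(a)) for a in fes.axes),
             "#! FIELDS " + " ".join(fes.names) + " free_energy"]
    mesh = np.meshgrid(*fes.axes, indexing="ij")
    flat = [m.ravel() for m in mesh] + [fes.values.ravel()]
    for row in zip(*flat):
        lines.append(" ".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_fes(path) -> FreeEnergySurface:
    path = Path(path)
    units, temperature, estimator, shape, names = "kJ/mol", np.nan, "?", None, ()
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("# free energy surface"):
            units = s.split("(")[1].split(")")[0]
        elif s.startswith("# temperature_K"):
            temperature = float(s.split()[-1])
        elif s.startswith("# estimator"):
            estimator = s.split()[-1]
        elif s.startswith("# shape"):
            shape = tuple(int(v) for v in s.split()[2:])
        elif s.startswith("#! FIELDS"):
            names = tuple(s.split()[2:-1])
        elif s.startswith("#"):
            continue
        else:
            rows.append([float(v) for v in s.split()])
    if shape is None:
        raise ValueError(f"{path}: missing '# shape' metadata")
    arr = np.array(rows)
    axes = []
    d = len(shape)
    for k in range(d):
        coords = arr[:, k].reshape(shape)
        sl = [0] * d
        sl[k] = slice(None)
        axes.append(coords[tuple(sl)])
    return FreeEnergySurface(axes=tuple(axes),
                             values=arr[:, d].reshape(shape),
                             temperature=temperature, estimator=estimator,
                             names=names, units=units)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {"system", "sampler", "cvs", "metad", "wte", "ptmetad",
                   "fes", "thermo", "rmsf", "pca", "units"}


@dataclass
class RunConfig:
    """Validated YAML run configuration with a master seed.

    Every stochastic stage derives its own seed from the master seed and a
    fixed per-stage offset, so one integer reproduces the whole pipeline.
    """

    seed: int
    sections: dict = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2 ** 31)

    def section(self, name: str) -> dict:
        return dict(self.sections.get(name, {}))

    def to_yaml(self) -> str:
        return yaml.safe_dump({"seed": self.seed, **self.sections},
                              sort_keys=True)


def parse_config(data: dict) -> RunConfig:
    data = dict(data or {})
    seed = data.pop("seed", None)
    if seed is None:
        raise ValueError("config requires an integer 'seed'")
    unknown = set(data) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(
            f"unknown config sections: {sorted(unknown)}; "
            f"known: {sorted(_KNOWN_SECTIONS)}")
    return RunConfig(seed=int(seed), sections=data)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return parse_config(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# trajectory export (optional, needs mdtraj)
# ---------------------------------------------------------------------------

def to_mdtraj(traj):
    """Convert a Cartesian Trajectory to an mdtraj.Trajectory of CA beads."""
    import mdtraj as md
    pos = traj.positions
    if pos.ndim != 3:
        raise ValueError("only Cartesian (frames, atoms, 3) trajectories")
    top = md.Topology()
    chain = top.add_chain()
    for i in range(pos.shape[1]):
        res = top.add_residue("ALA", chain)
        top.add_atom("CA", md.element.carbon, res)
    return md.Trajectory(xyz=pos / 10.0, topology=top,
                         time=traj.times)        # mdtraj uses nm


def write_trajectory(traj, basename) -> tuple[str, str]:
    """Write PDB topology + DCD coordinates; returns the two paths."""
    t = to_mdtraj(traj)
    pdb = f"{basename}.pdb"
    dcd = f"{basename}.dcd"
    t[0].save_pdb(pdb)
    t.save_dcd(dcd)
    return pdb, dcd


def read_milestones(pdb_path) -> list[np.ndarray]:
    """Path-CV milestone structures from a multi-model PDB (Angstrom)."""
    import mdtraj as md
    t = md.load(str(pdb_path))
    return [np.asarray(f, dtype=float) * 10.0 for f in t.xyz]


def read_trajectory(topology_path, coords_path=None, dt_ps: float = 1.0):
    """Read PDB (+DCD/XTC) into a package Trajectory (Angstrom, ps)."""
    import mdtraj as md

    from .trajectory import Trajectory
    if coords_path is None:
        t = md.load(str(topology_path))
    else:
        t = md.load(str(coords_path), top=str(topology_path))
    dt = float(t.timestep) if t.n_frames > 1 and t.timestep else dt_ps
    return Trajectory(positions=np.asarray(t.xyz, dtype=float) * 10.0,
                      dt_ps=dt)
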