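"""Configuration loading, file formats, and run manifests.

Formats
-------
* TOML run configuration (flat geometry/particle keys plus optional
  ``[run]``, ``[analysis]``, ``[classify]``, ``[continuum]`` tables);
  unknown keys are hard errors so typos cannot silently fall back to
  defaults.
* Extended-XYZ text trajectories (one block per snapshot: count line,
  comment line with metadata, then ``RC x y z ux uy uz`` per rod) for
  interoperability.
* NumPy ``.npz`` containers for trajectories and gridded fields.
* JSON for defect records, classification labels, and run manifests.

Everything is written at float64; write+read round trips are lossless
for the npz containers and good to the printed precision (17
significant digits) for the text formats.
"""

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ConfigError
from .fields import Grid2D, QField
from .geometry import Confinement
from .mc import Configuration, SimParams, Trajectory

__all__ = [
    "AnalysisOptions",
    "ClassifyOptions",
    "ContinuumOptions",
    "RunSpec",
    "load_config",
    "write_xyz",
    "read_xyz",
    "save_trajectory",
    "load_trajectory",
    "save_qfield",
    "load_qfield",
    "save_field_csv",
    "save_defects_json",
    "load_defects_json",
    "write_manifest",
]

_VERSION = "0.1.0"

log = logging.getLogger(__name__)


@dataclass
class AnalysisOptions:
    cell_size: float = 1.0
    seg_len: float = 0.5
    s_floor: float = 0.05
    threshold: float = 0.5
    merge_radius: float = 2.0
    charge_radius: float = 3.0


@dataclass
class ClassifyOptions:
    w_b: float | None = None      # None -> L/2
    c_inf: float = 5.0
    rho: float = 2.0
    offset: float = -0.5
    fail_residual: float = 0.35


@dataclass
class ContinuumOptions:
    spacing: float = 0.45
    a2: float = -1.0
    a4: float = 1.0
    K: float = 2.0
    step: float | None = None
    tol: float = 1e-9
    max_iter: int = 200_000
    noise: float = 0.01
    seed: int = 0


@dataclass
class RunSpec:
    """Fully validated bundle of parameters for one pipeline run."""

    params: SimParams
    confinement: Confinement
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    classify: ClassifyOptions = field(default_factory=ClassifyOptions)
    continuum: ContinuumOptions = field(default_factory=ContinuumOptions)


_FLAT_KEYS = {"L_over_D", "eta", "R_outer", "R_inner", "H"}
_RUN_KEYS = {"n_sweeps", "sample_every", "delta_t", "delta_r", "seed", "mode"}


def _take(table, allowed, where):
    unknown = set(table) - allowed
    if unknown:
        raise ConfigError(f"unknown config key {sorted(unknown)[0]!r} in {where}")
    return dict(table)


def load_config(path) -> RunSpec:
    """Parse and validate a TOML run configuration."""
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"malformed TOML in {path}: {exc}") from exc
    sections = {k: v for k, v in raw.items() if isinstance(v, dict)}
    flat = {k: v for k, v in raw.items() if not isinstance(v, dict)}
    bad_sections = set(sections) - {"run", "analysis", "classify", "continuum"}
    if bad_sections:
        raise ConfigError(f"unknown config section {sorted(bad_sections)[0]!r}")
    flat = _take(flat, _FLAT_KEYS, "top level")
    for key in ("L_over_D", "eta", "R_outer", "H"):
        if key not in flat:
            raise ConfigError(f"missing required config key {key!r}")
    run = _take(sections.get("run", {}), _RUN_KEYS, "[run]")
    run.setdefault("n_sweeps", 20_000)
    run.setdefault("sample_every", 20)
    run.setdefault("seed", 0)
    L = float(flat["L_over_D"])
    c = Confinement(float(flat["R_outer"]), float(flat.get("R_inner", 0.0)),
                    float(flat["H"]))
    if c.H >= L:
        raise ConfigError(
            f"H = {c.H} must be smaller than the particle length L = {L}")
    params = SimParams(L_over_D=L, eta=float(flat["eta"]), **run)
    ana = AnalysisOptions(**_take(sections.get("analysis", {}),
                                  set(AnalysisOptions.__dataclass_fields__),
                                  "[analysis]"))
    cls = ClassifyOptions(**_take(sections.get("classify", {}),
                                  set(ClassifyOptions.__dataclass_fields__),
                                  "[classify]"))
    cont = ContinuumOptions(**_take(sections.get("continuum", {}),
                                    set(ContinuumOptions.__dataclass_fields__),
                                    "[continuum]"))
    spec = RunSpec(params, c, ana, cls, cont)
    log.info("effective config: %s %s", params, c)
    return spec


# ---------------------------------------------------------------- trajectories

def write_xyz(traj: Trajectory, path):
    """Extended-XYZ text dump of every stored snapshot."""
    c = traj.confinement
    with open(path, "w") as fh:
        for s in range(traj.n_snapshots):
            fh.write(f"{traj.positions.shape[1]}\n")
            fh.write(f"sweep={int(traj.sweep_indices[s])} "
                     f"L={traj.params.L_over_D:.17g} "
                     f"R_outer={c.R_outer:.17g} R_inner={c.R_inner:.17g} "
                     f"H={c.H:.17g}\n")
            for p, u in zip(traj.positions[s], traj.orientations[s]):
                fh.write("RC " + " ".join(f"{v:.17g}" for v in (*p, *u)) + "\n")


def read_xyz(path):
    """Read an extended-XYZ trajectory back as Configuration snapshots."""
    configs = []
    sweeps = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i])
        meta = dict(kv.split("=") for kv in lines[i + 1].split())
        c = Confinement(float(meta["R_outer"]), float(meta["R_inner"]),
                        float(meta["H"]))
        block = np.array([ln.split()[1:] for ln in lines[i + 2:i + 2 + n]],
                         dtype=float).reshape(n, 6)
        configs.append(Configuration(block[:, :3], block[:, 3:], c,
                                     float(meta["L"])))
        sweeps.append(int(meta["sweep"]))
        i += 2 + n
    return configs, np.asarray(sweeps)


def save_trajectory(traj: Trajectory, path):
    c = traj.confinement
    meta = {k: v for k, v in asdict(traj.params).items()}
    np.savez_compressed(
        path, positions=traj.positions, orientations=traj.orientations,
        sweep_indices=traj.sweep_indices, order_series=traj.order_series,
        acceptance_rate=traj.acceptance_rate, seed=traj.seed,
        confinement=np.array([c.R_outer, c.R_inner, c.H]),
        params_json=json.dumps(meta))


def load_trajectory(path) -> Trajectory:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["params_json"]))
        R_outer, R_inner, H = z["confinement"]
        return Trajectory(
            SimParams(**meta), Confinement(float(R_outer), float(R_inner),
                                           float(H)),
            z["sweep_indices"], z["positions"], z["orientations"],
            z["order_series"], float(z["acceptance_rate"]), int(z["seed"]))


# --------------------------------------------------------------------- fields

def save_qfield(qf: QField, path):
    g = qf.grid
    c = g.confinement
    conf = (np.array([c.R_outer, c.R_inner, c.H]) if c is not None
            else np.array([np.nan, np.nan, np.nan]))
    np.savez_compressed(path, q1=qf.q1, q2=qf.q2, weight=qf.weight,
                        cell_size=g.cell_size, n=g.n, x0=g.x0,
                        mask=g.mask, confinement=conf)


def load_qfield(path) -> QField:
    with np.load(path, allow_pickle=False) as z:
        conf = z["confinement"]
        c = (None if np.isnan(conf[0])
             else Confinement(float(conf[0]), float(conf[1]), float(conf[2])))
        grid = Grid2D(float(z["cell_size"]), int(z["n"]), float(z["x0"]),
                      z["mask"], c)
        return QField(grid, z["q1"], z["q2"], z["weight"])


def save_field_csv(grid: Grid2D, values, path, defined=None):
    """Write a cell field as x,y,value rows (defined cells only)."""
    X, Y = grid.meshgrid()
    sel = np.ones_like(values, bool) if defined is None else defined
    data = np.column_stack([X[sel], Y[sel], values[sel]])
    np.savetxt(path, data, delimiter=",", header="x,y,value", comments="")


def save_defects_json(defects, path):
    records = [{"x": float(df.position[0]), "y": float(df.position[1]),
                "charge": df.charge, "score": df.score,
                "residual": df.residual} for df in defects]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def load_defects_json(path):
    from .fields import Defect
    with open(path) as fh:
        records = json.load(fh)
    return [Defect(np.array([r["x"], r["y"]]), r["charge"], r["score"],
                   r.get("residual", 0.0)) for r in records]


# ------------------------------------------------------------------- manifest

def config_hash(path):
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def write_manifest(path, command, seed, config_path=None, outputs=(),
                   extra=None):
    manifest = {
        "version": _VERSION,
        "command": command,
        "seed": seed,
        "config_sha256": config_hash(config_path) if config_path else None,
        "outputs": sorted(str(o) for o in outputs),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
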