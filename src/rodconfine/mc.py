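"""Metropolis Monte Carlo of hard spherocylinders in disk/annulus chambers.

The sampler performs single-rod moves that combine a uniform translation
(inside a cube of side ``2 delta_t``) with a rotation of the axis by a
uniform angle up to ``delta_r`` about a random axis.  A move is accepted
iff the displaced rod creates no overlap with other rods or the walls —
the hard-particle limit of the Metropolis rule.  One sweep is N
attempted moves on uniformly chosen rods.

Two transverse modes are supported:

* ``strict-2d`` (plate spacing H equal to the rod diameter): rod centres
  are pinned to the mid-plane and orientations are strictly in-plane;
  proposals are planar.
* ``quasi-2d`` (H between D and L): full 3D moves, with the plates
  providing the strong planarization.

Initialization uses a shrink–insert–inflate protocol: rods are placed at
a reduced diameter by rejection sampling and the diameter is then grown
in small stages, with overlap-relaxation sweeps plus genuine hard-core
MC equilibration between stages (long rods only pack at full diameter
once local nematic order has developed), until the full hard core is
reached.  Step sizes are tuned toward a 30–40% acceptance rate during
this phase and then frozen, so production sampling obeys detailed
balance.  See docs/methods.md for the full protocol.
"""

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as _k
from .errors import ConfigError, InitializationError
from .geometry import Confinement, Rod, particle_count, packing_fraction

__all__ = [
    "SimParams",
    "Configuration",
    "Trajectory",
    "initialize",
    "attempt_move",
    "run",
    "global_order_parameter",
    "equilibrated",
]

log = logging.getLogger(__name__)

STRICT_2D = "strict-2d"
QUASI_2D = "quasi-2d"

_DEFAULT_DELTA_T = 0.4
_DEFAULT_DELTA_R = 0.25


@dataclass
class SimParams:
    """Run-control parameters for one MC simulation."""

    L_over_D: float
    eta: float
    n_sweeps: int
    sample_every: int = 10
    delta_t: float | None = None  # None -> auto-tuned at init
    delta_r: float | None = None
    seed: int = 0
    mode: str = "auto"

    def __post_init__(self):
        if self.L_over_D <= 0:
            raise ConfigError("L_over_D must be positive")
        if not 0.0 <= self.eta < 1.0:
            raise ConfigError("eta must lie in [0, 1)")
        if self.n_sweeps < 1:
            raise ConfigError("n_sweeps must be >= 1")
        if self.sample_every < 1:
            raise ConfigError("sample_every must be >= 1")
        if self.delta_t is not None and self.delta_t <= 0:
            raise ConfigError("delta_t must be positive")
        if self.delta_r is not None and not 0.0 < self.delta_r <= np.pi:
            raise ConfigError("delta_r must lie in (0, pi]")
        if self.mode not in ("auto", STRICT_2D, QUASI_2D):
            raise ConfigError(f"unknown mode {self.mode!r}")

    def resolve_mode(self, c: Confinement) -> str:
        if self.mode != "auto":
            if self.mode == STRICT_2D and c.H != c.D:
                raise ConfigError("strict-2d mode requires H = D")
            return self.mode
        return STRICT_2D if c.H == c.D else QUASI_2D


@dataclass
class Configuration:
    """A set of rods in a chamber; the MC state.

    Positions and orientations are stored as (N, 3) arrays (the
    performance-relevant representation); :attr:`rods` materializes
    :class:`~rodconfine.geometry.Rod` objects on demand.  ``physical``
    is False only for synthetic fixtures that skip the hard-core test.
    """

    positions: np.ndarray
    orientations: np.ndarray
    confinement: Confinement
    L: float
    params: SimParams | None = None
    physical: bool = True

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float).reshape(-1, 3)
        self.orientations = np.ascontiguousarray(self.orientations, dtype=float).reshape(-1, 3)
        if self.positions.shape != self.orientations.shape:
            raise ConfigError("positions and orientations must have matching shapes")

    @property
    def n_rods(self):
        return self.positions.shape[0]

    @property
    def rods(self):
        return [Rod(self.positions[i].copy(), self.orientations[i].copy(), self.L)
                for i in range(self.n_rods)]

    def is_valid(self):
        """Exhaustive validity audit: no overlaps, all rods inside walls."""
        if self.n_rods == 0:
            return True
        n_ov, n_wall = _k.count_violations(
            self.positions, self.orientations, 0.5 * self.L, 1.0, 1.0,
            self.confinement.R_outer, self.confinement.R_inner, self.confinement.H)
        return n_ov == 0 and n_wall == 0

    def packing_fraction(self):
        return packing_fraction(self.n_rods, self.confinement, self.L)

    def copy(self):
        return Configuration(self.positions.copy(), self.orientations.copy(),
                             self.confinement, self.L, self.params, self.physical)


@dataclass
class Trajectory:
    """Stored MC output: snapshots, per-sweep order series, bookkeeping."""

    params: SimParams
    confinement: Confinement
    sweep_indices: np.ndarray       # (S,)
    positions: np.ndarray           # (S, N, 3)
    orientations: np.ndarray        # (S, N, 3)
    order_series: np.ndarray        # (n_sweeps,) largest eigenvalue of global Q
    acceptance_rate: float
    seed: int

    @property
    def n_snapshots(self):
        return len(self.sweep_indices)

    def configurations(self):
        """Snapshots as :class:`Configuration` objects (array views)."""
        return [
            Configuration(self.positions[s], self.orientations[s],
                          self.confinement, self.params.L_over_D,
                          params=self.params)
            for s in range(self.n_snapshots)
        ]


def _child_seeds(seed, n):
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def global_order_parameter(config: Configuration):
    """Global nematic tensor Q = <(3 u u^T - I)/2> and its largest eigenvalue."""
    if config.n_rods == 0:
        raise ConfigError("global order parameter undefined for an empty configuration")
    u = config.orientations
    M = (u[:, :, None] * u[:, None, :]).mean(axis=0)
    Q = 1.5 * M - 0.5 * np.eye(3)
    lam = float(np.linalg.eigvalsh(Q)[-1])
    return Q, lam


def equilibrated(order_series, window, tol=0.02):
    """Window-mean plateau test on the order-parameter series.

    True iff the means of the last two non-overlapping windows agree to
    relative tolerance ``tol``.
    """
    series = np.asarray(order_series, dtype=float)
    if window < 1:
        raise ConfigError("window must be >= 1")
    if len(series) < 2 * window:
        raise ConfigError("series shorter than two windows")
    m_prev = series[-2 * window:-window].mean()
    m_last = series[-window:].mean()
    if m_last == 0.0:
        return m_prev == 0.0
    return abs(m_last - m_prev) / abs(m_last) < tol


def _as_rng(rng):
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def attempt_move(config: Configuration, i: int, rng) -> bool:
    """Propose and apply one Metropolis move on rod ``i``.

    Returns True and mutates ``config`` in place if accepted; the
    configuration is valid after the call either way.
    """
    if not 0 <= i < config.n_rods:
        raise ConfigError(f"rod index {i} out of range")
    rng = _as_rng(rng)
    p = config.params
    delta_t = (p.delta_t if p and p.delta_t else _DEFAULT_DELTA_T)
    delta_r = (p.delta_r if p and p.delta_r else _DEFAULT_DELTA_R)
    c = config.confinement
    two_d = (p.resolve_mode(c) if p else
             (STRICT_2D if c.H == c.D else QUASI_2D)) == STRICT_2D
    pos = config.positions
    u = config.orientations
    t = pos[i] + rng.uniform(-delta_t, delta_t, size=3)
    if two_d:
        t[2] = pos[i, 2]
        ang = rng.uniform(-delta_r, delta_r)
        ca, sa = np.cos(ang), np.sin(ang)
        tu = np.array([ca * u[i, 0] - sa * u[i, 1],
                       sa * u[i, 0] + ca * u[i, 1], 0.0])
    else:
        k = rng.normal(size=3)
        k /= np.linalg.norm(k)
        psi = rng.uniform(0.0, delta_r)
        ui = u[i]
        tu = (ui * np.cos(psi) + np.cross(k, ui) * np.sin(psi)
              + k * (k @ ui) * (1.0 - np.cos(psi)))
        tu /= np.linalg.norm(tu)
    halfL = 0.5 * config.L
    if not _k.rod_fits(t[0], t[1], t[2], tu[0], tu[1], tu[2],
                       halfL, 1.0, c.R_outer, c.R_inner, c.H):
        return False
    if _k.overlaps_any_brute(pos, u, halfL, 1.0, i,
                             t[0], t[1], t[2], tu[0], tu[1], tu[2]):
        return False
    pos[i] = t
    u[i] = tu
    return True


def _cell_grid(c: Confinement, L):
    """Cell-list geometry: square cells with edge >= L + D so a 3x3
    neighbourhood is guaranteed to contain every possible overlap partner."""
    nc = max(1, int(2.0 * c.R_outer / (L + 1.0)))
    edge = 2.0 * c.R_outer / nc
    return edge, nc


def _tune_steps(pos, u, halfL, c, two_d, seeds, target=(0.30, 0.40),
                delta_t0=_DEFAULT_DELTA_T, delta_r0=_DEFAULT_DELTA_R):
    """Multiplicative step-size tuning toward the target acceptance band."""
    delta_t, delta_r = delta_t0, delta_r0
    edge, nc = _cell_grid(c, 2 * halfL)
    N = pos.shape[0]
    qser = np.empty((5, 6))
    empty3 = np.empty((0, N, 3))
    empty_sw = np.empty(0, dtype=np.int64)
    for seed in seeds:
        acc, _ = _k.run_sweeps(pos, u, halfL, 1.0, 1.0, c.R_outer, c.R_inner,
                               c.H, two_d, 5, delta_t, delta_r, seed,
                               0, empty3, empty3, empty_sw, qser, edge, nc)
        rate = acc / (5 * N)
        if rate < target[0]:
            delta_t = max(delta_t * 0.7, 1e-3)
            delta_r = max(delta_r * 0.7, 1e-3)
        elif rate > target[1]:
            delta_t = min(delta_t * 1.3, 2 * halfL)
            delta_r = min(delta_r * 1.3, np.pi)
        else:
            break
    return delta_t, delta_r


def initialize(params: SimParams, c: Confinement, rng=None, *,
               start_diameter=0.3, growth=1.02,
               relax_chunk=5, max_stage_chunks=150,
               hop_cycles=50) -> Configuration:
    """Build a valid configuration at the target packing fraction.

    Shrink–insert–inflate: N rods are placed at diameter
    ``start_diameter`` by rejection sampling; the diameter then grows by
    factor ``growth`` per stage (increments capped near full size).
    Each stage runs greedy overlap-depth descent, escalating to rescue
    rounds (violator re-insertion with locally aligned orientations,
    violator-only thermal kicks, greedy re-descent) up to ``hop_cycles``
    rounds; between stages, real hard-core MC sweeps at the current
    diameter let nematic order develop.  Raises
    :class:`InitializationError` (reporting the packing fraction
    achieved at the last feasible diameter) when the rescue rounds stop
    making headway — the jamming signature.  See docs/methods.md.
    """
    rng = _as_rng(rng if rng is not None else params.seed)
    L = params.L_over_D
    if c.H >= L:
        raise ConfigError("plate spacing H must be smaller than the rod length L")
    two_d = params.resolve_mode(c) == STRICT_2D
    N = particle_count(params.eta, c, L)
    if N == 0:
        cfg = Configuration(np.zeros((0, 3)), np.zeros((0, 3)), c, L, params)
        return cfg
    halfL = 0.5 * L
    seeds = [int(rng.integers(1, 2**31)) for _ in range(max_stage_chunks * 64)]
    seed_iter = iter(seeds)

    dia = float(start_diameter)
    pos, u, placed = _k.insert_random(N, halfL, dia, 1.0, c.R_outer,
                                      c.R_inner, c.H, two_d, next(seed_iter),
                                      max_tries=400 * N + 20000)
    if placed < N:
        ach = packing_fraction(placed, c, L) * dia**2
        raise InitializationError(
            f"could only insert {placed}/{N} rods at diameter {dia:.2f}",
            achieved_eta=ach)
    def _relax(dia_target, n_sweeps, temperature):
        return _k.relax_toward(pos, u, halfL, dia_target + 1e-6, 1.0,
                               c.R_outer, c.R_inner, c.H, two_d, n_sweeps,
                               0.25, 0.25, next(seed_iter), temperature)

    edge, nc = _cell_grid(c, L)
    _empty3 = np.empty((0, N, 3))
    _empty_sw = np.empty(0, dtype=np.int64)

    def _equil(dia_now, n_sweeps):
        # proper hard-core MC at the current (valid) diameter; this is
        # where nematic order develops during inflation
        qser = np.empty((n_sweeps, 6))
        _k.run_sweeps(pos, u, halfL, dia_now, 1.0, c.R_outer, c.R_inner,
                      c.H, two_d, n_sweeps, 0.35, 0.3, next(seed_iter),
                      0, _empty3, _empty3, _empty_sw, qser, edge, nc)

    while dia < 1.0:
        # multiplicative growth early, capped at +0.01 D near full size
        # and +0.005 D for the last few percent: late-stage overlaps
        # must stay shallow or long rods wedge
        cap = 0.005 if dia > 0.95 else 0.01
        target = min(1.0, dia * growth, dia + cap)
        # phase 1: greedy descent of the total violation depth (the
        # tiny diameter margin keeps "penalty zero" strictly clear of
        # the hard-core boundary)
        best = np.inf
        since_improve = 0
        viol = 1
        for _chunk in range(max_stage_chunks):
            viol = _relax(target, relax_chunk, 0.0)
            if viol == 0:
                break
            if viol < best:
                best = viol
                since_improve = 0
            else:
                since_improve += 1
                if since_improve >= 6:
                    break
        # phase 2: the descent can converge to a positive local minimum
        # (a few mutually wedged rods).  Each rescue round combines the
        # three escapes that work in practice: re-insert violators
        # elsewhere by rejection sampling, one violator-only thermal
        # kick (escalating temperature), then greedy re-descent.  No
        # headway over many rounds is the jamming signature.
        if viol != 0:
            best_round = np.inf
            round_stall = 0
            for _round in range(hop_cycles):
                flags = _k.violator_flags(pos, u, halfL, target + 1e-6, 1.0,
                                          c.R_outer, c.R_inner, c.H)
                idx = np.flatnonzero(flags)
                if len(idx) == 0:
                    viol = 0
                    break
                for i in idx:
                    for _try in range(4000):
                        x = rng.uniform(-c.R_outer, c.R_outer)
                        y = rng.uniform(-c.R_outer, c.R_outer)
                        if x * x + y * y > c.R_outer**2:
                            continue
                        # align with the nearest rod's in-plane axis:
                        # a random orientation has near-zero insertion
                        # probability inside an ordered nematic
                        d2 = ((pos[:, 0] - x)**2 + (pos[:, 1] - y)**2)
                        d2[i] = np.inf
                        j = int(np.argmin(d2))
                        phi = np.arctan2(u[j, 1], u[j, 0]) \
                            + rng.normal(0.0, 0.3)
                        if two_d:
                            z = 0.5 * c.H
                            uv = np.array([np.cos(phi), np.sin(phi), 0.0])
                        else:
                            z = rng.uniform(0.5, c.H - 0.5)
                            tz = rng.normal(0.0, 0.08)
                            cz = np.sqrt(max(0.0, 1.0 - tz * tz))
                            uv = np.array([cz * np.cos(phi),
                                           cz * np.sin(phi), tz])
                        if not _k.rod_fits(x, y, z, uv[0], uv[1], uv[2],
                                           halfL, 1.0, c.R_outer, c.R_inner,
                                           c.H):
                            continue
                        if _k.overlaps_any_brute(pos, u, halfL,
                                                 target + 1e-6, i,
                                                 x, y, z, uv[0], uv[1], uv[2]):
                            continue
                        pos[i] = (x, y, z)
                        u[i] = uv
                        break
                _relax(target, relax_chunk, 0.01 * (1 + _round % 6))
                for _g in range(3):
                    viol = _relax(target, relax_chunk, 0.0)
                    if viol == 0:
                        break
                if viol == 0:
                    break
                if viol < best_round:
                    best_round = viol
                    round_stall = 0
                else:
                    round_stall += 1
                    if round_stall >= 15:
                        break  # jammed: no headway over many rescue rounds
        if viol != 0:
            vol = np.pi * dia**2 * L / 4.0 + np.pi * dia**3 / 6.0
            ach = N * vol / c.volume
            raise InitializationError(
                f"inflation stalled at diameter {dia:.3f} "
                f"(target {target:.3f}, {viol} residual violations); "
                f"achieved eta = {ach:.3f} of requested {params.eta:.3f}",
                achieved_eta=ach)
        dia = target
        # between-stage MC relaxation at the achieved diameter: long rods
        # only pack at full size once local nematic order has developed,
        # so spend real sweeps in the ordering window
        _equil(dia, 150 if dia >= 0.5 else 20)
    # tune and freeze step sizes
    delta_t, delta_r = params.delta_t, params.delta_r
    if delta_t is None or delta_r is None:
        dt_tuned, dr_tuned = _tune_steps(pos, u, halfL, c, two_d,
                                         [next(seed_iter) for _ in range(12)])
        delta_t = delta_t if delta_t is not None else dt_tuned
        delta_r = delta_r if delta_r is not None else dr_tuned
        log.info("tuned step sizes: delta_t=%.3f delta_r=%.3f", delta_t, delta_r)
    frozen = replace(params, delta_t=float(delta_t), delta_r=float(delta_r))
    cfg = Configuration(pos, u, c, L, frozen)
    log.info("initialized %d rods at eta=%.4f (target %.4f)",
             N, cfg.packing_fraction(), params.eta)
    return cfg


def run(params: SimParams, c: Confinement, config: Configuration | None = None) -> Trajectory:
    """Run a full MC simulation and return its trajectory.

    The whole run — initialization, step tuning and production — is a
    deterministic function of ``params.seed``.  An existing valid
    ``config`` may be passed to continue sampling from it.
    """
    seeds = _child_seeds(params.seed, 4)
    if config is None:
        config = initialize(params, c, np.random.default_rng(seeds[0]))
    params_eff = config.params if config.params is not None else params
    N = config.n_rods
    n_sweeps = params.n_sweeps
    n_snap = n_sweeps // params.sample_every
    snap_pos = np.empty((n_snap, N, 3))
    snap_u = np.empty((n_snap, N, 3))
    snap_sweep = np.zeros(n_snap, dtype=np.int64)
    qser = np.zeros((n_sweeps, 6))
    if N == 0:
        return Trajectory(params_eff, c, snap_sweep[:0], snap_pos[:0],
                          snap_u[:0], np.zeros(n_sweeps), 0.0, params.seed)
    two_d = params_eff.resolve_mode(c) == STRICT_2D
    edge, nc = _cell_grid(c, config.L)
    delta_t = params_eff.delta_t or _DEFAULT_DELTA_T
    delta_r = params_eff.delta_r or _DEFAULT_DELTA_R
    acc, nsnap = _k.run_sweeps(
        config.positions, config.orientations, 0.5 * config.L, 1.0, 1.0,
        c.R_outer, c.R_inner, c.H, two_d, n_sweeps, delta_t, delta_r,
        seeds[1], params.sample_every, snap_pos, snap_u, snap_sweep,
        qser, edge, nc)
    # per-sweep global Q from the accumulated second moments
    M = np.empty((n_sweeps, 3, 3))
    M[:, 0, 0] = qser[:, 0]
    M[:, 1, 1] = qser[:, 1]
    M[:, 2, 2] = qser[:, 2]
    M[:, 0, 1] = M[:, 1, 0] = qser[:, 3]
    M[:, 0, 2] = M[:, 2, 0] = qser[:, 4]
    M[:, 1, 2] = M[:, 2, 1] = qser[:, 5]
    Q = 1.5 * M / N - 0.5 * np.eye(3)
    order_series = np.linalg.eigvalsh(Q)[:, -1]
    rate = acc / (n_sweeps * N)
    log.info("run finished: %d sweeps, acceptance %.1f%%, final lambda_max %.3f",
             n_sweeps, 100 * rate, order_series[-1])
    return Trajectory(params_eff, c, snap_sweep[:nsnap], snap_pos[:nsnap],
                      snap_u[:nsnap], order_series, rate, params.seed)
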