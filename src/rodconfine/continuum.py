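"""Single-elastic-constant 2D Q-tensor relaxation on disk and annulus.

The continuum baseline against which the finite-particle simulations
are contrasted.  The state is the 2D symmetric traceless tensor

    Q = [[q1, q2], [q2, -q1]],   S = sqrt(q1^2 + q2^2),

normalized so S equals the largest eigenvalue of Q (matching the
particle-based field analysis).  The free energy per unit area is

    f = a2 S^2 + a4 S^4 + (K/2) (|grad q1|^2 + |grad q2|^2),

with a2 < 0 < a4 (bulk minimum at S_eq = sqrt(-a2 / (2 a4))) and a
single elastic constant K.  Anchoring is strong (Dirichlet): cells in a
band just outside the domain are pinned to the tangential director at
S_eq.  Relaxation is explicit gradient descent from a small seeded
noise state; the step size is backtracked whenever a step would raise
the energy, so the recorded energy trace is non-increasing.

Topology is the point: on a disk (Euler characteristic 1) the converged
solution must carry total boundary charge +1, realized as two
diametrically opposite +1/2 defects near the perimeter; on an annulus
(Euler characteristic 0) the defect-free tangential state wins.
"""

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ConvergenceError
from .fields import Grid2D, QField
from .geometry import Confinement

__all__ = ["ContinuumParams", "ContinuumResult", "relax_q2d"]

log = logging.getLogger(__name__)


@dataclass
class ContinuumParams:
    """Parameters of the Landau-type relaxation.

    With the defaults (a2 = -1, a4 = 1, K = 2, lengths in rod diameters
    D) the bulk order is S_eq = 1/sqrt(2) and the defect core size
    sqrt(K/|a2|) is a couple of D — small against a chamber of tens of
    D, large against the default grid spacing.
    """

    spacing: float = 0.45          # grid spacing, units of D
    a2: float = -1.0
    a4: float = 1.0
    K: float = 2.0
    step: float | None = None      # None -> 0.2 * spacing^2 / K
    tol: float = 1e-9              # stop when |dF| per step < tol * |F|
    max_iter: int = 200_000
    noise: float = 0.01            # initial noise amplitude, units of S_eq
    seed: int = 0
    check_every: int = 50

    def __post_init__(self):
        if self.a4 <= 0:
            raise ConfigError("a4 must be positive")
        if self.a2 >= 0:
            raise ConfigError("a2 must be negative for an ordered bulk")
        if self.K <= 0:
            raise ConfigError("elastic constant K must be positive")
        if self.tol <= 0:
            raise ConfigError("tol must be positive")

    @property
    def s_eq(self):
        return float(np.sqrt(-self.a2 / (2.0 * self.a4)))


@dataclass
class ContinuumResult:
    field: QField
    energy_trace: np.ndarray
    iterations: int
    params: ContinuumParams


def _masks(c: Confinement, h, pad_cells=3):
    half = c.R_outer + pad_cells * h
    n = int(np.ceil(2 * half / h))
    x0 = -0.5 * n * h
    xc = x0 + (np.arange(n) + 0.5) * h
    X, Y = np.meshgrid(xc, xc, indexing="ij")
    r = np.hypot(X, Y)
    inside = r <= c.R_outer
    if c.R_inner > 0:
        inside &= r >= c.R_inner
    grid = Grid2D(h, n, x0, inside, c)
    return grid, X, Y, inside


def _tangential_q(X, Y, s_eq):
    # director along the azimuthal direction: theta = phi + pi/2
    phi = np.arctan2(Y, X)
    th2 = 2.0 * (phi + 0.5 * np.pi)
    return s_eq * np.cos(th2), s_eq * np.sin(th2)


def _laplacian(f, h):
    lap = np.zeros_like(f)
    lap[1:-1, 1:-1] = (f[2:, 1:-1] + f[:-2, 1:-1] + f[1:-1, 2:]
                       + f[1:-1, :-2] - 4.0 * f[1:-1, 1:-1]) / (h * h)
    return lap


def _energy(q1, q2, active, p, h):
    s2 = q1**2 + q2**2
    bulk = (p.a2 * s2 + p.a4 * s2**2)[active].sum() * h * h
    # forward-difference gradient energy over edges touching active cells
    gx1 = (q1[1:, :] - q1[:-1, :]) / h
    gy1 = (q1[:, 1:] - q1[:, :-1]) / h
    gx2 = (q2[1:, :] - q2[:-1, :]) / h
    gy2 = (q2[:, 1:] - q2[:, :-1]) / h
    ex = active[1:, :] | active[:-1, :]
    ey = active[:, 1:] | active[:, :-1]
    elast = 0.5 * p.K * ((gx1**2 + gx2**2)[ex].sum()
                         + (gy1**2 + gy2**2)[ey].sum()) * h * h
    return bulk + elast


def relax_q2d(c: Confinement, p: ContinuumParams = None,
              uniform_boundary=None):
    """Relax the 2D Q-tensor in a disk/annulus with strong anchoring.

    Returns a :class:`ContinuumResult` whose ``field`` is a
    :class:`~rodconfine.fields.QField` on the relaxation grid, directly
    consumable by the particle-field analysis (one code path for
    continuum and Monte Carlo defect detection).

    ``uniform_boundary`` (an angle, radians) replaces the tangential
    Dirichlet data with a uniform director — the textbook check that a
    compatible boundary relaxes to a uniform bulk at S_eq.
    """
    p = p or ContinuumParams()
    h = p.spacing
    grid, X, Y, inside = _masks(c, h)
    s_eq = p.s_eq
    if uniform_boundary is None:
        b1, b2 = _tangential_q(X, Y, s_eq)
    else:
        b1 = np.full_like(X, s_eq * np.cos(2 * uniform_boundary))
        b2 = np.full_like(X, s_eq * np.sin(2 * uniform_boundary))
    q1 = b1.copy()
    q2 = b2.copy()
    rng = np.random.default_rng(p.seed)
    q1[inside] = p.noise * s_eq * rng.standard_normal(inside.sum())
    q2[inside] = p.noise * s_eq * rng.standard_normal(inside.sum())
    dt = p.step if p.step is not None else 0.2 * h * h / p.K
    energies = [_energy(q1, q2, inside, p, h)]
    it = 0
    prev_q1, prev_q2 = q1.copy(), q2.copy()
    while it < p.max_iter:
        for _ in range(p.check_every):
            s2 = q1**2 + q2**2
            coef = 2.0 * p.a2 + 4.0 * p.a4 * s2
            g1 = coef * q1 - p.K * _laplacian(q1, h)
            g2 = coef * q2 - p.K * _laplacian(q2, h)
            q1[inside] -= dt * g1[inside]
            q2[inside] -= dt * g2[inside]
            it += 1
        e = _energy(q1, q2, inside, p, h)
        if e > energies[-1] + 1e-12:
            # step too aggressive: rewind and shrink
            q1, q2 = prev_q1.copy(), prev_q2.copy()
            dt *= 0.5
            if dt < 1e-12:
                raise ConvergenceError("step size underflow",
                                       energy_trace=np.asarray(energies))
            continue
        de = energies[-1] - e
        energies.append(e)
        prev_q1, prev_q2 = q1.copy(), q2.copy()
        if de / p.check_every < p.tol * max(abs(e), 1.0):
            break
    else:
        raise ConvergenceError(
            f"no convergence within {p.max_iter} iterations",
            energy_trace=np.asarray(energies))
    log.info("continuum relaxation: %d iterations, F = %.6g", it, energies[-1])
    weight = inside.astype(float)
    return ContinuumResult(QField(grid, q1 * weight, q2 * weight, weight),
                           np.asarray(energies), it, p)
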