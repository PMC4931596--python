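"""Analytic director fields with planted defects, and rod fixtures.

The standard multi-defect nematic ansatz: for defects of half-integer
charge q_i at points r_i,

    theta(r) = background + sum_i q_i * atan2(y - y_i, x - x_i)   (mod pi)

has, by construction, director winding exactly q_i around each planted
defect.  These fields exercise every analysis and classification
operation without running any Monte Carlo.

Rod configurations drawn from a field (:func:`rods_from_field`) are
fixtures only: rods may overlap (``physical=False``), since the field
analysis depends on orientations, not on hard-core validity.
"""

import logging

import numpy as np

from .errors import AnalysisError, ConfigError
from .fields import DirectorField, Grid2D
from .geometry import Confinement
from .mc import Configuration

__all__ = ["make_defect_field", "make_dn_field", "rods_from_field"]

log = logging.getLogger(__name__)


def _check_half_integer(q):
    if abs(2 * q - round(2 * q)) > 1e-9 or q == 0:
        raise ConfigError(f"defect charge {q} is not a nonzero half-integer")
    return round(2 * q) / 2


def defect_field_angle(x, y, defects, background=0.0):
    """Evaluate the multi-defect ansatz at points (x, y)."""
    theta = np.full(np.broadcast(x, y).shape, float(background))
    for (dx, dy), q in defects:
        theta = theta + q * np.arctan2(np.asarray(y) - dy, np.asarray(x) - dx)
    return np.mod(theta, np.pi)


def make_defect_field(defects, background=0.0, grid: Grid2D = None) -> DirectorField:
    """Director field with planted half-integer defects on ``grid``.

    ``defects`` is a sequence of ((x, y), charge) pairs.  A defect that
    lands exactly on a sampling point is jittered by half a cell (and
    logged) so the angle stays defined everywhere on the grid.
    """
    if grid is None:
        raise ConfigError("a Grid2D is required")
    items = []
    h = grid.cell_size
    X, Y = grid.meshgrid()
    for (dx, dy), q in defects:
        q = _check_half_integer(q)
        near = np.min(np.hypot(X - dx, Y - dy))
        if near < 1e-9:
            log.info("defect at (%g, %g) sits on a grid node; jittered by h/2",
                     dx, dy)
            dx += 0.5 * h
            dy += 0.5 * h
        items.append(((dx, dy), q))
    theta = defect_field_angle(X, Y, items, background)
    defined = grid.mask.copy() if grid.mask is not None else np.ones_like(theta, bool)
    return DirectorField(grid, theta, defined)


def make_dn_field(n, c: Confinement, grid: Grid2D, rim_offset=None) -> DirectorField:
    """n-fold symmetric annulus field: n domains separated by defect pairs.

    Plants n equally spaced +1/2 defects just inside the outer rim and
    n virtual -1/2 defects just inside the inner hole (outside the
    annulus), on top of a +1 virtual defect at the chamber axis that
    supplies the tangential background.  The result is invariant under
    rotation by 2 pi / n (directors co-rotating), carries winding +1 on
    a ring hugging the outer wall, and ``symmetry_number`` recovers n.
    """
    if n < 3:
        raise ConfigError("n-fold annulus fields need n >= 3")
    if c.is_disk:
        raise ConfigError("make_dn_field requires an annulus")
    h = grid.cell_size
    if rim_offset is None:
        rim_offset = 2.0 * h
    r_out = c.R_outer - rim_offset
    r_in = c.R_inner - rim_offset
    if r_in <= 0:
        raise ConfigError("inner hole too small for the requested rim offset")
    if 2 * np.pi * r_in / n < 3 * h:
        raise ConfigError(f"n = {n} exceeds the grid's angular resolution "
                          "at the inner rim")
    defects = [((0.0, 0.0), 1.0)]
    for k in range(n):
        a_out = 2 * np.pi * (k + 0.5) / n
        a_in = 2 * np.pi * k / n
        defects.append(((r_out * np.cos(a_out), r_out * np.sin(a_out)), 0.5))
        defects.append(((r_in * np.cos(a_in), r_in * np.sin(a_in)), -0.5))
    return make_defect_field(defects, background=0.5 * np.pi, grid=grid)


def rods_from_field(d: DirectorField, N, sigma, c: Confinement, rng,
                    H_fraction=0.5) -> Configuration:
    """Sample N rods whose orientations follow the director field.

    Positions are uniform over the accessible footprint; orientations
    are the field value at the rod centre plus wrapped-normal noise of
    width ``sigma``.  Overlaps are allowed — this is an analysis
    fixture, not a physical configuration (``physical=False``).
    """
    if N < 0 or sigma < 0:
        raise ConfigError("N and sigma must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pos = np.empty((N, 3))
    theta = np.empty(N)
    filled = 0
    while filled < N:
        m = max(64, 2 * (N - filled))
        x = rng.uniform(-c.R_outer, c.R_outer, m)
        y = rng.uniform(-c.R_outer, c.R_outer, m)
        r = np.hypot(x, y)
        keep = r <= c.R_outer
        if c.R_inner > 0:
            keep &= r >= c.R_inner
        x, y = x[keep], y[keep]
        ix, iy = d.grid.cell_of(x, y)
        good = d.defined[ix, iy]
        x, y, ix, iy = x[good], y[good], ix[good], iy[good]
        take = min(len(x), N - filled)
        sl = slice(filled, filled + take)
        pos[sl, 0] = x[:take]
        pos[sl, 1] = y[:take]
        pos[sl, 2] = H_fraction * c.H
        theta[sl] = d.theta[ix[:take], iy[:take]]
        filled += take
    if sigma > 0:
        theta = theta + rng.normal(0.0, sigma, N)
    u = np.zeros((N, 3))
    u[:, 0] = np.cos(theta)
    u[:, 1] = np.sin(theta)
    # L only sets the segment span during coarse-graining; keep it shorter
    # than chamber features so orientations sample the field locally
    L = min(4.0, 0.5 * (c.R_outer - c.R_inner))
    return Configuration(pos, u, c, L, params=None, physical=False)
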