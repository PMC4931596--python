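"""Sub-particle-resolution order-parameter fields and defect detection.

The analysis follows the coarse-graining used for strongly confined rod
nematics: every rod axis is chopped into short segments and each segment
deposits its (in-plane) orientation into the grid cell containing its
midpoint, as the 2D nematic tensor ``2 u u^T - I``.  Averaging over
segments and snapshots yields a per-cell symmetric traceless tensor
whose largest eigenvalue is the local scalar order parameter
``S in [0, 1]`` and whose principal axis is the director ``theta``
(defined mod pi).

Singularities are localized by the angular deficit: the nematic winding
of the director around each 2x2 plaquette of cells, normalized so an
ideal half-integer defect inside the plaquette scores 1 and a smooth
field scores 0.  Detected defects are charged by the winding of the
director along a small circle around the deficit peak.

All angle arithmetic uses the angle-doubled representation (2 theta),
the natural encoding of the head-tail symmetry of a nematic.
"""

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import AnalysisError, ConfigError
from .geometry import Confinement, spherocylinder_volume

__all__ = [
    "Grid2D",
    "QField",
    "SField",
    "DirectorField",
    "DeficitField",
    "PackingField",
    "Defect",
    "local_q_field",
    "scalar_and_director",
    "angular_deficit",
    "detect_defects",
    "ring_winding",
    "total_charge",
    "local_packing_fraction",
    "subsample_error",
]

DEFAULT_SEG_LEN = 0.5
DEFAULT_S_FLOOR = 0.05


def wrap_nematic(d):
    """Map angle differences to the nematic branch (-pi/2, pi/2]."""
    w = np.mod(np.asarray(d, dtype=float) + 0.5 * np.pi, np.pi) - 0.5 * np.pi
    return np.where(w == -0.5 * np.pi, 0.5 * np.pi, w)


@dataclass(frozen=True)
class Grid2D:
    """Regular square grid of in-plane cells covering the chamber.

    Cells are indexed ``[ix, iy]``; cell (ix, iy) is centred at
    ``(x0 + (ix + 1/2) h, x0 + (iy + 1/2) h)`` with ``h = cell_size``.
    """

    cell_size: float
    n: int
    x0: float
    mask: np.ndarray = field(repr=False)
    confinement: Confinement | None = field(default=None, repr=False)

    @classmethod
    def for_confinement(cls, c: Confinement, cell_size=1.0, pad=2):
        if cell_size > c.D + 1e-12:
            raise ConfigError("cell_size must not exceed the rod diameter "
                              "(sub-particle resolution)")
        half = c.R_outer + pad * cell_size
        n = int(np.ceil(2 * half / cell_size))
        x0 = -0.5 * n * cell_size
        xc = x0 + (np.arange(n) + 0.5) * cell_size
        X, Y = np.meshgrid(xc, xc, indexing="ij")
        r = np.hypot(X, Y)
        mask = r <= c.R_outer
        if c.R_inner > 0:
            mask &= r >= c.R_inner
        return cls(cell_size, n, x0, mask, c)

    @property
    def centers(self):
        return self.x0 + (np.arange(self.n) + 0.5) * self.cell_size

    def meshgrid(self):
        xc = self.centers
        return np.meshgrid(xc, xc, indexing="ij")

    def cell_of(self, x, y):
        ix = np.clip(((np.asarray(x) - self.x0) / self.cell_size).astype(int),
                     0, self.n - 1)
        iy = np.clip(((np.asarray(y) - self.x0) / self.cell_size).astype(int),
                     0, self.n - 1)
        return ix, iy

    def vertex_positions(self):
        """Interior grid vertices (corners shared by 2x2 cell blocks)."""
        xv = self.x0 + (np.arange(1, self.n)) * self.cell_size
        return np.meshgrid(xv, xv, indexing="ij")


@dataclass
class QField:
    """Per-cell 2D symmetric traceless tensor [[q1, q2], [q2, -q1]]."""

    grid: Grid2D
    q1: np.ndarray
    q2: np.ndarray
    weight: np.ndarray

    @property
    def defined(self):
        return self.weight > 0


@dataclass
class SField:
    grid: Grid2D
    S: np.ndarray
    defined: np.ndarray


@dataclass
class DirectorField:
    """Director angle theta in [0, pi) where the local order is resolved."""

    grid: Grid2D
    theta: np.ndarray
    defined: np.ndarray


@dataclass
class DeficitField:
    """Normalized angular deficit on interior grid vertices, in [0, 1]."""

    grid: Grid2D
    deficit: np.ndarray       # (n-1, n-1)
    winding: np.ndarray       # signed winding / pi, same shape
    defined: np.ndarray


@dataclass
class PackingField:
    grid: Grid2D
    phi: np.ndarray
    defined: np.ndarray


@dataclass
class Defect:
    """A localized orientational singularity."""

    position: np.ndarray      # in-plane (x, y)
    charge: float | None      # half-integer; None if the loop left the field
    score: float              # peak deficit value
    residual: float = 0.0     # |raw winding - rounded charge|


def _iter_snapshots(snapshots):
    """Accept a Trajectory or any sequence of Configuration-likes."""
    if hasattr(snapshots, "configurations"):
        snapshots = snapshots.configurations()
    out = [(np.asarray(s.positions, dtype=float),
            np.asarray(s.orientations, dtype=float), float(s.L))
           for s in snapshots]
    if not out:
        raise ConfigError("empty snapshot sequence")
    return out


def _segment_deposit(snaps, grid, seg_len):
    """Accumulate per-cell (cos 2phi, sin 2phi, count, volume) over segments."""
    n = grid.n
    c2 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    w = np.zeros((n, n))
    vol = np.zeros((n, n))
    oop = 0.0
    nseg_tot = 0
    for pos, u, L in snaps:
        if pos.shape[0] == 0:
            continue
        n_seg = max(1, int(round(L / seg_len)))
        offs = ((np.arange(n_seg) + 0.5) / n_seg - 0.5) * L
        mid_x = pos[:, 0, None] + offs[None, :] * u[:, 0, None]
        mid_y = pos[:, 1, None] + offs[None, :] * u[:, 1, None]
        norm_xy = np.hypot(u[:, 0], u[:, 1])
        oop += np.abs(u[:, 2]).sum()
        ok = norm_xy > 1e-9
        phi = np.arctan2(u[:, 1], u[:, 0])
        c2r = np.cos(2 * phi)
        s2r = np.sin(2 * phi)
        ix, iy = grid.cell_of(mid_x, mid_y)
        seg_vol = spherocylinder_volume(L) / n_seg
        np.add.at(c2, (ix, iy), np.broadcast_to(c2r[:, None] * ok[:, None],
                                                ix.shape))
        np.add.at(s2, (ix, iy), np.broadcast_to(s2r[:, None] * ok[:, None],
                                                ix.shape))
        np.add.at(w, (ix, iy), np.broadcast_to(ok[:, None], ix.shape).astype(float))
        np.add.at(vol, (ix, iy), np.full(ix.shape, seg_vol))
        nseg_tot += pos.shape[0]
    return c2, s2, w, vol, (oop / max(nseg_tot, 1))


def local_q_field(snapshots, grid: Grid2D, seg_len=DEFAULT_SEG_LEN) -> QField:
    """Ensemble-averaged sub-particle 2D Q-tensor field.

    In quasi-2D data the 3D orientations are projected in-plane before
    tensor accumulation (out-of-plane components are a small diagnostic
    quantity in the plate-confined regime).
    """
    snaps = _iter_snapshots(snapshots)
    c2, s2, w, _, _ = _segment_deposit(snaps, grid, seg_len)
    with np.errstate(invalid="ignore", divide="ignore"):
        q1 = np.where(w > 0, c2 / np.maximum(w, 1), 0.0)
        q2 = np.where(w > 0, s2 / np.maximum(w, 1), 0.0)
    return QField(grid, q1, q2, w)


def scalar_and_director(q: QField, s_floor=DEFAULT_S_FLOOR):
    """Largest eigenvalue (scalar order S) and principal axis of the 2D Q.

    The director is flagged undefined where the cell was never sampled
    or where ``S <= s_floor`` (near-isotropic noise has no meaningful
    axis).
    """
    S = np.hypot(q.q1, q.q2)
    theta = np.mod(0.5 * np.arctan2(q.q2, q.q1), np.pi)
    s_defined = q.defined
    d_defined = s_defined & (S > s_floor)
    return SField(q.grid, S, s_defined), DirectorField(q.grid, theta, d_defined)


def angular_deficit(d: DirectorField) -> DeficitField:
    """Nematic winding of the director around each 2x2 cell plaquette.

    Successive angle differences along the 4-cell loop are wrapped to
    the nematic branch (-pi/2, pi/2]; their sum is an exact multiple of
    pi.  The deficit is |sum|/pi: 1 at an ideal half-integer defect
    core, 0 on smooth plaquettes.
    """
    t = d.theta
    m = d.defined
    t00, t10 = t[:-1, :-1], t[1:, :-1]
    t11, t01 = t[1:, 1:], t[:-1, 1:]
    total = (wrap_nematic(t10 - t00) + wrap_nematic(t11 - t10)
             + wrap_nematic(t01 - t11) + wrap_nematic(t00 - t01))
    winding = total / np.pi
    defined = m[:-1, :-1] & m[1:, :-1] & m[1:, 1:] & m[:-1, 1:]
    return DeficitField(d.grid, np.abs(winding) * defined, winding * defined,
                        defined)


def _director_on_circle(d: DirectorField, center, radius, n_samples):
    phi = np.linspace(0.0, 2 * np.pi, n_samples, endpoint=False)
    xs = center[0] + radius * np.cos(phi)
    ys = center[1] + radius * np.sin(phi)
    ix, iy = d.grid.cell_of(xs, ys)
    theta = d.theta[ix, iy]
    ok = d.defined[ix, iy]
    # reject samples whose nominal point actually falls off the grid
    lo, hi = d.grid.x0, -d.grid.x0
    ok &= (xs >= lo) & (xs < hi) & (ys >= lo) & (ys < hi)
    return phi, theta, ok


def _winding_of_run(theta):
    return wrap_nematic(np.diff(theta)).sum()


def _charge_at(d: DirectorField, center, radius, n_samples=72):
    """Winding / 2pi around ``center``; None if < 3/4 of the loop is defined."""
    phi, theta, ok = _director_on_circle(d, center, radius, n_samples)
    dphi = 2 * np.pi / n_samples
    if ok.all():
        diffs = wrap_nematic(np.diff(np.append(theta, theta[0])))
        raw = diffs.sum() / (2 * np.pi)
        return raw
    # longest contiguous defined arc (circular)
    if not ok.any():
        return None
    ext = np.concatenate([ok, ok])
    best_len, best_start = 0, 0
    run = 0
    for i, flag in enumerate(ext):
        if flag:
            run += 1
            if run > best_len:
                best_len, best_start = run, i - run + 1
        else:
            run = 0
    best_len = min(best_len, n_samples)
    if (best_len - 1) * dphi < 1.5 * np.pi:
        return None
    idx = (best_start + np.arange(best_len)) % n_samples
    arc = (best_len - 1) * dphi
    return _winding_of_run(theta[idx]) * (2 * np.pi / arc) / (2 * np.pi)


def detect_defects(d: DirectorField, deficit: DeficitField, threshold=0.5,
                   merge_radius=2.0, charge_radius=3.0,
                   n_samples=72) -> list[Defect]:
    """Locate and charge orientational singularities.

    Above-threshold deficit vertices are clustered (8-connectivity,
    clusters closer than ``merge_radius`` cells merged); each cluster
    yields one defect at its deficit-weighted centroid, charged by the
    director winding along a circle of ``charge_radius`` cells.  Clusters
    whose winding rounds to zero are discarded; a loop that leaves the
    defined region with less than 3/4 of a turn available is kept but
    flagged uncharged (``charge is None``).
    """
    grid = d.grid
    h = grid.cell_size
    mask = deficit.defined & (deficit.deficit >= threshold)
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_lab == 0:
        return []
    Xv, Yv = grid.vertex_positions()
    cents = []
    scores = []
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        wgt = deficit.deficit[sel]
        cents.append([np.average(Xv[sel], weights=wgt),
                      np.average(Yv[sel], weights=wgt)])
        scores.append(float(wgt.max()))
    cents = np.asarray(cents)
    # greedy merge of nearby clusters
    parent = list(range(len(cents)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(cents)):
        for j in range(i + 1, len(cents)):
            if np.hypot(*(cents[i] - cents[j])) < merge_radius * h:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(cents)):
        groups.setdefault(find(i), []).append(i)
    defects = []
    for members in groups.values():
        wgt = np.array([scores[i] for i in members])
        pos = np.average(cents[members], axis=0, weights=wgt)
        score = float(wgt.max())
        raw = _charge_at(d, pos, charge_radius * h, n_samples)
        if raw is None:
            defects.append(Defect(pos, None, score))
            continue
        q = round(2.0 * raw) / 2.0
        if q == 0.0:
            continue
        defects.append(Defect(pos, q, score, residual=abs(raw - q)))
    defects.sort(key=lambda df: -df.score)
    return defects


def ring_winding(d: DirectorField, radius, center=(0.0, 0.0), n_samples=None):
    """Director winding / 2pi along a circle; errors on undefined cells."""
    if n_samples is None:
        n_samples = max(90, int(4 * np.pi * radius / d.grid.cell_size))
    phi, theta, ok = _director_on_circle(d, center, radius, n_samples)
    if not ok.all():
        raise AnalysisError(
            f"ring of radius {radius:.3g} crosses undefined director cells")
    diffs = wrap_nematic(np.diff(np.append(theta, theta[0])))
    return float(diffs.sum() / (2 * np.pi))


def total_charge(defects, d: DirectorField, boundary: Confinement,
                 ring_fraction=0.95):
    """Topological charge enclosed by a ring just inside the outer wall.

    Returns the boundary winding of the director along the ring at
    ``ring_fraction * R_outer``.  The sum of detected defect charges is
    a cross-check only: virtual defects outside the domain legitimately
    break the equality, so a mismatch is reported in the log rather than
    enforced.
    """
    import logging
    w = ring_winding(d, ring_fraction * boundary.R_outer)
    charged = [df.charge for df in defects if df.charge is not None]
    if charged and abs(sum(charged) - w) > 0.26:
        logging.getLogger(__name__).info(
            "boundary winding %+.2f != sum of defect charges %+.2f "
            "(virtual defects outside the domain?)", w, sum(charged))
    return w


def local_packing_fraction(snapshots, grid: Grid2D,
                           seg_len=DEFAULT_SEG_LEN) -> PackingField:
    """Ensemble-averaged local volume fraction of the rods.

    Each axis segment deposits its share of the rod volume into the
    cell holding its midpoint; the cell value is the deposited volume
    divided by the cell's slab volume (cell area times plate spacing).
    The average over accessible cells therefore reproduces the global
    packing fraction.
    """
    snaps = _iter_snapshots(snapshots)
    if grid.confinement is None:
        raise ConfigError("grid must carry its confinement for packing analysis")
    _, _, _, vol, _ = _segment_deposit(snaps, grid, seg_len)
    slab = grid.cell_size**2 * grid.confinement.H
    phi = vol / (len(snaps) * slab)
    return PackingField(grid, phi, grid.mask.copy())


def subsample_error(snapshots, statistic, k):
    """Block (subsample) standard error of an ensemble statistic.

    Snapshots are split into ``k`` contiguous blocks, ``statistic`` is
    evaluated on each block, and the standard deviation over blocks
    divided by sqrt(k) is returned.
    """
    if k < 2:
        raise ConfigError("subsample count k must be >= 2")
    if hasattr(snapshots, "configurations"):
        snapshots = snapshots.configurations()
    snapshots = list(snapshots)
    if len(snapshots) < k:
        raise ConfigError("need at least k snapshots")
    blocks = np.array_split(np.arange(len(snapshots)), k)
    vals = np.asarray([np.asarray(statistic([snapshots[i] for i in b]),
                                  dtype=float) for b in blocks])
    return vals.std(axis=0, ddof=1) / np.sqrt(k)
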