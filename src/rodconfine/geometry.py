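"""Hard-body geometry of spherocylinders in shallow cylindrical chambers.

All lengths are expressed in units of the rod diameter ``D`` (``D = 1``
internally).  A spherocylinder of length ``L`` is a cylinder of that
axis length capped by two hemispheres, so its tip-to-tip extent is
``L + D``.  Chambers are either disks (``R_inner = 0``) or annuli,
bounded above and below by parallel plates a distance ``H`` apart.

Overlap and wall tests are exact: two rods overlap iff the minimum
distance between their axis segments is strictly below ``D`` (tangency
counts as touching, not overlapping), and a rod fits in the chamber iff
its axis keeps a clearance of ``D/2`` from every wall.
"""

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as _k
from .errors import ConfigError

__all__ = [
    "Rod",
    "Confinement",
    "confinement_ratio",
    "segment_min_distance",
    "rods_overlap",
    "rod_in_confinement",
    "spherocylinder_volume",
    "particle_count",
    "packing_fraction",
]

_UNIT_TOL = 1e-12


def _check_unit(u, name="u"):
    u = np.asarray(u, dtype=float)
    if u.shape != (3,):
        raise ConfigError(f"{name} must be a 3-vector, got shape {u.shape}")
    if abs(u @ u - 1.0) > 1e-10:
        raise ConfigError(f"{name} must be a unit vector (|{name}|^2 = {u @ u:.12g})")
    return u


@dataclass
class Rod:
    """One hard spherocylinder: centre, unit axis, length, diameter."""

    center: np.ndarray
    u: np.ndarray
    L: float
    D: float = 1.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ConfigError("Rod.center must be a 3-vector")
        self.u = _check_unit(self.u)
        if self.L < 0:
            raise ConfigError("Rod.L must be non-negative")
        if self.D <= 0:
            raise ConfigError("Rod.D must be positive")

    @property
    def half_length(self):
        return 0.5 * self.L

    @property
    def endpoints(self):
        """Both axis endpoints, shape (2, 3)."""
        h = self.half_length * self.u
        return np.stack([self.center - h, self.center + h])


@dataclass(frozen=True)
class Confinement:
    """Disk or annulus chamber: outer radius, inner radius, plate spacing.

    ``R_inner = 0`` means a disk.  The plates sit at z = 0 and z = H.
    """

    R_outer: float
    R_inner: float = 0.0
    H: float = 1.0
    D: float = field(default=1.0, repr=False)

    def __post_init__(self):
        if self.R_outer <= 0:
            raise ConfigError("R_outer must be positive")
        if self.R_inner < 0:
            raise ConfigError("R_inner must be non-negative")
        if self.H < self.D:
            raise ConfigError(
                f"plate spacing H = {self.H} must be at least one rod diameter"
            )
        if self.R_inner > 0 and not (self.R_inner + self.D < self.R_outer - self.D):
            raise ConfigError("no rod-accessible annular gap: R_inner too close to R_outer")

    @property
    def is_disk(self):
        return self.R_inner == 0.0

    @property
    def volume(self):
        """Chamber volume in D^3."""
        return np.pi * (self.R_outer**2 - self.R_inner**2) * self.H

    @property
    def footprint_area(self):
        """In-plane area in D^2."""
        return np.pi * (self.R_outer**2 - self.R_inner**2)


def confinement_ratio(L, R_outer):
    """Lateral confinement ratio kappa = L / (2 R_outer).

    kappa = 1 when a rod axis can just span the chamber diameter;
    kappa -> 0 is the unconfined limit.
    """
    kappa = L / (2.0 * R_outer)
    if not 0.0 < kappa <= 1.0:
        raise ConfigError(f"kappa = {kappa:.4g} outside (0, 1]: rod does not fit")
    return kappa


def segment_min_distance(p1, u1, l1, p2, u2, l2):
    """Minimum Euclidean distance between two finite segments.

    Segment i is the set {p_i + s u_i : |s| <= l_i}; u_i must be a unit
    vector and l_i a non-negative half-length.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    u1 = _check_unit(u1, "u1")
    u2 = _check_unit(u2, "u2")
    if l1 < 0 or l2 < 0:
        raise ConfigError("half-lengths must be non-negative")
    return float(
        _k.seg_dist(p1[0], p1[1], p1[2], u1[0], u1[1], u1[2], float(l1),
                    p2[0], p2[1], p2[2], u2[0], u2[1], u2[2], float(l2))
    )


def rods_overlap(a: Rod, b: Rod) -> bool:
    """True iff the two rods' hard cores interpenetrate (strict)."""
    if a.D != b.D:
        raise ConfigError("rods_overlap requires equal diameters")
    d = segment_min_distance(a.center, a.u, a.half_length,
                             b.center, b.u, b.half_length)
    return d < a.D


def rod_in_confinement(a: Rod, c: Confinement) -> bool:
    """True iff the rod fits entirely inside the chamber walls."""
    return bool(
        _k.rod_fits(a.center[0], a.center[1], a.center[2],
                    a.u[0], a.u[1], a.u[2],
                    a.half_length, a.D, c.R_outer, c.R_inner, c.H)
    )


def spherocylinder_volume(L, D=1.0):
    """Volume of a spherocylinder: cylinder pi D^2 L / 4 plus cap sphere pi D^3 / 6."""
    if L < 0:
        raise ConfigError("L must be non-negative")
    if D <= 0:
        raise ConfigError("D must be positive")
    return np.pi * D * D * L / 4.0 + np.pi * D**3 / 6.0


def particle_count(eta, c: Confinement, L, D=1.0) -> int:
    """Number of rods realizing packing fraction ``eta`` in chamber ``c``.

    Rounded to the nearest integer; use :func:`packing_fraction` for the
    realized value.
    """
    if not 0.0 <= eta < 1.0:
        raise ConfigError(f"packing fraction eta = {eta} outside [0, 1)")
    return int(round(eta * c.volume / spherocylinder_volume(L, D)))


def packing_fraction(N, c: Confinement, L, D=1.0) -> float:
    """Packing fraction realized by N rods in chamber ``c``."""
    if N < 0:
        raise ConfigError("N must be non-negative")
    return N * spherocylinder_volume(L, D) / c.volume
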