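"""Classification of converged confinement patterns.

Disk chambers: the taxonomy is built on the bipolar ansatz — the
two-defect nematic field

    theta(r) = (phi_+ + phi_-) / 2,

with phi_+- the polar angles of r about the defect points (+-a, 0).
Depending on where the two +1/2 singularities sit, the pattern is
labelled B_i (inside the disk), B_b (at its boundary), B_o (virtual
defects a finite distance outside) or B_inf (virtual defects
effectively at infinity, i.e. a nearly uniform nematic).

Annulus chambers: n-fold symmetric domain structures (dihedral symbol
D_n) are recognized from the angular modulation of the scalar order S
and of the director's misalignment with the tangential direction along
the mid-annulus circle — domain walls depress S, so the symmetry is
readable even when (for n >= 4) the walls are extended disclination
lines without pointlike outer defects.  A purely axisymmetric,
defect-free tangential state reports the infinity sentinel.

The inscribed-n-gon rule predicts which n the hole size selects: n rods
of length L forming a regular n-gon have apothem (L/2) / tan(pi / n);
the hole radius at which that polygon of rod surfaces just wraps the
hole sets the regime boundary.
"""

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import AnalysisError, ConfigError
from .fields import DirectorField, Grid2D, SField, wrap_nematic
from .geometry import Confinement

__all__ = [
    "PatternLabel",
    "bipolar_ansatz",
    "fit_bipolar",
    "classify_disk",
    "symmetry_number",
    "predict_n",
    "D_INF",
]

D_INF = math.inf  # sentinel for the axisymmetric (defect-free) annulus state

DEFAULT_C_INF = 5.0
DEFAULT_FAIL_RESIDUAL = 0.35
DEFAULT_DOMINANCE = 2.0


@dataclass
class PatternLabel:
    """Classification outcome with the evidence that produced it."""

    family: str                      # "B_i" | "B_b" | "B_o" | "B_inf" | "D_n" | "unclassified"
    n: float | None = None           # symmetry count for D_n (math.inf sentinel)
    evidence: dict = field(default_factory=dict)


def bipolar_angle(x, y, a, axis_angle=0.0):
    """Bipolar two-defect angle field evaluated at (x, y)."""
    ca, sa = np.cos(axis_angle), np.sin(axis_angle)
    xr = ca * np.asarray(x) + sa * np.asarray(y)
    yr = -sa * np.asarray(x) + ca * np.asarray(y)
    th = 0.5 * (np.arctan2(yr, xr - a) + np.arctan2(yr, xr + a))
    return np.mod(th + axis_angle, np.pi)


def bipolar_ansatz(a, grid: Grid2D, axis_angle=0.0) -> DirectorField:
    """Director field of two +1/2 defects at (+-a, 0) on the given grid."""
    if a <= 0:
        raise ConfigError("bipolar ansatz requires a > 0 "
                          "(a = 0 degenerates to a radial +1 defect)")
    X, Y = grid.meshgrid()
    theta = bipolar_angle(X, Y, a, axis_angle)
    defined = grid.mask.copy() if grid.mask is not None else np.ones_like(theta, bool)
    return DirectorField(grid, theta, defined)


def _angle_residual(theta_model, theta_data):
    # mean angle-doubled misfit in [0, 1]: 0 = identical, 1 = perpendicular
    return float(np.mean(0.5 * (1.0 - np.cos(2.0 * (theta_model - theta_data)))))


def fit_bipolar(d: DirectorField, c: Confinement, a_max_factor=12.0):
    """Least-squares fit of the bipolar ansatz to a measured disk field.

    Free parameters: defect half-separation ``a`` and global axis angle.
    The misfit per cell is the angle-doubled residual
    ``(1 - cos 2(theta_fit - theta))/2``; returns
    ``(a_hat, axis_angle, residual)`` with the residual averaged over
    defined cells.  Large ``a_hat`` means virtual defects: the field
    approaches a uniform nematic as a -> infinity.
    """
    if not c.is_disk:
        raise ConfigError("fit_bipolar applies to disk geometry only")
    X, Y = d.grid.meshgrid()
    sel = d.defined
    if sel.sum() < 16:
        raise AnalysisError("too few defined director cells to fit")
    x, y, th = X[sel], Y[sel], d.theta[sel]
    R = c.R_outer

    def cost(p):
        log_a, psi = p
        return _angle_residual(bipolar_angle(x, y, np.exp(log_a), psi), th)

    best = None
    for a0 in np.geomspace(0.1 * R, a_max_factor * R, 14):
        for psi0 in np.linspace(0.0, np.pi, 8, endpoint=False):
            v = cost((np.log(a0), psi0))
            if best is None or v < best[1]:
                best = ((np.log(a0), psi0), v)
    res = optimize.minimize(cost, best[0], method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-8})
    a_hat = float(np.exp(res.x[0]))
    psi = float(np.mod(res.x[1], np.pi))
    return a_hat, psi, float(res.fun)


def classify_disk(defects, fit, c: Confinement, L=None, w_b=None,
                  c_inf=DEFAULT_C_INF,
                  fail_residual=DEFAULT_FAIL_RESIDUAL) -> PatternLabel:
    """Disk-pattern taxonomy from detected defects plus the bipolar fit.

    Two interior +1/2 defects deeper than the boundary band ``w_b``
    (default L/2 — the anchoring layer is of order the rod length) give
    B_i; within the band, B_b.  With no detected defects the fitted
    virtual-defect distance decides: ``a_hat <= c_inf R_outer`` is B_o,
    beyond that B_inf.  Anything else is returned as unclassified with
    diagnostics.
    """
    a_hat, psi, residual = fit
    if w_b is None:
        w_b = 0.5 * L if L is not None else 0.1 * c.R_outer
    evidence = {"a_hat": a_hat, "axis_angle": psi, "residual": residual,
                "w_b": w_b, "n_defects": len(defects)}
    if residual > fail_residual:
        return PatternLabel("unclassified", evidence={**evidence,
                                                      "reason": "poor bipolar fit"})
    charged = [df for df in defects if df.charge is not None]
    if len(charged) == 2:
        if any(df.charge != 0.5 for df in charged):
            return PatternLabel("unclassified", evidence={
                **evidence, "reason": "unexpected defect charges",
                "charges": [df.charge for df in charged]})
        radii = [float(np.hypot(*df.position)) for df in charged]
        evidence["defect_radii"] = radii
        if max(radii) < c.R_outer - w_b:
            return PatternLabel("B_i", evidence=evidence)
        return PatternLabel("B_b", evidence=evidence)
    if len(charged) == 0:
        if a_hat <= c_inf * c.R_outer:
            return PatternLabel("B_o", evidence=evidence)
        return PatternLabel("B_inf", evidence=evidence)
    return PatternLabel("unclassified", evidence={
        **evidence, "reason": f"{len(charged)} charged defects (expected 0 or 2)"})


def _ring_profile(values, defined, grid, radius, n_samples):
    """Sample a cell field along a circle, stepping to the nearest defined
    cell radially when the nominal one is undefined."""
    phi = np.linspace(0.0, 2 * np.pi, n_samples, endpoint=False)
    out = np.empty(n_samples)
    for i, p in enumerate(phi):
        val = None
        for dr in np.arange(0.0, 6.0) * grid.cell_size:
            for sgn in (0, -1, 1):
                r = radius + sgn * dr
                if r <= 0:
                    continue
                ix, iy = grid.cell_of(r * np.cos(p), r * np.sin(p))
                if defined[ix, iy]:
                    val = values[ix, iy]
                    break
            if val is not None:
                break
        if val is None:
            raise AnalysisError("no defined cells near the sampling circle")
        out[i] = val
    return phi, out


def symmetry_number(s: SField, d: DirectorField, c: Confinement,
                    rho=DEFAULT_DOMINANCE, n_max=12, n_samples=720,
                    mod_floor=0.02):
    """Dominant angular symmetry n of an annulus pattern, or the
    infinity sentinel for an axisymmetric defect-free state.

    Profiles of the scalar order S and of the director's tangential
    misalignment sin^2(theta - theta_tangent) are sampled along the
    mid-annulus circle; their angular Fourier power spectra (variance
    normalized, then summed) vote on the fundamental.  Harmonics that
    are multiples of the winner support it rather than competing, so
    dominance is tested against the strongest non-multiple harmonic.
    """
    if c.is_disk:
        raise ConfigError("symmetry_number applies to annular geometry")
    r_mid = 0.5 * (c.R_inner + c.R_outer)
    phi, s_prof = _ring_profile(s.S, s.defined, s.grid, r_mid, n_samples)
    _, th_prof = _ring_profile(d.theta, d.defined, d.grid, r_mid, n_samples)
    mis = np.sin(th_prof - (phi + 0.5 * np.pi)) ** 2
    power = np.zeros(n_max + 1)
    modulation = 0.0
    for prof in (s_prof, mis):
        f = prof - prof.mean()
        modulation = max(modulation, float(f.std()))
        psd = np.abs(np.fft.rfft(f))**2
        tot = psd[1:].sum()
        if tot > 0:
            power[1:] += psd[1:n_max + 1] / tot
    if modulation < mod_floor:
        return D_INF
    n_star = int(np.argmax(power[2:]) + 2)
    rivals = [power[k] for k in range(2, n_max + 1)
              if k != n_star and k % n_star != 0]
    if rivals and power[n_star] < rho * max(rivals):
        return D_INF
    return n_star


def predict_n(R_inner, L, D=1.0, offset=-0.5, n_max=64):
    """Inscribed-n-gon prediction of the annulus symmetry number.

    ``n`` rods of length L arranged as a regular n-gon around the hole
    have apothem ``r_n = (L/2) / tan(pi/n) + offset``; the default
    offset of -D/2 puts the rod surface, not its axis, against the
    hole.  Returns the largest n (>= 3) whose polygon fits around a
    hole of radius ``R_inner``, or 2 (the bipolar-like state) when even
    the triangle does not fit.
    """
    if R_inner < 0 or L <= 0 or D <= 0:
        raise ConfigError("R_inner must be >= 0 and L, D > 0")
    n = 2
    for k in range(3, n_max + 1):
        r_k = 0.5 * L / math.tan(math.pi / k) + offset * D
        if r_k <= R_inner + 1e-9:   # tolerate roundoff at exact thresholds
            n = k
        else:
            break
    return n
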