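"""Biot–Savart field of a distributed-winding Helmholtz coil pair.

Two identical coaxial coils (axis = x) carry N turns each, distributed over
a rectangular winding cross-section (radii ``inner_radius``–``outer_radius``,
axial width ``axial_width``).  Every turn is modeled as an ideal circular
current loop; on-axis fields use the closed form

    B(x) = μ0 I R² / (2 (R² + x²)^{3/2}),

off-axis fields the standard complete-elliptic-integral solution.  Reported
magnitudes are sinusoid amplitudes (peak values) of the drive current.

Biological tissue has relative permeability ≈ 1 and therefore does not
perturb B; the same maps apply with or without the phantom present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import ellipe, ellipk

from mihsim.constants import MU0

__all__ = [
    "CoilSpec",
    "DriveCurrent",
    "FieldMap",
    "loop_axial_field",
    "loop_field_offaxis",
    "helmholtz_axis_profile",
    "helmholtz_center_closed_form",
    "field_map_3d",
    "center_flux_density",
    "calibrate_separation",
    "uniformity_report",
]


@dataclass(frozen=True)
class DriveCurrent:
    """Sinusoidal coil drive: peak current amplitude (A) and frequency (Hz)."""

    amplitude: float = 8.0
    frequency: float = 100.0e3

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.frequency <= 0:
            raise ValueError("drive amplitude and frequency must be > 0")


@dataclass(frozen=True)
class CoilSpec:
    """Helmholtz-pair geometry and winding layout.

    ``separation`` is the distance between the two winding-pack center
    planes.  The classical Helmholtz condition (separation = radius) is the
    default; :func:`calibrate_separation` solves for the separation that
    matches a requested center flux density.  Each winding pack distributes
    ``turns`` loops on an ``n_radial`` × ``n_axial`` grid of cell centers
    spanning the radial build and axial width; a 1 × 1 layout is the ideal
    thin coil at the mean radius.  ``conductor_conductivity`` (copper,
    Table-level metadata) is carried but unused — no impedance model.
    """

    turns: int = 180
    inner_radius: float = 0.14
    outer_radius: float = 0.15
    axial_width: float = 0.05
    separation: float = 0.145
    n_radial: int = 12
    n_axial: int = 15
    conductor_conductivity: float = 5.998e7

    def __post_init__(self) -> None:
        if not (0 < self.inner_radius <= self.outer_radius):
            raise ValueError("need 0 < inner_radius <= outer_radius")
        if self.axial_width <= 0 or self.separation <= 0:
            raise ValueError("axial_width and separation must be > 0")
        if self.turns < 1 or self.n_radial < 1 or self.n_axial < 1:
            raise ValueError("turns and layout subdivisions must be >= 1")

    @property
    def mean_radius(self) -> float:
        return 0.5 * (self.inner_radius + self.outer_radius)

    def loop_positions(self) -> tuple[np.ndarray, np.ndarray, float]:
        """All loops of the pair: (radii, axial positions, turns per loop).

        Axial positions are along the coil axis (x), measured from the pair
        midpoint; each of the ``2 * n_radial * n_axial`` loops carries
        ``turns / (n_radial * n_axial)`` turns.
        """
        dr = (self.outer_radius - self.inner_radius) / self.n_radial
        radii = self.inner_radius + dr * (np.arange(self.n_radial) + 0.5)
        dz = self.axial_width / self.n_axial
        offsets = -0.5 * self.axial_width + dz * (np.arange(self.n_axial) + 0.5)
        r_list, x_list = [], []
        for sign in (+1.0, -1.0):
            rr, xx = np.meshgrid(radii, sign * 0.5 * self.separation + offsets)
            r_list.append(rr.ravel())
            x_list.append(xx.ravel())
        weight = self.turns / (self.n_radial * self.n_axial)
        return np.concatenate(r_list), np.concatenate(x_list), weight


@dataclass
class FieldMap:
    """Sampled magnetic field: positions (m), flux density B (T).

    ``H = B / μ0`` holds everywhere because all media here have relative
    permeability 1.  ``E`` optionally carries induced electric-field
    magnitudes (V/m) from the quasi-static estimator.
    """

    points: np.ndarray
    B: np.ndarray
    E: np.ndarray | None = None

    @property
    def H(self) -> np.ndarray:
        return self.B / MU0

    @property
    def magnitude(self) -> np.ndarray:
        B = np.asarray(self.B)
        if B.ndim == 1:
            return np.abs(B)
        return np.linalg.norm(B, axis=-1)


def loop_axial_field(loop_radius: float, current: float, x) -> np.ndarray | float:
    """On-axis flux density (T) of a single circular current loop.

    ``x`` is the axial distance from the loop plane; the sign of the result
    follows the sign of ``current``.
    """
    if loop_radius <= 0:
        raise ValueError("loop_radius must be > 0")
    x = np.asarray(x, dtype=float)
    out = MU0 * current * loop_radius**2 / (2.0 * (loop_radius**2 + x**2) ** 1.5)
    return out if out.ndim else float(out)


def loop_field_offaxis(
    loop_radius: float,
    current: float,
    points,
    *,
    wire_clearance: float = 1.0e-3,
    cap: bool = False,
) -> np.ndarray:
    """Flux-density vectors (T) of one loop at arbitrary points.

    The loop lies in the y–z plane, centered on the origin, axis along x.
    Uses the complete-elliptic-integral solution; ``points`` closer than
    ``wire_clearance`` to the wire raise an error unless ``cap=True``, in
    which case they are evaluated at the clearance distance (magnitude cap).
    """
    if loop_radius <= 0:
        raise ValueError("loop_radius must be > 0")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x = pts[:, 0]
    rho = np.hypot(pts[:, 1], pts[:, 2])

    dist_wire = np.hypot(rho - loop_radius, x)
    close = dist_wire < wire_clearance
    if np.any(close):
        if not cap:
            raise ValueError(
                f"{int(close.sum())} sample point(s) within {wire_clearance} m "
                "of the wire; refine the grid or pass cap=True"
            )
        # push capped points out to the clearance circle around the wire;
        # points exactly on the wire move radially outward
        rho = rho.copy()
        x = x.copy()
        d = dist_wire[close]
        dir_r = np.where(d > 1e-12, (rho[close] - loop_radius) / np.maximum(d, 1e-12), 1.0)
        dir_x = np.where(d > 1e-12, x[close] / np.maximum(d, 1e-12), 0.0)
        rho[close] = loop_radius + dir_r * wire_clearance
        x[close] = dir_x * wire_clearance

    on_axis = rho < 1e-12 * loop_radius
    rho_safe = np.where(on_axis, 1.0, rho)

    denom = (loop_radius + rho_safe) ** 2 + x**2
    m = 4.0 * loop_radius * rho_safe / denom  # elliptic parameter m = k²
    m = np.clip(m, 0.0, 1.0 - 1e-15)
    K, E = ellipk(m), ellipe(m)
    gamma = (loop_radius - rho_safe) ** 2 + x**2
    pref = MU0 * current / (2.0 * math.pi * np.sqrt(denom))
    Bx = pref * (K + (loop_radius**2 - rho_safe**2 - x**2) / gamma * E)
    Brho = (
        pref
        * x
        / rho_safe
        * (-K + (loop_radius**2 + rho_safe**2 + x**2) / gamma * E)
    )

    Bx = np.where(on_axis, loop_axial_field(loop_radius, current, x), Bx)
    Brho = np.where(on_axis, 0.0, Brho)

    out = np.zeros_like(pts)
    out[:, 0] = Bx
    with np.errstate(invalid="ignore", divide="ignore"):
        ey = np.where(on_axis, 0.0, pts[:, 1] / rho_safe)
        ez = np.where(on_axis, 0.0, pts[:, 2] / rho_safe)
    out[:, 1] = Brho * ey
    out[:, 2] = Brho * ez
    return out if np.asarray(points).ndim > 1 else out[0]


def helmholtz_center_closed_form(
    turns: int = 180, current: float = 8.0, radius: float = 0.145
) -> float:
    """Ideal thin-coil Helmholtz center flux density (4/5)^{3/2} μ0 N I / R."""
    return (4.0 / 5.0) ** 1.5 * MU0 * turns * current / radius


def helmholtz_axis_profile(coil: CoilSpec, drive: DriveCurrent, x_samples) -> FieldMap:
    """Axial flux density of the pair by superposing all winding loops."""
    xs = np.atleast_1d(np.asarray(x_samples, dtype=float))
    radii, x_loops, weight = coil.loop_positions()
    B = np.zeros_like(xs)
    for r, xl in zip(radii, x_loops):
        B += weight * loop_axial_field(r, drive.amplitude, xs - xl)
    points = np.zeros((xs.size, 3))
    points[:, 0] = xs
    return FieldMap(points=points, B=B)


def center_flux_density(coil: CoilSpec, drive: DriveCurrent) -> float:
    """Peak flux density (T) at the geometric center of the pair."""
    return float(helmholtz_axis_profile(coil, drive, 0.0).B[0])


def field_map_3d(
    coil: CoilSpec, drive: DriveCurrent, points, *, cap: bool = False
) -> FieldMap:
    """Vector B on arbitrary sample points by loop superposition.

    Tissue does not perturb the field (relative permeability 1), so the same
    map is valid with the phantom present.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    radii, x_loops, weight = coil.loop_positions()
    B = np.zeros_like(pts)
    shifted = pts.copy()
    for r, xl in zip(radii, x_loops):
        shifted[:, 0] = pts[:, 0] - xl
        B += weight * loop_field_offaxis(r, drive.amplitude, shifted, cap=cap)
    return FieldMap(points=pts, B=B)


def calibrate_separation(
    coil: CoilSpec,
    drive: DriveCurrent,
    target_flux_density: float,
    bracket: tuple[float, float] = (0.08, 0.40),
) -> CoilSpec:
    """Solve for the center-plane separation that yields the requested
    center flux density (T); returns a new :class:`CoilSpec`.

    The center field decreases monotonically with separation over the
    bracket, so a root always exists when the target lies between the
    bracket endpoints' fields.
    """
    lo, hi = bracket

    def f(s: float) -> float:
        return center_flux_density(replace(coil, separation=s), drive) - target_flux_density

    if f(lo) < 0 or f(hi) > 0:
        raise ValueError(
            f"target {target_flux_density} T not attainable for separations in {bracket}"
        )
    s = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    return replace(coil, separation=float(s))


def uniformity_report(field_map: FieldMap, region=None) -> dict[str, float]:
    """Extrema and relative ripple of |B| over a sample subset.

    ``region`` is a boolean mask over the map's samples (default: all).
    Ripple is (max − min) / center, where "center" is the sample nearest
    the coordinate origin.
    """
    mag = field_map.magnitude
    if region is None:
        region = np.ones(mag.shape, dtype=bool)
    region = np.asarray(region, dtype=bool)
    if region.shape != mag.shape:
        raise ValueError("region mask does not match the field map samples")
    if not region.any():
        raise ValueError("empty region")
    sel = mag[region]
    center_idx = int(np.argmin(np.linalg.norm(field_map.points, axis=-1)))
    center = float(mag[center_idx])
    return {
        "min": float(sel.min()),
        "max": float(sel.max()),
        "center": center,
        "ripple": float((sel.max() - sel.min()) / center),
    }
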