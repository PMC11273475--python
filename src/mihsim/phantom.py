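"""Tissue property registry and the voxelized layered mouse-head phantom.

The registry carries the measured dielectric (100 kHz) and thermophysical
parameters of murine tissues, the injected magnetite nanofluid, the tumor
tissue and the tumor/nanofluid mixture at volume fraction 0.003.  The phantom
is a labeled isotropic voxel grid: an ellipsoidal brain core wrapped in
concentric skull and scalp shells, a cylindrical melanoma disk (surface area
451.52 mm², thickness 2 mm) embedded at the head apex, and a muscle-like body
stub below the head that provides the far-field heat sink.

Coordinate convention: physical coordinates in meters, origin at the
geometric center of the Helmholtz coil (= tumor center); x is the coil axis,
z points upward through the tumor.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TissueProperties",
    "TissueRegistry",
    "MixtureSpec",
    "VoxelPhantom",
    "mixture_properties",
    "build_head_phantom",
    "region_mask",
    "AIR",
    "DEFAULT_MIXTURE_PHI",
]

AIR = "air"

#: Canonical nanofluid volume fraction of the study conditions.
DEFAULT_MIXTURE_PHI = 0.003

_CSV_COLUMNS = [
    "sigma_S_per_m",
    "eps_r",
    "rho_kg_m3",
    "c_J_kgK",
    "k_W_mK",
    "omega_b_per_s",
    "Qm_W_m3",
]

# Documented fallbacks for values the source tables do not print.
_DIELECTRIC_FALLBACK = {
    "tumor tissue": "muscle",
    "mixed tissue": "muscle",
    "magnetic nanofluids": "muscle",
}
_THERMAL_FALLBACK = {"torso": "muscle", "limbs": "muscle"}


@dataclass(frozen=True)
class TissueProperties:
    """Physical properties of one tissue; ``None`` marks an untabulated value.

    Units: conductivity S/m, density kg/m³, specific_heat J/(kg·K),
    thermal_conductivity W/(m·K), perfusion_rate 1/s, metabolic_heat W/m³.
    """

    name: str
    conductivity: float | None = None
    relative_permittivity: float | None = None
    density: float | None = None
    specific_heat: float | None = None
    thermal_conductivity: float | None = None
    perfusion_rate: float | None = None
    metabolic_heat: float | None = None

    def __post_init__(self) -> None:
        for field in (
            "conductivity",
            "relative_permittivity",
            "density",
            "specific_heat",
            "thermal_conductivity",
            "perfusion_rate",
            "metabolic_heat",
        ):
            value = getattr(self, field)
            if value is not None and value < 0:
                raise ValueError(f"{self.name}: {field} must be >= 0, got {value}")


class TissueRegistry:
    """Lookup table of :class:`TissueProperties`, loaded from a CSV mirror of
    the printed parameter tables."""

    def __init__(self, tissues: Iterable[TissueProperties]):
        self._tissues: dict[str, TissueProperties] = {}
        for t in tissues:
            if t.name in self._tissues:
                raise ValueError(f"duplicate tissue entry: {t.name!r}")
            self._tissues[t.name] = t

    @classmethod
    def from_csv(cls, path=None) -> "TissueRegistry":
        if path is None:
            text = (resources.files("mihsim.data") / "tissues.csv").read_text()
            df = pd.read_csv(io.StringIO(text))
        else:
            df = pd.read_csv(path)
        tissues = []
        for _, row in df.iterrows():
            kwargs = {
                col_to_field: None if pd.isna(row[col]) else float(row[col])
                for col, col_to_field in zip(
                    _CSV_COLUMNS,
                    (
                        "conductivity",
                        "relative_permittivity",
                        "density",
                        "specific_heat",
                        "thermal_conductivity",
                        "perfusion_rate",
                        "metabolic_heat",
                    ),
                )
            }
            tissues.append(TissueProperties(name=str(row["tissue"]), **kwargs))
        return cls(tissues)

    def to_csv(self, path) -> None:
        rows = []
        for t in self._tissues.values():
            rows.append(
                {
                    "tissue": t.name,
                    "sigma_S_per_m": t.conductivity,
                    "eps_r": t.relative_permittivity,
                    "rho_kg_m3": t.density,
                    "c_J_kgK": t.specific_heat,
                    "k_W_mK": t.thermal_conductivity,
                    "omega_b_per_s": t.perfusion_rate,
                    "Qm_W_m3": t.metabolic_heat,
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._tissues)

    def __contains__(self, name: str) -> bool:
        return name in self._tissues

    def lookup(self, name: str) -> TissueProperties:
        """Raw registry entry, exactly as tabulated (may contain ``None``)."""
        try:
            return self._tissues[name]
        except KeyError:
            raise KeyError(f"unknown tissue {name!r}") from None

    def resolved(self, name: str) -> TissueProperties:
        """Entry with documented fallbacks filled in.

        Dielectric values absent for tumor/mixed/nanofluid fall back to
        muscle; thermal values absent for torso/limbs fall back to muscle;
        mixed tissue inherits tumor perfusion and metabolic heat; the pure
        nanofluid is non-perfused and non-metabolizing.  Air keeps its
        missing thermal entries (it is excluded from the thermal solve).
        """
        t = self.lookup(name)
        updates: dict[str, float] = {}
        if t.conductivity is None and name in _DIELECTRIC_FALLBACK:
            donor = self.lookup(_DIELECTRIC_FALLBACK[name])
            updates["conductivity"] = donor.conductivity
            updates["relative_permittivity"] = donor.relative_permittivity
        if t.density is None and name in _THERMAL_FALLBACK:
            donor = self.lookup(_THERMAL_FALLBACK[name])
            updates.update(
                density=donor.density,
                specific_heat=donor.specific_heat,
                thermal_conductivity=donor.thermal_conductivity,
                perfusion_rate=donor.perfusion_rate,
                metabolic_heat=donor.metabolic_heat,
            )
        if name == "mixed tissue":
            tumor = self.lookup("tumor tissue")
            if t.perfusion_rate is None:
                updates["perfusion_rate"] = tumor.perfusion_rate
            if t.metabolic_heat is None:
                updates["metabolic_heat"] = tumor.metabolic_heat
        if name == "magnetic nanofluids":
            if t.perfusion_rate is None:
                updates["perfusion_rate"] = 0.0
            if t.metabolic_heat is None:
                updates["metabolic_heat"] = 0.0
        return replace(t, **updates) if updates else t


@dataclass(frozen=True)
class MixtureSpec:
    """Volume-fraction mixture of a base tissue with nanoparticle material."""

    volume_fraction: float
    base_tissue: str = "tumor tissue"
    particle_material: str = "magnetic nanofluids"

    def __post_init__(self) -> None:
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise ValueError(
                f"volume_fraction must be in [0, 1], got {self.volume_fraction}"
            )


def mixture_properties(spec: MixtureSpec, registry: TissueRegistry) -> TissueProperties:
    """Properties of tumor tissue loaded with magnetic fluid.

    Density and specific heat are volume-fraction-weighted means of the two
    constituents; at the canonical φ = 0.003 the thermal conductivity is the
    tabulated mixed-tissue value (no standard mixing rule reproduces it),
    otherwise a volume-weighted mean is used.  Perfusion, metabolic heat and
    dielectric values are inherited from the base tissue.
    """
    phi = spec.volume_fraction
    base = registry.resolved(spec.base_tissue)
    part = registry.resolved(spec.particle_material)
    if phi == 0.0:
        return base

    def mix(a: float | None, b: float | None) -> float | None:
        if a is None or b is None:
            return a
        return (1.0 - phi) * a + phi * b

    if (
        "mixed tissue" in registry
        and abs(phi - DEFAULT_MIXTURE_PHI) < 1e-12
        and registry.lookup("mixed tissue").thermal_conductivity is not None
    ):
        k = registry.lookup("mixed tissue").thermal_conductivity
    else:
        k = mix(base.thermal_conductivity, part.thermal_conductivity)

    return TissueProperties(
        name=f"{spec.base_tissue}+{spec.particle_material} (phi={phi:g})",
        conductivity=base.conductivity,
        relative_permittivity=base.relative_permittivity,
        density=mix(base.density, part.density),
        specific_heat=mix(base.specific_heat, part.specific_heat),
        thermal_conductivity=k,
        perfusion_rate=base.perfusion_rate,
        metabolic_heat=base.metabolic_heat,
    )


@dataclass
class VoxelPhantom:
    """Labeled isotropic voxel grid.

    ``labels[i, j, k]`` indexes into ``tissue_names``; ``origin`` is the
    physical coordinate (m) of the *center* of voxel (0, 0, 0).
    """

    labels: np.ndarray
    voxel_size: float
    origin: np.ndarray
    tissue_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.labels.max(initial=0) >= len(self.tissue_names):
            raise ValueError("label index out of range of tissue_names")

    # -- geometry ---------------------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**3

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates along each axis (m)."""
        return tuple(
            self.origin[d] + self.voxel_size * np.arange(self.labels.shape[d])
            for d in range(3)
        )

    def point_to_index(self, point) -> tuple[int, int, int]:
        """Indices of the voxel containing a physical point."""
        point = np.asarray(point, dtype=float)
        # floor(x + 1/2): half-integer indices (points on voxel faces) resolve
        # to the upper voxel at every resolution
        idx = np.floor((point - self.origin) / self.voxel_size + 0.5).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.labels.shape)):
            raise ValueError(f"point {point} outside the phantom grid")
        return tuple(int(i) for i in idx)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid (m)."""
        return tuple(s * self.voxel_size for s in self.labels.shape)

    # -- labels -----------------------------------------------------------
    def label_index(self, name: str) -> int:
        try:
            return self.tissue_names.index(name)
        except ValueError:
            raise KeyError(f"unknown tissue label {name!r}") from None

    def region_mask(self, name: str) -> np.ndarray:
        return self.labels == self.label_index(name)

    def counts(self) -> dict[str, int]:
        n = np.bincount(self.labels.ravel(), minlength=len(self.tissue_names))
        return {name: int(c) for name, c in zip(self.tissue_names, n)}

    def tissue_volume(self, name: str) -> float:
        """Volume of one labeled region, m³."""
        return float(self.region_mask(name).sum()) * self.voxel_volume

    # -- export -----------------------------------------------------------
    def to_hdf5(self, path) -> None:
        from mihsim.io import phantom_to_hdf5

        phantom_to_hdf5(self, path)

    def to_vtk(self, path) -> None:
        from mihsim.io import write_vtk_structured_points

        write_vtk_structured_points(
            path,
            origin=self.origin - 0.5 * self.voxel_size,
            spacing=self.voxel_size,
            cell_data={"tissue_label": self.labels},
        )


def region_mask(phantom: VoxelPhantom, name: str) -> np.ndarray:
    """Boolean grid selecting exactly the voxels labeled ``name``."""
    return phantom.region_mask(name)


def build_head_phantom(
    voxel_size: float = 0.5e-3,
    *,
    tumor_area: float = 451.52e-6,
    tumor_thickness: float = 2.0e-3,
    scalp_thickness: float = 1.0e-3,
    skull_thickness: float = 1.0e-3,
    brain_semiaxes: tuple[float, float, float] = (8.0e-3, 6.0e-3, 6.0e-3),
    embed_depth: float = 0.5e-3,
    stub_radius: float = 6.0e-3,
    stub_length: float = 10.0e-3,
    margin_voxels: int = 2,
    grid_offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> VoxelPhantom:
    """Voxelize the layered head phantom with the melanoma disk on top.

    The melanoma is a right cylinder (flat disk) of surface area
    ``tumor_area`` and height ``tumor_thickness`` whose center is mapped to
    the spatial origin (the Helmholtz-coil center).  The head — an
    ellipsoidal brain core wrapped in skull and scalp shells — sits under
    the disk with its apex ``embed_depth`` above the disk's lower face, so
    the lesion is slightly embedded in the scalp; this keeps the thermal
    contact patch a physical quantity independent of grid resolution.  A
    muscle-like body stub extends from the head to the bottom grid face,
    where the solver pins the far-field temperature.

    Parameters are in meters.  ``grid_offset`` shifts all voxel centers by a
    (sub-voxel) amount, used to verify discretization invariances.
    """
    if voxel_size <= 0 or voxel_size > 1.0e-3:
        raise ValueError("voxel_size must be in (0, 1] mm")
    if tumor_thickness / voxel_size < 2.0 - 1e-9:
        raise ValueError(
            f"voxel_size {voxel_size} too coarse to resolve the "
            f"{tumor_thickness * 1e3:g} mm tumor thickness (< 2 voxels)"
        )

    vx = voxel_size
    r_t = math.sqrt(tumor_area / math.pi)
    half = tumor_thickness / 2.0
    shells = skull_thickness + scalp_thickness
    a1, b1, c1 = brain_semiaxes
    skull_semi = (a1 + skull_thickness, b1 + skull_thickness, c1 + skull_thickness)
    scalp_semi = (a1 + shells, b1 + shells, c1 + shells)
    apex_z = -half + embed_depth
    center = np.array([0.0, 0.0, apex_z - scalp_semi[2]])
    head_bottom = center[2] - scalp_semi[2]
    z_bottom = head_bottom - stub_length

    half_xy = max(r_t, scalp_semi[0], stub_radius) + margin_voxels * vx
    n_half = math.ceil(half_xy / vx)
    xs = vx * np.arange(-n_half, n_half + 1) + grid_offset[0]
    ys = vx * np.arange(-n_half, n_half + 1) + grid_offset[1]
    # Align the z grid so the tumor slab [-half, half] is captured by exactly
    # round(thickness / vx) voxel layers symmetric about z = 0: for an even
    # layer count the slab is centered on a voxel *face*, so the grid is
    # shifted by half a voxel.
    n_lay = max(int(round(tumor_thickness / vx)), 1)
    z_align = 0.5 * vx if n_lay % 2 == 0 else 0.0
    n_up = math.ceil((half + margin_voxels * vx) / vx)
    n_down = math.ceil((z_align - z_bottom) / vx - 0.5)
    zs = vx * np.arange(-n_down, n_up + 1) + z_align + grid_offset[2]

    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]

    names = ("air", "torso", "scalp", "skull", "brain tissue", "mixed tissue")
    labels = np.zeros((xs.size, ys.size, zs.size), dtype=np.uint8)

    r2d = X**2 + Y**2
    stub = (r2d <= stub_radius**2) & (Z <= center[2])
    labels[np.broadcast_to(stub, labels.shape)] = names.index("torso")

    def ellipsoid(semi):
        a, b, c = semi
        return ((X - center[0]) / a) ** 2 + ((Y - center[1]) / b) ** 2 + (
            (Z - center[2]) / c
        ) ** 2 <= 1.0

    labels[ellipsoid(scalp_semi)] = names.index("scalp")
    labels[ellipsoid(skull_semi)] = names.index("skull")
    labels[ellipsoid(brain_semiaxes)] = names.index("brain tissue")

    tumor = (r2d <= r_t**2) & (np.abs(Z) <= half - 0.25 * vx)
    labels[np.broadcast_to(tumor, labels.shape)] = names.index("mixed tissue")

    origin = np.array([xs[0], ys[0], zs[0]])
    return VoxelPhantom(labels=labels, voxel_size=vx, origin=origin, tissue_names=names)
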