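"""Quasi-static induced electric field and current density in tissue.

At 100 kHz the displacement current is negligible, so on a circular path of
radius r concentric with the coil axis, Faraday's law with a uniform axial
flux-density amplitude B gives the induced-field amplitude

    E = π f B r        (from E·2πr = 2πf · B·πr²),

and Ohm's law in an isotropic conductor gives J = σE.  These are bounded
analytic estimates on idealized circular paths — not solutions of the full
eddy-current problem in heterogeneous anatomy — and are reported as
order-of-magnitude exposure references only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mihsim.phantom import AIR, TissueProperties, TissueRegistry, VoxelPhantom

__all__ = ["induced_e_circular_path", "current_density", "exposure_report",
           "EXPOSURE_REPORT_NOTE"]

EXPOSURE_REPORT_NOTE = (
    "Quasi-static circular-path bounds (E = pi f B r at each region's maximal "
    "radius about the coil axis); not a finite-element eddy-current solution."
)


def induced_e_circular_path(frequency: float, flux_density: float, radius: float):
    """Induced electric-field amplitude E = π f B r (V/m) on a circular path
    of radius r around the coil axis, for uniform axial amplitude B."""
    if frequency < 0 or flux_density < 0:
        raise ValueError("frequency and flux density must be >= 0")
    r = np.asarray(radius, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be >= 0")
    out = np.pi * frequency * flux_density * r
    return float(out) if out.ndim == 0 else out


def current_density(e_field: float, tissue: TissueProperties):
    """Conduction current density J = σE (A/m²) from the tissue's tabulated
    conductivity."""
    e = np.asarray(e_field, dtype=float)
    if np.any(e < 0):
        raise ValueError("E must be >= 0")
    if tissue.conductivity is None:
        raise KeyError(f"tissue {tissue.name!r} has no tabulated conductivity")
    out = tissue.conductivity * e
    return float(out) if out.ndim == 0 else out


def exposure_report(
    phantom: VoxelPhantom,
    registry: TissueRegistry,
    flux_density: float,
    frequency: float,
) -> pd.DataFrame:
    """Per-tissue exposure estimates over the phantom.

    For each labeled tissue the effective loop radius is the region's
    maximal in-plane radius about the coil axis (x), which makes the E
    estimate an upper-bound flavor.  Columns: tissue, r_eff_m, E_V_per_m,
    J_A_per_m2.  Estimates scale linearly with B (hence drive current).
    """
    xs, ys, zs = phantom.axes()
    rows = []
    for name in phantom.tissue_names:
        if name == AIR:
            continue
        mask = phantom.region_mask(name)
        if not mask.any():
            continue
        _, jj, kk = np.nonzero(mask)
        r_eff = float(np.max(np.hypot(ys[jj], zs[kk])))
        tissue = registry.resolved(name)
        e = induced_e_circular_path(frequency, flux_density, r_eff)
        rows.append(
            {
                "tissue": name,
                "r_eff_m": r_eff,
                "E_V_per_m": e,
                "J_A_per_m2": current_density(e, tissue),
            }
        )
    return pd.DataFrame(rows, columns=["tissue", "r_eff_m", "E_V_per_m", "J_A_per_m2"])
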