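"""Relaxation-loss heating power of superparamagnetic nanoparticles.

A magnetic fluid in an alternating field H(t) = H₀ sin(2πft) dissipates
power because its magnetization lags the field (Néel and Brownian
relaxation, combined into an effective time τ_eff).  The volumetric loss
power follows the Rosensweig model

    P₀ = π μ₀ χ₀ H₀² f · (2πf τ_eff) / (1 + (2πf τ_eff)²)   [W/m³],

with the equilibrium susceptibility χ₀ = χ_i · 3 L(ξ)/ξ, the Langevin
function L(ξ) = coth ξ − 1/ξ, Langevin parameter ξ = μ₀ M_d H₀ V / (k_B T)
and initial susceptibility χ_i = μ₀ φ M_d² V / (3 k_B T).

The tumor heat source applied in the bioheat stage is α·P₀ with correction
factor α = 0.55, spread uniformly over the lesion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from mihsim.constants import K_B, MU0

__all__ = [
    "NanoparticleSpec",
    "PowerResult",
    "langevin",
    "langevin_parameter",
    "initial_susceptibility",
    "equilibrium_susceptibility",
    "relaxation_loss_power",
    "effective_relaxation_time",
    "calibrate_tau_eff",
    "magnetite_spec",
    "heat_source_density",
]

# Below this ξ the Taylor series ξ/3 − ξ³/45 is used for L(ξ); the series'
# next term is ξ⁵·2/945, i.e. relative error < 1e-10 at the crossover.
_LANGEVIN_SERIES_CUTOFF = 1.0e-2


@dataclass(frozen=True)
class NanoparticleSpec:
    """Magnetic-fluid physics: domain magnetization M_d (A/m), single-particle
    volume V (m³), volume fraction φ, temperature T (K) and effective
    relaxation time τ_eff (s)."""

    domain_magnetization: float
    particle_volume: float
    volume_fraction: float
    temperature: float = 310.15
    tau_eff: float | None = None

    def __post_init__(self) -> None:
        if self.domain_magnetization <= 0 or self.particle_volume <= 0:
            raise ValueError("M_d and particle volume must be > 0")
        if not 0 < self.volume_fraction <= 1:
            raise ValueError("volume_fraction must be in (0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.tau_eff is not None and self.tau_eff <= 0:
            raise ValueError("tau_eff must be > 0 s")

    @classmethod
    def from_diameter(
        cls,
        domain_magnetization: float,
        diameter: float,
        volume_fraction: float,
        temperature: float = 310.15,
        tau_eff: float | None = None,
    ) -> "NanoparticleSpec":
        """Spherical particle of the given diameter (m): V = π d³ / 6."""
        return cls(
            domain_magnetization=domain_magnetization,
            particle_volume=math.pi * diameter**3 / 6.0,
            volume_fraction=volume_fraction,
            temperature=temperature,
            tau_eff=tau_eff,
        )


@dataclass(frozen=True)
class PowerResult:
    """Loss-power evaluation at one working point (H₀, f)."""

    langevin_parameter: float
    chi_initial: float
    chi_equilibrium: float
    loss_power: float
    applied_field: float
    frequency: float
    tau_eff: float


def langevin(xi):
    """Langevin function L(ξ) = coth ξ − 1/ξ, with the removable singularity
    at ξ = 0 handled by its Taylor series."""
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0):
        raise ValueError("Langevin parameter must be >= 0")
    small = xi < _LANGEVIN_SERIES_CUTOFF
    safe = np.where(small, 1.0, xi)
    exact = 1.0 / np.tanh(safe) - 1.0 / safe
    series = xi / 3.0 - xi**3 / 45.0
    out = np.where(small, series, exact)
    return float(out) if out.ndim == 0 else out


def langevin_parameter(spec: NanoparticleSpec, applied_field: float) -> float:
    """ξ = μ₀ M_d H₀ V / (k_B T) — magnetic vs. thermal energy."""
    if applied_field < 0:
        raise ValueError("applied field must be >= 0")
    return (
        MU0
        * spec.domain_magnetization
        * applied_field
        * spec.particle_volume
        / (K_B * spec.temperature)
    )


def initial_susceptibility(spec: NanoparticleSpec) -> float:
    """χ_i = μ₀ φ M_d² V / (3 k_B T)."""
    return (
        MU0
        * spec.volume_fraction
        * spec.domain_magnetization**2
        * spec.particle_volume
        / (3.0 * K_B * spec.temperature)
    )


def equilibrium_susceptibility(spec: NanoparticleSpec, applied_field: float) -> float:
    """χ₀ = χ_i · 3 L(ξ)/ξ;  χ₀ → χ_i as H₀ → 0 and decreases with field
    (Langevin saturation)."""
    chi_i = initial_susceptibility(spec)
    xi = langevin_parameter(spec, applied_field)
    if xi < _LANGEVIN_SERIES_CUTOFF:
        # 3 L(ξ)/ξ = 1 − ξ²/15 + O(ξ⁴)
        return chi_i * (1.0 - xi**2 / 15.0)
    return chi_i * 3.0 * langevin(xi) / xi


def relaxation_loss_power(
    spec: NanoparticleSpec, applied_field: float, frequency: float
) -> PowerResult:
    """Volumetric loss power of the fluid at peak field H₀ and frequency f."""
    if applied_field < 0 or frequency < 0:
        raise ValueError("applied field and frequency must be >= 0")
    if spec.tau_eff is None:
        raise ValueError("spec.tau_eff is unset; provide it or calibrate it")
    chi0 = equilibrium_susceptibility(spec, applied_field)
    x = 2.0 * math.pi * frequency * spec.tau_eff
    p0 = math.pi * MU0 * chi0 * applied_field**2 * frequency * x / (1.0 + x**2)
    return PowerResult(
        langevin_parameter=langevin_parameter(spec, applied_field),
        chi_initial=initial_susceptibility(spec),
        chi_equilibrium=chi0,
        loss_power=p0,
        applied_field=applied_field,
        frequency=frequency,
        tau_eff=spec.tau_eff,
    )


def effective_relaxation_time(neel_time: float, brown_time: float) -> float:
    """Harmonic combination 1/τ_eff = 1/τ_N + 1/τ_B of the two channels."""
    if neel_time <= 0 or brown_time <= 0:
        raise ValueError("relaxation times must be > 0")
    return 1.0 / (1.0 / neel_time + 1.0 / brown_time)


def calibrate_tau_eff(
    spec: NanoparticleSpec,
    applied_field: float,
    frequency: float,
    target_power: float,
    branch: str = "fast",
) -> NanoparticleSpec:
    """Solve τ_eff so that the loss power at (H₀, f) equals ``target_power``.

    P₀(τ) ∝ x/(1+x²) with x = 2πfτ peaks at x = 1, so any attainable target
    has two roots; ``branch='fast'`` picks the sub-peak (shorter, Néel-like)
    time, ``'slow'`` the super-peak one.
    """
    if target_power <= 0:
        raise ValueError("target power must be > 0")
    chi0 = equilibrium_susceptibility(spec, applied_field)
    scale = math.pi * MU0 * chi0 * applied_field**2 * frequency
    y = target_power / scale  # = x/(1+x²), max 1/2
    if y > 0.5:
        raise ValueError(
            f"target {target_power:g} W/m³ exceeds the peak attainable "
            f"{0.5 * scale:g} W/m³ at this working point"
        )
    disc = math.sqrt(1.0 - 4.0 * y * y)
    if branch == "fast":
        x = (1.0 - disc) / (2.0 * y)
    elif branch == "slow":
        x = (1.0 + disc) / (2.0 * y)
    else:
        raise ValueError("branch must be 'fast' or 'slow'")
    return replace(spec, tau_eff=x / (2.0 * math.pi * frequency))


def magnetite_spec(
    *,
    domain_magnetization: float = 446.0e3,
    diameter: float = 19.0e-9,
    volume_fraction: float = 0.003,
    temperature: float = 310.15,
    calibrate_to_power: float | None = 673920.0,
    calibration_field: float = 6814.2,
    calibration_frequency: float = 100.0e3,
) -> NanoparticleSpec:
    """Default magnetite fluid of the study conditions.

    19 nm single-domain magnetite (M_d = 446 kA/m) at body temperature and
    φ = 0.003, with τ_eff solved on the fast branch so the loss power at the
    working point (6814.2 A/m, 100 kHz) equals 673,920 W/m³.  Pass
    ``calibrate_to_power=None`` for a manual spec with τ_eff unset.
    """
    spec = NanoparticleSpec.from_diameter(
        domain_magnetization, diameter, volume_fraction, temperature
    )
    if calibrate_to_power is None:
        return spec
    return calibrate_tau_eff(
        spec, calibration_field, calibration_frequency, calibrate_to_power
    )


def heat_source_density(loss_power: float, alpha: float = 0.55) -> float:
    """Tumor heat-source density α·P₀ (W/m³), with correction factor
    α ∈ [0, 1] applied to the nanoparticle loss power only."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    return alpha * loss_power
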