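"""Finite-volume Pennes bioheat solver on the voxel phantom.

Each tissue voxel obeys

    ρc ∂T/∂t = ∇·(k∇T) + ρ_b C_b ω_b (T_b − T) + Q_m + q_source,

i.e. conduction, a blood-perfusion heat *sink* pulling tissue toward the
arterial temperature T_b, metabolic heat, and the nanoparticle source
(α·P₀ inside the tumor).  The spatial stencil uses harmonic-mean face
conductivities across tissue interfaces, so heat flux is continuous through
material jumps.  Air voxels are excluded from the solve; tissue–air faces
default to thermal insulation (a convective Robin condition is available),
and tissue faces on the domain boundary — the body-stub base — are held at
the arterial/core temperature.

Time integration is implicit (backward Euler, unconditionally stable;
matrix factorized once per time step size) or explicit with an enforced
stability bound dt ≤ min ρc Δx²/(6k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from mihsim.phantom import AIR, TissueRegistry, VoxelPhantom

__all__ = [
    "BioheatParams",
    "ThermalState",
    "PennesOperator",
    "SimulationResult",
    "assemble_coefficients",
    "step",
    "simulate",
    "stability_limit",
]

# Above this many unknowns the implicit solve switches from a cached sparse
# LU factorization to conjugate gradients (the system is SPD).
_DIRECT_SOLVER_LIMIT = 150_000


@dataclass(frozen=True)
class BioheatParams:
    """Solver settings and blood properties.

    Blood density/specific heat are not tabulated in the source data;
    defaults are a tumor-like blood surrogate (1060 kg/m³, 3650 J/(kg·K)).
    ``surface_bc`` applies to tissue–air faces: "insulated" (default) or
    "convective" with film coefficient ``h_W_m2K`` toward ``ambient_C``.
    Tissue faces on the domain boundary are fixed at ``far_boundary_C``.
    """

    blood_density: float = 1060.0
    blood_specific_heat: float = 3650.0
    blood_temperature_C: float = 37.0
    duration_s: float = 300.0
    dt_s: float = 1.0
    initial_temperature_C: float = 37.0
    scheme: str = "implicit"
    surface_bc: str = "insulated"
    h_W_m2K: float = 10.0
    ambient_C: float = 25.0
    far_boundary_C: float = 37.0
    output_every_s: float = 5.0

    def __post_init__(self) -> None:
        if self.duration_s < 0 or self.dt_s <= 0:
            raise ValueError("need duration >= 0 and dt > 0")
        if self.blood_density <= 0 or self.blood_specific_heat <= 0:
            raise ValueError("blood density and specific heat must be > 0")
        if self.scheme not in ("implicit", "explicit"):
            raise ValueError("scheme must be 'implicit' or 'explicit'")
        if self.surface_bc not in ("insulated", "convective"):
            raise ValueError("surface_bc must be 'insulated' or 'convective'")


@dataclass
class ThermalState:
    """Temperature snapshot (°C) on the full grid; air voxels are NaN."""

    temperature: np.ndarray
    time: float


class PennesOperator:
    """Assembled spatial operator:  C dT/dt = −M T + r  on tissue voxels."""

    def __init__(self, phantom, params, M, capacity, load, tissue_index, index_grid):
        self.phantom = phantom
        self.params = params
        self.M = M.tocsr()
        self.capacity = capacity  # ρc per unknown, J/(m³·K)
        self.load = load  # constant source term, W/m³
        self.tissue_index = tissue_index  # label id per unknown
        self.index_grid = index_grid  # (nx,ny,nz) int, −1 in air
        self.n = capacity.size
        self._solvers: dict[float, object] = {}

    # -- vector/grid conversion ------------------------------------------
    def to_grid(self, T: np.ndarray, time: float = 0.0) -> ThermalState:
        grid = np.full(self.index_grid.shape, np.nan)
        grid[self.index_grid >= 0] = T
        return ThermalState(temperature=grid, time=time)

    def uniform_vector(self, value: float) -> np.ndarray:
        return np.full(self.n, float(value))

    def total_enthalpy(self, T: np.ndarray) -> float:
        """Σ ρc·T per voxel volume (J), for conservation diagnostics."""
        return float(np.sum(self.capacity * T) * self.phantom.voxel_volume)

    # -- stability --------------------------------------------------------
    def stability_detail(self) -> tuple[float, str]:
        dx = self.phantom.voxel_size
        k = self._k_per_unknown
        dt = self.capacity * dx**2 / (6.0 * k)
        i = int(np.argmin(dt))
        return float(dt[i]), self.phantom.tissue_names[self.tissue_index[i]]

    # -- stepping ---------------------------------------------------------
    def step_implicit(self, T: np.ndarray, dt: float) -> np.ndarray:
        solver = self._solvers.get(dt)
        if solver is None:
            A = sp.diags(self.capacity / dt) + self.M
            if self.n <= _DIRECT_SOLVER_LIMIT:
                lu = spla.splu(A.tocsc())
                solver = ("direct", lu)
            else:
                precond = sp.diags(1.0 / A.diagonal())
                solver = ("cg", A.tocsr(), precond)
            self._solvers[dt] = solver
        b = self.capacity / dt * T + self.load
        if solver[0] == "direct":
            return solver[1].solve(b)
        _, A, precond = solver
        x, info = spla.cg(A, b, x0=T, rtol=1e-10, atol=0.0, M=precond)
        if info != 0:
            raise RuntimeError(f"CG failed to converge (info={info})")
        return x

    def step_explicit(self, T: np.ndarray, dt: float) -> np.ndarray:
        dt_max, tissue = self.stability_detail()
        if dt > dt_max * (1.0 + 1e-12):
            raise ValueError(
                f"explicit dt={dt:g} s violates the stability bound "
                f"{dt_max:g} s set by {tissue!r} voxels"
            )
        return T + dt / self.capacity * (self.load - self.M @ T)


def assemble_coefficients(
    phantom: VoxelPhantom,
    params: BioheatParams,
    source: np.ndarray | None = None,
    registry: TissueRegistry | None = None,
) -> PennesOperator:
    """Build the solver-ready operator for one phantom + parameter set.

    ``source`` is a full-grid volumetric heat source (W/m³, nonnegative);
    ``None`` means no external source.  Raises if any non-air voxel lacks
    tabulated (or fallback-resolved) thermal properties.
    """
    if registry is None:
        registry = TissueRegistry.from_csv()
    labels = phantom.labels
    shape = labels.shape
    dx = phantom.voxel_size

    n_labels = len(phantom.tissue_names)
    rho = np.full(n_labels, np.nan)
    c = np.full(n_labels, np.nan)
    k = np.full(n_labels, np.nan)
    omega = np.full(n_labels, np.nan)
    qm = np.full(n_labels, np.nan)
    present = np.bincount(labels.ravel(), minlength=n_labels) > 0
    for li, name in enumerate(phantom.tissue_names):
        if name == AIR or not present[li]:
            continue
        t = registry.resolved(name)
        vals = (
            t.density,
            t.specific_heat,
            t.thermal_conductivity,
            t.perfusion_rate,
            t.metabolic_heat,
        )
        if any(v is None for v in vals):
            raise ValueError(f"tissue {name!r} lacks thermal properties")
        rho[li], c[li], k[li], omega[li], qm[li] = vals

    try:
        air_label = phantom.tissue_names.index(AIR)
        tissue_mask = labels != air_label
    except ValueError:
        tissue_mask = np.ones(shape, dtype=bool)
    n = int(tissue_mask.sum())
    if n == 0:
        raise ValueError("phantom contains no tissue voxels")

    index_grid = np.full(shape, -1, dtype=np.int64)
    index_grid[tissue_mask] = np.arange(n)
    tissue_index = labels[tissue_mask].astype(np.int64)

    k_vox = k[labels]  # NaN in air
    k_flat = k_vox[tissue_mask]

    capacity = (rho * c)[labels][tissue_mask]
    g_perf = (
        params.blood_density * params.blood_specific_heat * omega[labels][tissue_mask]
    )
    load = qm[labels][tissue_mask] + g_perf * params.blood_temperature_C
    if source is not None:
        source = np.asarray(source, dtype=float)
        if source.shape != shape:
            raise ValueError("source grid shape does not match the phantom")
        if np.any(source < 0):
            raise ValueError("source grid must be nonnegative")
        load = load + source[tissue_mask]
    diag = g_perf.copy()

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    if params.surface_bc == "convective":
        # series of half-cell conduction and the film resistance, per face
        u_surface = 1.0 / (dx / (2.0 * k_flat) + 1.0 / params.h_W_m2K) / dx
    else:
        u_surface = np.zeros(n)
    u_far = 2.0 * k_flat / dx**2  # half-cell conduction to the fixed face

    def lo_slice(axis):
        sl = [slice(None)] * 3
        sl[axis] = slice(None, -1)
        return tuple(sl)

    def hi_slice(axis):
        sl = [slice(None)] * 3
        sl[axis] = slice(1, None)
        return tuple(sl)

    for axis in range(3):
        a = index_grid[lo_slice(axis)].ravel()
        b = index_grid[hi_slice(axis)].ravel()
        ka = k_vox[lo_slice(axis)].ravel()
        kb = k_vox[hi_slice(axis)].ravel()

        both = (a >= 0) & (b >= 0)
        g = np.zeros(a.shape)
        g[both] = 2.0 * ka[both] * kb[both] / (ka[both] + kb[both]) / dx**2
        ia, ib, gv = a[both], b[both], g[both]
        rows += [ia, ib, ia, ib]
        cols += [ib, ia, ia, ib]
        vals += [-gv, -gv, gv, gv]

        # tissue face against an air voxel -> surface condition
        for t_idx in (a[(a >= 0) & (b < 0)], b[(b >= 0) & (a < 0)]):
            if t_idx.size:
                diag_add = u_surface[t_idx]
                np.add.at(diag, t_idx, diag_add)
                np.add.at(load, t_idx, diag_add * params.ambient_C)

        # tissue face on the domain boundary -> fixed far-field temperature
        for edge in (index_grid.take(0, axis=axis), index_grid.take(-1, axis=axis)):
            t_idx = edge.ravel()
            t_idx = t_idx[t_idx >= 0]
            if t_idx.size:
                np.add.at(diag, t_idx, u_far[t_idx])
                np.add.at(load, t_idx, u_far[t_idx] * params.far_boundary_C)

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    M = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    op = PennesOperator(phantom, params, M, capacity, load, tissue_index, index_grid)
    op._k_per_unknown = k_flat
    return op


def step(op: PennesOperator, T: np.ndarray, dt: float, scheme: str | None = None):
    """Advance the temperature vector by one time step."""
    scheme = scheme or op.params.scheme
    if scheme == "implicit":
        return op.step_implicit(T, dt)
    if scheme == "explicit":
        return op.step_explicit(T, dt)
    raise ValueError(f"unknown scheme {scheme!r}")


def stability_limit(
    phantom: VoxelPhantom,
    params: BioheatParams | None = None,
    registry: TissueRegistry | None = None,
) -> float:
    """Largest explicit-stable time step, min over voxels of ρc Δx²/(6k)."""
    op = assemble_coefficients(phantom, params or BioheatParams(), None, registry)
    return op.stability_detail()[0]


@dataclass
class SimulationResult:
    """Output of :func:`simulate`: probe series, snapshots and final state."""

    times: np.ndarray
    probe_series: "pd.DataFrame"  # noqa: F821 - imported lazily
    final_state: ThermalState
    snapshots: dict[float, np.ndarray] = field(default_factory=dict)
    operator: PennesOperator | None = None

    def probe_curve(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        return self.times, self.probe_series[name].to_numpy()


def simulate(
    phantom: VoxelPhantom,
    params: BioheatParams,
    source: np.ndarray | None = None,
    probes: dict | None = None,
    snapshot_times: tuple[float, ...] = (),
    registry: TissueRegistry | None = None,
) -> SimulationResult:
    """Run the bioheat solve from a uniform start for ``params.duration_s``.

    ``probes`` maps names to physical points (m); each must lie in a tissue
    voxel.  Probe temperatures are recorded at t = 0 and every
    ``params.output_every_s`` (and at the final time).  ``snapshot_times``
    requests full temperature grids at the nearest recorded instants.
    """
    import pandas as pd

    op = assemble_coefficients(phantom, params, source, registry)

    probe_idx: dict[str, int] = {}
    for name, point in (probes or {}).items():
        ijk = phantom.point_to_index(point)
        flat = op.index_grid[ijk]
        if flat < 0:
            raise ValueError(f"probe {name!r} at {point} lies in an air voxel")
        probe_idx[name] = int(flat)

    T = op.uniform_vector(params.initial_temperature_C)
    duration, dt = params.duration_s, params.dt_s
    n_steps = max(int(round(duration / dt)), 1) if duration > 0 else 0
    dt = duration / n_steps if n_steps else dt
    record_every = max(int(round(params.output_every_s / dt)), 1) if n_steps else 1

    times = [0.0]
    records = {name: [T[i]] for name, i in probe_idx.items()}
    snapshots: dict[float, np.ndarray] = {}
    want_snap = sorted(set(float(t) for t in snapshot_times))
    if want_snap and want_snap[0] <= 0.0:
        snapshots[0.0] = op.to_grid(T, 0.0).temperature
        want_snap = [t for t in want_snap if t > 0.0]

    for istep in range(1, n_steps + 1):
        T = step(op, T, dt)
        t_now = istep * dt
        if istep % record_every == 0 or istep == n_steps:
            times.append(t_now)
            for name, i in probe_idx.items():
                records[name].append(T[i])
        while want_snap and t_now >= want_snap[0] - 0.5 * dt:
            snapshots[want_snap.pop(0)] = op.to_grid(T, t_now).temperature

    times_arr = np.asarray(times)
    frame = pd.DataFrame({"time_s": times_arr, **{k: np.asarray(v) for k, v in records.items()}})
    final = op.to_grid(T, duration)
    if not snapshots or duration not in snapshots:
        snapshots[duration] = final.temperature
    return SimulationResult(
        times=times_arr,
        probe_series=frame,
        final_state=final,
        snapshots=snapshots,
        operator=op,
    )
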