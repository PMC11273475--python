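"""Pennes solver: assembly coefficients, oracles, stability and invariants."""

import math

import numpy as np
import pytest

from mihsim.bioheat import (
    BioheatParams,
    assemble_coefficients,
    simulate,
    stability_limit,
    step,
)
from mihsim.phantom import VoxelPhantom

from conftest import make_block_phantom


def perfused_block_oracle(t, q_source, registry, tissue="mixed tissue",
                          blood_rho=1060.0, blood_c=3650.0, t_blood=37.0):
    """Closed-form solution of the lumped perfused-block ODE
    ρc dT/dt = q + Q_m + ρ_b C_b ω_b (T_b − T), from T(0) = T_b."""
    props = registry.resolved(tissue)
    g = blood_rho * blood_c * props.perfusion_rate
    dT = (q_source + props.metabolic_heat) / g
    tau = props.density * props.specific_heat / g
    return t_blood + dT * (1.0 - math.exp(-t / tau))


def two_tissue_phantom():
    """Small skull/brain block with an air margin (insulated surfaces)."""
    labels = np.zeros((12, 10, 10), dtype=np.uint8)
    labels[1:6, 1:9, 1:9] = 1  # skull
    labels[6:11, 1:9, 1:9] = 2  # brain
    vx = 0.5e-3
    return VoxelPhantom(
        labels=labels,
        voxel_size=vx,
        origin=-0.5 * vx * (np.array(labels.shape) - 1),
        tissue_names=("air", "skull", "brain tissue"),
    )


class TestAssembly:
    def test_homogeneous_faces_share_one_conductivity(self, registry):
        ph = make_block_phantom(shape=(3, 3, 3), tissue="skull")
        op = assemble_coefficients(ph, BioheatParams(), None, registry)
        M = op.M.tocoo()
        off = M.data[M.row != M.col]
        g = 0.32 / ph.voxel_size**2
        assert np.allclose(off, -g)

    def test_interface_face_uses_harmonic_mean(self, registry):
        ph = two_tissue_phantom()
        op = assemble_coefficients(ph, BioheatParams(), None, registry)
        i = op.index_grid[5, 4, 4]  # skull voxel
        j = op.index_grid[6, 4, 4]  # brain neighbor
        g = -op.M[i, j] * ph.voxel_size**2
        expected = 2 * 0.32 * 0.515 / (0.32 + 0.515)
        assert g == pytest.approx(expected, rel=1e-12)
        assert round(expected, 4) == 0.3947

    def test_zero_perfusion_tissue_has_no_sink(self, registry):
        ph = make_block_phantom(shape=(3, 3, 3), tissue="magnetic nanofluids")
        op = assemble_coefficients(ph, BioheatParams(), None, registry)
        # insulated surfaces + ω_b = 0 -> zero row sums (pure conduction)
        row_sums = np.asarray(op.M.sum(axis=1)).ravel()
        assert np.allclose(row_sums, 0.0, atol=1e-6)

    def test_negative_source_rejected(self, registry):
        ph = make_block_phantom(shape=(3, 3, 3))
        src = np.full(ph.grid_shape, -1.0)
        with pytest.raises(ValueError):
            assemble_coefficients(ph, BioheatParams(), src, registry)


class TestStepping:
    def test_uniform_equilibrium_is_stationary(self, registry):
        ph = make_block_phantom(shape=(4, 4, 4), tissue="magnetic nanofluids")
        op = assemble_coefficients(ph, BioheatParams(), None, registry)
        T = op.uniform_vector(37.0)
        for scheme in ("implicit", "explicit"):
            T1 = step(op, T, 0.01, scheme)  # nanofluid k=40 bounds explicit dt
            assert np.allclose(T1, 37.0, atol=1e-10)

    def test_single_implicit_step_second_order_local_error(self, registry):
        ph = make_block_phantom(shape=(4, 4, 4))
        src = np.zeros(ph.grid_shape)
        src[ph.labels == 1] = 370656.0
        op = assemble_coefficients(ph, BioheatParams(), src, registry)
        errs = []
        for dt in (2.0, 1.0):
            T1 = op.step_implicit(op.uniform_vector(37.0), dt)
            exact = perfused_block_oracle(dt, 370656.0, registry)
            errs.append(abs(T1[0] - exact))
        assert 3.0 < errs[0] / errs[1] < 5.0

    def test_doubling_source_doubles_elevation(self, registry):
        ph = make_block_phantom(shape=(4, 4, 4))
        base = np.zeros(ph.grid_shape)
        base[ph.labels == 1] = 1e5
        params = BioheatParams(duration_s=50.0, dt_s=1.0)
        r0 = simulate(ph, params, None, probes={"c": (0, 0, 0)}, registry=registry)
        r1 = simulate(ph, params, base, probes={"c": (0, 0, 0)}, registry=registry)
        r2 = simulate(ph, params, 2 * base, probes={"c": (0, 0, 0)}, registry=registry)
        t0 = r0.probe_series["c"].iloc[-1]
        t1 = r1.probe_series["c"].iloc[-1]
        t2 = r2.probe_series["c"].iloc[-1]
        assert (t2 - t0) == pytest.approx(2 * (t1 - t0), rel=1e-8)

    def test_explicit_stability_guard_names_tissue(self, registry):
        ph = make_block_phantom(shape=(4, 4, 4), tissue="mixed tissue")
        op = assemble_coefficients(ph, BioheatParams(), None, registry)
        dt_max, tissue = op.stability_detail()
        props = registry.resolved("mixed tissue")
        expected = (
            props.density * props.specific_heat * ph.voxel_size**2
            / (6 * props.thermal_conductivity)
        )
        assert dt_max == pytest.approx(expected, rel=1e-12)
        assert dt_max == pytest.approx(0.307, abs=5e-4)
        with pytest.raises(ValueError, match="mixed tissue"):
            op.step_explicit(op.uniform_vector(37.0), 2 * dt_max)

    def test_stability_limit_quarter_scaling(self, registry):
        fine = make_block_phantom(shape=(4, 4, 4), voxel_size=0.25e-3)
        coarse = make_block_phantom(shape=(4, 4, 4), voxel_size=0.5e-3)
        assert stability_limit(fine, registry=registry) == pytest.approx(
            stability_limit(coarse, registry=registry) / 4.0, rel=1e-12
        )


class TestOracles:
    def test_perfused_block_follows_scalar_ode(self, registry):
        """Uniform insulated perfused block with uniform source: every voxel
        must track T_b + ΔT_ss (1 − e^{−t/τ}) with ΔT_ss = (q+Q_m)/(ρ_b C_b ω_b)."""
        ph = make_block_phantom(shape=(6, 6, 6))
        q = 370656.0
        src = np.zeros(ph.grid_shape)
        src[ph.labels == 1] = q
        params = BioheatParams(duration_s=300.0, dt_s=1.0)
        res = simulate(ph, params, src, probes={"c": (0, 0, 0)}, registry=registry)
        for t_check in (100.0, 300.0):
            i = int(np.argmin(np.abs(res.times - t_check)))
            exact = perfused_block_oracle(res.times[i], q, registry)
            assert res.probe_series["c"].iloc[i] == pytest.approx(
                exact, abs=0.005 * (exact - 37.0)
            )
        T = res.final_state.temperature
        interior = T[~np.isnan(T)]
        assert np.ptp(interior) < 1e-8  # uniform problem stays uniform

    def test_energy_conservation_without_sinks(self, registry):
        ph = make_block_phantom(shape=(6, 6, 6), tissue="magnetic nanofluids")
        op = assemble_coefficients(ph, BioheatParams(), None, registry)
        rng = np.random.default_rng(7)
        T = 37.0 + rng.uniform(-2.0, 2.0, op.n)
        e0 = op.total_enthalpy(T)
        for _ in range(25):
            T = op.step_implicit(T, 0.5)
        assert op.total_enthalpy(T) == pytest.approx(e0, rel=1e-9)

    def test_enthalpy_growth_matches_source_power(self, registry):
        ph = make_block_phantom(shape=(6, 6, 6), tissue="magnetic nanofluids")
        q = 2.5e5
        src = np.zeros(ph.grid_shape)
        src[ph.labels == 1] = q
        op = assemble_coefficients(ph, BioheatParams(), src, registry)
        T = op.uniform_vector(37.0)
        n_steps, dt = 40, 0.5
        e0 = op.total_enthalpy(T)
        for _ in range(n_steps):
            T = op.step_implicit(T, dt)
        v_region = ph.tissue_volume("magnetic nanofluids")
        expected = q * v_region * n_steps * dt
        assert op.total_enthalpy(T) - e0 == pytest.approx(expected, rel=1e-9)

    def test_maximum_principle(self, registry):
        ph = make_block_phantom(shape=(6, 6, 6), tissue="magnetic nanofluids")
        op = assemble_coefficients(ph, BioheatParams(), None, registry)
        rng = np.random.default_rng(11)
        T = 37.0 + rng.uniform(-3.0, 3.0, op.n)
        lo, hi = T.min(), T.max()
        dt_max, _ = op.stability_detail()
        for scheme, dt in (("implicit", 1.0), ("explicit", 0.9 * dt_max)):
            Ts = T.copy()
            for _ in range(30):
                Ts = step(op, Ts, dt, scheme)
                assert Ts.min() >= lo - 1e-9 and Ts.max() <= hi + 1e-9

    def test_explicit_and_implicit_schemes_agree(self, registry):
        ph = two_tissue_phantom()
        src = np.zeros(ph.grid_shape)
        src[ph.labels == 2] = 2e5
        probes = {"skull": (-2e-3, 0.0, 0.0), "brain": (2e-3, 0.0, 0.0)}
        dt = 0.05  # below the explicit bound, shared by both schemes
        common = dict(duration_s=60.0, dt_s=dt, output_every_s=10.0)
        imp = simulate(ph, BioheatParams(scheme="implicit", **common), src,
                       probes=probes, registry=registry)
        exp = simulate(ph, BioheatParams(scheme="explicit", **common), src,
                       probes=probes, registry=registry)
        for name in probes:
            diff = np.abs(
                imp.probe_series[name].to_numpy() - exp.probe_series[name].to_numpy()
            )
            assert diff.max() < 0.05


class TestSimulate:
    def test_zero_source_drift_stays_within_metabolic_band(
        self, default_phantom, registry
    ):
        """Without the nanoparticle source the Q_m/perfusion balance moves no
        tissue by more than 0.3 °C over the 300 s exposure."""
        res = simulate(
            default_phantom,
            BioheatParams(duration_s=300.0, dt_s=2.0),
            None,
            probes={
                "tumor": (0.0, 0.0, 0.0),
                "brain": (0.0, 0.0, -10e-3),
                "stub": (0.0, 0.0, -20e-3),
            },
            registry=registry,
        )
        T = res.final_state.temperature
        assert np.nanmax(np.abs(T - 37.0)) < 0.3

    def test_probe_in_air_rejected(self, registry):
        ph = make_block_phantom(shape=(4, 4, 4))
        with pytest.raises(ValueError, match="air"):
            simulate(ph, BioheatParams(duration_s=1.0), None,
                     probes={"out": (0.0, 0.0, 1.25e-3)}, registry=registry)

    def test_zero_duration_returns_initial_state(self, registry):
        ph = make_block_phantom(shape=(4, 4, 4))
        res = simulate(ph, BioheatParams(duration_s=0.0), None,
                       probes={"c": (0, 0, 0)}, registry=registry)
        assert np.nanmax(np.abs(res.final_state.temperature - 37.0)) == 0.0

    def test_convective_surface_cools_below_insulated(self, registry):
        ph = make_block_phantom(shape=(6, 6, 6), tissue="magnetic nanofluids")
        src = np.zeros(ph.grid_shape)
        src[ph.labels == 1] = 1e5
        kw = dict(duration_s=120.0, dt_s=1.0)
        warm = simulate(ph, BioheatParams(surface_bc="insulated", **kw), src,
                        probes={"c": (0, 0, 0)}, registry=registry)
        cool = simulate(ph, BioheatParams(surface_bc="convective", **kw), src,
                        probes={"c": (0, 0, 0)}, registry=registry)
        assert cool.probe_series["c"].iloc[-1] < warm.probe_series["c"].iloc[-1]
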