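"""Lattice construction, LBM invariants, sources, sampling."""

import numpy as np
import pytest

from gliaxon.fields import (
    ATTRACTANT,
    INHIBITOR,
    FieldState,
    SourceSet,
    analytic_point_source,
    build_lattice,
    lbm_step,
    receptor_ligand_fraction,
    release_rates,
    run_to_quasi_steady,
    sample_fields,
    sample_gradient,
    sample_gradients_and_concentrations,
    seed_attractant_analytic,
)
from gliaxon.geometry import ScarGeometry
from gliaxon.params import BaseConfig, resolve_parameters


@pytest.fixture
def small_params():
    # fast-decaying variant for compact test boxes
    return resolve_parameters(BaseConfig(L=1280.0, lambda_diff=320.0))


@pytest.fixture
def small_lattice():
    return build_lattice(1280.0, 40.0)


class TestReceptorLigand:
    def test_limits_and_half_saturation(self):
        assert receptor_ligand_fraction(0.0, 1e-3) == 0.0
        assert receptor_ligand_fraction(1e-3, 1e-3) == pytest.approx(0.5)
        assert receptor_ligand_fraction(1e6, 1e-3) == pytest.approx(1.0, abs=1e-8)

    def test_monotone(self):
        rho = np.linspace(0, 1, 100)
        rl = receptor_ligand_fraction(rho, 1e-3)
        assert np.all(np.diff(rl) > 0) and np.all((rl >= 0) & (rl < 1))

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            receptor_ligand_fraction(-0.1, 1e-3)


class TestReleaseRates:
    def test_competitive_partition(self):
        s20, s30, Kd = 1.8e-4, 1.8e-4, 1e-3
        for rho1 in [0.0, 0.5e-3, 1e-3, 5e-3, 1.0]:
            s2, s3 = release_rates(rho1, s20, s30, Kd)
            assert s2 / s20 + s3 / s30 == pytest.approx(1.0)
        s2, s3 = release_rates(0.0, s20, s30, Kd)
        assert (s2, s3) == (s20, 0.0)
        s2, s3 = release_rates(Kd, s20, s30, Kd)
        assert s2 == pytest.approx(s20 / 2) and s3 == pytest.approx(s30 / 2)


class TestLattice:
    def test_node_count(self):
        assert build_lattice(6720.0, 70.0).n == 96

    def test_non_integral_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_lattice(6720.0, 67.0)

    def test_degenerate_scar_empty_mask(self):
        geom = ScarGeometry(ra=0.0, rz=0.0, center=(640.0,) * 3)
        assert not build_lattice(1280.0, 40.0, geom).solid.any()

    def test_sphere_mask_volume(self):
        L, dx, R = 1280.0, 20.0, 400.0
        geom = ScarGeometry(ra=R, rz=R, center=(L / 2,) * 3)
        lat = build_lattice(L, dx, geom)
        vol = lat.solid.sum() * dx**3
        exact = 4 / 3 * np.pi * R**3
        shell = 4 * np.pi * R**2 * dx  # one-cell discretization shell
        assert abs(vol - exact) < shell


class TestAnalyticOracle:
    def test_pure_diffusion_limit(self):
        d = 123.0
        assert analytic_point_source(d, 1.0, 10.0, 0.0) == pytest.approx(
            1.0 / (4 * np.pi * 10.0 * d)
        )

    def test_decay_length_efolding(self):
        D, k = 100.0, 1e-4
        d = np.sqrt(D / k)
        ratio = analytic_point_source(d, 1.0, D, k) / analytic_point_source(d, 1.0, D, 0.0)
        assert ratio == pytest.approx(np.exp(-1))

    def test_singular_origin_rejected(self):
        with pytest.raises(ValueError):
            analytic_point_source(0.0, 1.0, 1.0, 1.0)


class TestLBMInvariants:
    def test_uniform_field_is_equilibrium(self, small_params):
        geom = ScarGeometry(ra=240.0, rz=320.0, center=(640.0,) * 3)
        lat = build_lattice(1280.0, 40.0, geom)
        st = FieldState(lat, small_params.replace(k1=0.0))
        rho = np.where(lat.solid, 0.0, 2.5)
        st.set_rho(ATTRACTANT, rho)
        src = SourceSet(targets=np.zeros((0, 3)))
        for _ in range(5):
            lbm_step(st, src, factors=(ATTRACTANT,))
        assert np.allclose(st.rho(ATTRACTANT), rho, atol=1e-13)

    def test_mass_conserved_with_obstacle_no_decay(self, small_params):
        geom = ScarGeometry(ra=240.0, rz=320.0, center=(640.0,) * 3)
        lat = build_lattice(1280.0, 40.0, geom)
        st = FieldState(lat, small_params.replace(k1=0.0, k2=0.0, k3=0.0))
        rng = np.random.default_rng(5)
        rho = np.where(lat.solid, 0.0, rng.random(lat.solid.shape))
        st.set_rho(ATTRACTANT, rho)
        m0 = st.total_mass(ATTRACTANT)
        src = SourceSet(targets=np.zeros((0, 3)))
        for _ in range(1000):
            lbm_step(st, src, factors=(ATTRACTANT,))
        assert abs(st.total_mass(ATTRACTANT) - m0) / m0 < 1e-12
        assert st.rho(ATTRACTANT).min() >= 0.0

    def test_decay_only_geometric_law(self, small_params, small_lattice):
        st = FieldState(small_lattice, small_params)
        rng = np.random.default_rng(6)
        st.set_rho(ATTRACTANT, rng.random(small_lattice.solid.shape))
        m0 = st.total_mass(ATTRACTANT)
        src = SourceSet(targets=np.zeros((0, 3)))
        n = 200
        for _ in range(n):
            lbm_step(st, src, factors=(ATTRACTANT,))
        expected = m0 * (1.0 - small_params.k1 * st.dt) ** n
        assert st.total_mass(ATTRACTANT) == pytest.approx(expected, rel=1e-12)

    def test_unstable_relaxation_rejected(self, small_lattice):
        params = resolve_parameters(BaseConfig(L=1280.0, ratio_D=50.0))
        with pytest.raises(ValueError, match="relaxation"):
            # dt sized for D1 makes the slow factors' tau valid, but an
            # explicit oversized dt must be rejected
            FieldState(small_lattice, params, dt=1e4)

    def test_source_mass_balance(self, small_params, small_lattice):
        # steady total mass of a decaying field with constant source is Q/k
        st = FieldState(small_lattice, small_params)
        src = SourceSet(targets=np.array([[640.0, 640.0, 640.0]]))
        info = run_to_quasi_steady(st, src, tol=1e-7, max_steps=20000)
        assert info["converged"]
        expected = small_params.sigma1 * small_lattice.dx**3 / small_params.k1
        assert st.total_mass(ATTRACTANT) == pytest.approx(expected, rel=0.01)

    def test_zero_sources_converges_immediately(self, small_params, small_lattice):
        st = FieldState(small_lattice, small_params)
        src = SourceSet(targets=np.zeros((0, 3)))
        info = run_to_quasi_steady(st, src, tol=1e-6, max_steps=100)
        assert info["converged"] and st.total_mass(ATTRACTANT) == 0.0

    def test_ring_source_field_has_lattice_rotation_symmetry(self, small_params):
        # a 12-fold source ring is invariant under 90° rotation, and so is the
        # lattice; the solved field must share that symmetry
        L = 1280.0
        lat = build_lattice(L, 40.0)
        st = FieldState(lat, small_params)
        az = 2 * np.pi * np.arange(12) / 12
        ring = np.stack(
            [L / 2 + 300 * np.cos(az), L / 2 + 300 * np.sin(az), np.full(12, L / 2)], axis=1
        )
        src = SourceSet(targets=ring)
        for _ in range(300):
            lbm_step(st, src, factors=(ATTRACTANT,))
        rho = st.rho(ATTRACTANT)
        assert np.allclose(rho, np.rot90(rho, k=1, axes=(0, 1)), rtol=1e-10, atol=1e-18)

    def test_obstacle_shadow_lowers_far_side_concentration(self, small_params):
        # the scar blocks diffusion: at equal distance behind the scar the
        # attractant is strictly lower than without the obstacle
        L, dx = 1280.0, 40.0
        geom = ScarGeometry(ra=280.0, rz=280.0, center=(L / 2,) * 3)
        src_pos = np.array([[L / 2, L / 2, L / 2 + 280.0 + 60.0]])
        probe = np.array([[L / 2, L / 2, L / 2 - 280.0 - 60.0]])
        vals = {}
        for name, g in [("open", None), ("scar", geom)]:
            lat = build_lattice(L, dx, g)
            st = FieldState(lat, small_params)
            src = SourceSet(targets=src_pos)
            for _ in range(600):
                lbm_step(st, src, factors=(ATTRACTANT,))
            vals[name] = sample_fields(st, probe, (ATTRACTANT,))[0, 0]
        assert vals["scar"] < 0.7 * vals["open"]


class TestSampling:
    def test_uniform_field_zero_gradient(self, small_params, small_lattice):
        st = FieldState(small_lattice, small_params)
        st.set_rho(ATTRACTANT, np.full(small_lattice.solid.shape, 3.3))
        g = sample_gradient(st, ATTRACTANT, np.array([617.0, 432.0, 555.5]))
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_linear_field_exact_gradient(self, small_params, small_lattice):
        ax = small_lattice.axis
        Z = np.broadcast_to(ax[None, None, :], small_lattice.solid.shape)
        st = FieldState(small_lattice, small_params)
        st.set_rho(ATTRACTANT, 0.01 * Z)
        g = sample_gradient(st, ATTRACTANT, np.array([640.0, 640.0, 617.3]))
        assert g == pytest.approx([0.0, 0.0, 0.01], abs=1e-12)

    def test_point_outside_domain_rejected(self, small_params, small_lattice):
        st = FieldState(small_lattice, small_params)
        with pytest.raises(ValueError):
            sample_fields(st, np.array([[2000.0, 0.0, 0.0]]))

    def test_gradient_of_screened_source_matches_analytic(self, small_params):
        # mid-field radial gradient against the derivative of the oracle
        L, dx = 1280.0, 40.0
        lat = build_lattice(L, dx)
        st = FieldState(lat, small_params)
        c = L / 2 - dx / 2
        src = SourceSet(targets=np.array([[c, c, c]]), spreading="nearest")
        run_to_quasi_steady(st, src, tol=1e-8, max_steps=20000)
        Q, D, k = small_params.sigma1 * dx**3, small_params.D1, small_params.k1
        kappa = np.sqrt(k / D)
        for m in [4, 5, 6]:
            d = m * dx * np.sqrt(2)
            pos = np.array([c + m * dx, c + m * dx, c])
            g = sample_gradient(st, ATTRACTANT, pos)
            radial = (g[0] + g[1]) / np.sqrt(2)
            expected = -analytic_point_source(d, Q, D, k) * (1.0 / d + kappa)
            assert radial == pytest.approx(expected, rel=0.10)


def test_grid_convergence_of_point_source_field(small_params):
    # halving Δx reduces the mid-field error against the analytic oracle
    L = 1280.0
    src_pos = np.array([[620.0, 620.0, 620.0]])
    # only the attractant is stepped; align the other decay rates so the
    # coarse grid's larger dt stays admissible
    params = small_params.replace(k2=small_params.k1, k3=small_params.k1)
    errors = {}
    for dx in (80.0, 40.0):
        lat = build_lattice(L, dx)
        st = FieldState(lat, params, tau_max=0.75)
        src = SourceSet(targets=src_pos, spreading="trilinear")
        run_to_quasi_steady(st, src, tol=1e-8, max_steps=30000, min_steps=50)
        Q = params.sigma1 * dx**3
        probes = src_pos + np.array(
            [[260.0, 0, 0], [0, 260.0, 0], [0, 0, 260.0], [180.0, 180.0, 0]]
        )
        num = sample_fields(st, probes, (ATTRACTANT,))[0]
        d = np.linalg.norm(probes - src_pos, axis=1)
        ana = analytic_point_source(d, Q, params.D1, params.k1)
        errors[dx] = np.max(np.abs(num - ana) / ana)
    assert errors[40.0] < errors[80.0]


def test_analytic_seed_matches_oracle_superposition(small_params, small_lattice):
    st = FieldState(small_lattice, small_params)
    tg = np.array([[400.0, 640.0, 640.0], [900.0, 640.0, 640.0]])
    seed_attractant_analytic(st, SourceSet(targets=tg))
    probe = np.array([650.0, 650.0, 650.0])
    Q = small_params.sigma1 * small_lattice.dx**3
    # compare at a node center
    i = tuple(int(v // small_lattice.dx) for v in probe)
    node = (np.array(i) + 0.5) * small_lattice.dx
    expected = sum(
        analytic_point_source(np.linalg.norm(node - t), Q, small_params.D1, small_params.k1)
        for t in tg
    )
    assert st.rho(ATTRACTANT)[i] == pytest.approx(expected, rel=1e-12)
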