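import numpy as np
import pytest
import scipy.sparse.linalg as spla

from nanopierce.core import MeshError, SolverError
from nanopierce.mechanics import (
    Indenter,
    PrestressSpec,
    apply_prestress,
    assemble_stiffness,
    beam_tension_deflection,
    build_network,
    midline_profile,
    simply_supported_beam_fe,
    simulate_indentation,
    stress_peak_fwhm,
)
from nanopierce.mechanics.simulate import NDOF, _free_dofs


def small_model(**kw):
    return build_network(600.0, 100.0, **kw)


PRE = PrestressSpec(membrane=100.0, filament=50e3, bundle=50e3)


class TestMesh:
    def test_grid_counts(self):
        m = build_network(1000.0, 200.0)
        assert m.n_nodes == 11 * 11
        assert len(m.filaments) == 2 * 11 * 10
        assert len(m.triangles) == 200

    def test_degenerate_spacing_rejected(self):
        with pytest.raises(MeshError):
            build_network(100.0, 200.0)

    def test_mirror_symmetry(self):
        m = small_model()
        for axis in (0, 1):
            flipped = m.nodes.copy()
            flipped[:, axis] *= -1
            # every node must have a mirror partner
            a = {tuple(np.round(p, 6)) for p in m.nodes}
            b = {tuple(np.round(p, 6)) for p in flipped}
            assert a == b

    def test_edges_clamped(self):
        m = small_model()
        xy = m.nodes[m.clamped_nodes][:, :2]
        assert np.all(np.max(np.abs(xy), axis=1) == pytest.approx(600.0))

    def test_bundles_along_x(self):
        m = build_network(1000.0, 200.0, fiber_lines=3)
        for n1, n2 in m.bundles:
            assert m.nodes[n1, 1] == m.nodes[n2, 1]  # constant y: along x


class TestPrestress:
    def test_filament_axial_force_units(self):
        m = small_model().with_prestress(PRE)
        # 50 kPa x 38.46 nm^2 = 1.923e-12 N = 1.923e-3 nN
        assert m.filament_axial_force() == pytest.approx(1.923e-3, rel=1e-3)

    def test_membrane_tension_units(self):
        m = small_model().with_prestress(PRE)
        # 100 Pa x 5 nm = 5e-7 N/m = 5e-7 nN/nm
        assert m.membrane_tension() == pytest.approx(5e-7, rel=1e-9)

    def test_zero_spec_is_noop(self):
        m = small_model()
        m2 = apply_prestress(m, PrestressSpec())
        k1 = assemble_stiffness(m)
        k2 = assemble_stiffness(m2)
        assert (k1 - k2).nnz == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            apply_prestress(small_model(), PrestressSpec(membrane=-1.0))


class TestStiffness:
    @pytest.mark.parametrize("spec", [PrestressSpec(), PRE])
    def test_symmetric_positive_definite(self, spec):
        m = apply_prestress(small_model(), spec)
        k = assemble_stiffness(m)
        asym = abs(k - k.T)
        assert asym.max() < 1e-10 * abs(k).max()
        free = _free_dofs(m)
        kff = k[np.ix_(free, free)].toarray()
        eigmin = np.linalg.eigvalsh(kff)[0]
        assert eigmin > 0


class TestSimulation:
    def test_zero_travel_zero_response(self):
        res = simulate_indentation(apply_prestress(small_model(), PRE),
                                   Indenter(travel=0.0))
        assert np.allclose(res.displacement, 0.0)
        # stress equals the prestress baseline everywhere
        assert res.max_membrane_stress == pytest.approx(100.0, rel=1e-6)

    def test_too_few_steps_rejected(self):
        with pytest.raises(SolverError):
            simulate_indentation(small_model(), Indenter(travel=50.0, steps=5))

    def test_clamped_nodes_fixed(self):
        m = apply_prestress(small_model(), PRE)
        res = simulate_indentation(m, Indenter(travel=50.0, steps=10))
        assert np.allclose(res.displacement[m.clamped_nodes], 0.0)

    def test_linear_small_travel(self):
        m = apply_prestress(small_model(), PRE)
        r1 = simulate_indentation(m, Indenter(travel=1.0, steps=10))
        r2 = simulate_indentation(m, Indenter(travel=2.0, steps=10))
        w1 = r1.displacement[:, 2]
        w2 = r2.displacement[:, 2]
        assert np.max(np.abs(w2 - 2 * w1)) <= 0.02 * np.max(np.abs(w2))

    def test_stress_field_symmetry(self):
        m = apply_prestress(small_model(), PRE)
        res = simulate_indentation(m, Indenter(travel=60.0, steps=10))
        c, s = res.centroids, res.stress_von_mises
        # mirror each centroid in x and find its partner
        import scipy.spatial

        tree = scipy.spatial.cKDTree(c)
        _, idx = tree.query(np.column_stack([-c[:, 0], c[:, 1]]))
        assert np.max(np.abs(s[idx] - s)) < 1e-6 * s.max()


@pytest.fixture(scope="module")
def pair():
    m = build_network(1000.0, 100.0)
    ind = Indenter(travel=100.0, steps=10)
    r0 = simulate_indentation(apply_prestress(m, PrestressSpec()), ind)
    r1 = simulate_indentation(apply_prestress(m, PRE), ind)
    return r0, r1


class TestPrestressContrast:
    def test_max_stress_larger_with_prestress(self, pair):
        r0, r1 = pair
        assert r1.max_membrane_stress > r0.max_membrane_stress

    def test_center_displacement_smaller_with_prestress(self, pair):
        r0, r1 = pair
        x0, w0, _ = midline_profile(r0)
        x1, w1, _ = midline_profile(r1)
        c0 = w0[np.argmin(np.abs(x0))]
        c1 = w1[np.argmin(np.abs(x1))]
        assert abs(c1) < abs(c0)

    def test_fwhm_narrower_with_prestress(self, pair):
        r0, r1 = pair
        x0, _, s0 = midline_profile(r0)
        x1, _, s1 = midline_profile(r1)
        assert stress_peak_fwhm(x1, s1) < stress_peak_fwhm(x0, s0)

    def test_profile_symmetry(self, pair):
        for r in pair:
            x, w, s = midline_profile(r)
            assert np.max(np.abs(w - w[::-1])) < 0.01 * np.max(np.abs(w))
            assert np.max(np.abs(s - s[::-1])) < 0.01 * np.max(np.abs(s))

    def test_monotone_in_each_component_upper_range(self):
        # swept in the tension-dominated range; from zero prestress the
        # bending-to-tension transition makes the global max non-monotone
        m = build_network(1000.0, 100.0)
        ind = Indenter(travel=100.0, steps=10)
        for comp in range(3):
            vals = []
            for f in (0.75, 1.0, 2.0):
                s = [100.0, 50e3, 50e3]
                s[comp] *= f
                r = simulate_indentation(apply_prestress(m, PrestressSpec(*s)), ind)
                vals.append(r.max_membrane_stress)
            assert vals[0] <= vals[1] <= vals[2]


@pytest.mark.slow
def test_mesh_refinement_qualitative_convergence():
    # spacings all resolve the tip footprint; halving then changes the max
    # stress by a decreasing amount
    vals = []
    for sp in (50.0, 25.0, 12.5):
        m = build_network(500.0, sp)
        r = simulate_indentation(apply_prestress(m, PRE), Indenter(travel=100.0, steps=10))
        vals.append(r.max_membrane_stress)
    assert abs(vals[2] - vals[1]) < abs(vals[1] - vals[0])


class TestTensionedBeam:
    def test_classical_limit(self):
        w = beam_tension_deflection(1000.0, 1e6, 0.0, 1.0)
        assert w == pytest.approx(1000.0**3 / (48.0 * 1e6), rel=1e-12)

    def test_taut_string_limit(self):
        # large tension: w -> F2 L / (4 F1)
        w = beam_tension_deflection(1000.0, 1e6, 1e4, 1.0)
        assert w == pytest.approx(1000.0 / (4.0 * 1e4), rel=0.05)

    def test_monotone_decreasing_in_tension(self):
        tensions = np.logspace(-4, 3, 30)
        w = [beam_tension_deflection(1000.0, 1e6, t, 1.0) for t in tensions]
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_fe_matches_closed_form(self):
        for f1 in (0.0, 1e-2, 1.0, 100.0):
            wc = beam_tension_deflection(1000.0, 1e6, f1, 1.0)
            wf = simply_supported_beam_fe(1000.0, 1e6, f1, 1.0, n_elements=200)
            assert wf == pytest.approx(wc, rel=5e-3)

    def test_fe_matches_finite_difference_oracle(self):
        # independent dense solve of EI w'''' - F1 w'' = 0 with a midspan
        # point load, pinned ends (w = 0, w'' = 0)
        length, ei, f1, f2 = 1000.0, 1e6, 0.5, 1.0
        n = 2001
        h = length / (n - 1)
        main = np.zeros((n, n))
        for i in range(2, n - 2):
            main[i, i - 2 : i + 3] += ei / h**4 * np.array([1.0, -4.0, 6.0, -4.0, 1.0])
            main[i, i - 1 : i + 2] += -f1 / h**2 * np.array([1.0, -2.0, 1.0])
        # boundary rows: w = 0 at ends; w'' = 0 via ghost reflection rows
        main[0, 0] = 1.0
        main[n - 1, n - 1] = 1.0
        main[1, 0:4] = [-2.0, 5.0, -4.0, 1.0]  # w''''(h) with w''(0)=0 reflection
        main[1, 0:3] += -f1 * h**2 / ei * np.array([1.0, -2.0, 1.0])
        main[1] *= ei / h**4
        main[n - 2, n - 4 : n] = np.array([1.0, -4.0, 5.0, -2.0]) * ei / h**4
        main[n - 2, n - 3 : n] += -f1 / h**2 * np.array([1.0, -2.0, 1.0])
        rhs = np.zeros(n)
        rhs[(n - 1) // 2] = f2 / h
        w = np.linalg.solve(main, rhs)
        w_mid = w[(n - 1) // 2]
        assert beam_tension_deflection(length, ei, f1, f2) == pytest.approx(w_mid, rel=5e-3)
        assert simply_supported_beam_fe(length, ei, f1, f2) == pytest.approx(w_mid, rel=5e-3)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            beam_tension_deflection(-1.0, 1e6, 0.0, 1.0)
        with pytest.raises(ValueError):
            beam_tension_deflection(1000.0, 1e6, -1.0, 1.0)
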