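"""Geometry builders: classification, meshing, labels, serialisation."""

import math

import numpy as np
import pytest

from osteofrac.geometry import (
    Microstructure,
    Osteon,
    SENBSpec,
    SingleOsteonSpec,
    build_senb,
    build_single_osteon,
    build_strip,
    classify_point,
    graded_coords,
    read_layout,
    single_osteon_microstructure,
    write_layout,
)


@pytest.fixture(scope="module")
def osteon_mesh():
    spec = SingleOsteonSpec()
    return spec, build_single_osteon(spec, h_fine=0.0025, ell=0.005)


class TestClassification:
    def test_single_osteon_labels(self):
        spec = SingleOsteonSpec()
        micro = single_osteon_microstructure(spec)
        c = spec.s / 2.0
        assert classify_point(micro, (c, c)) == "canal"
        assert classify_point(micro, (c + 0.05, c)) == "osteon"
        assert classify_point(micro, (c + 0.077, c)) == "cement_line"
        assert classify_point(micro, (0.0, 0.0)) == "matrix"

    def test_empty_microstructure_is_all_matrix(self):
        micro = Microstructure(osteons=[], t_cem=0.005)
        assert classify_point(micro, (0.1, 0.1)) == "matrix"

    def test_overlap_detection(self):
        micro = Microstructure(
            osteons=[Osteon(0.0, 0.0, 0.075, 0.025), Osteon(0.1, 0.0, 0.075, 0.025)],
            t_cem=0.005,
        )
        with pytest.raises(ValueError):
            micro.validate()


class TestSpecValidation:
    def test_single_osteon_invariants(self):
        with pytest.raises(ValueError):
            SingleOsteonSpec(r_i=0.08)  # canal larger than osteon
        with pytest.raises(ValueError):
            SingleOsteonSpec(r_o=0.21)  # does not fit the cell
        with pytest.raises(ValueError):
            SingleOsteonSpec(a_notch=0.25)

    def test_senb_invariants(self):
        with pytest.raises(ValueError):
            SENBSpec(a0=5.0)
        with pytest.raises(ValueError):
            SENBSpec(window=("circle", 3.0))  # window larger than the beam


class TestGradedCoords:
    def test_fine_interval_uniform(self):
        x = graded_coords(0.0, 1.0, 0.4, 0.6, 0.01)
        fine = x[(x >= 0.4 - 1e-12) & (x <= 0.6 + 1e-12)]
        assert np.allclose(np.diff(fine), 0.01)
        assert x[0] == 0.0 and x[-1] == pytest.approx(1.0)

    def test_spacing_grows_outward(self):
        x = graded_coords(0.0, 1.0, 0.4, 0.6, 0.01, growth=1.4)
        left = np.diff(x[x <= 0.4 + 1e-12])
        assert (np.diff(left) <= 1e-12).all()  # growing towards the boundary


class TestSingleOsteonMesh:
    def test_mesh_is_valid(self, osteon_mesh):
        spec, mesh = osteon_mesh
        mesh.validate(ell=0.005)
        assert mesh.h_min <= 0.005 / 2.0 + 1e-12

    def test_reference_density_element_count(self):
        # full-density meshing lands on the order of 40 000 elements
        mesh = build_single_osteon(SingleOsteonSpec(), h_fine=0.00125, ell=0.0025)
        assert 2e4 <= mesh.n_elems <= 1e5

    def test_osteon_area_fraction_recovered(self, osteon_mesh):
        spec, mesh = osteon_mesh
        analytic = math.pi * (spec.r_o**2 - spec.r_i**2) / spec.s**2
        names = np.array([mesh.material_names[i] for i in mesh.material_id])
        xy = mesh.nodes[mesh.elems]
        # shoelace area per quad
        x, y = xy[..., 0], xy[..., 1]
        area = 0.5 * np.abs(
            np.sum(x * np.roll(y, -1, axis=1) - np.roll(x, -1, axis=1) * y, axis=1)
        )
        frac = area[names == "osteon"].sum() / spec.s**2
        assert frac == pytest.approx(analytic, rel=0.02)

    def test_labels_match_centroid_classification(self, osteon_mesh):
        spec, mesh = osteon_mesh
        micro = single_osteon_microstructure(spec)
        cent = mesh.element_centroids()
        expect = micro.classify(cent)
        got = np.array([mesh.material_names[i] for i in mesh.material_id])
        assert (got == expect).all()

    def test_canal_meshed_as_hole(self, osteon_mesh):
        spec, mesh = osteon_mesh
        c = spec.s / 2.0
        cent = mesh.element_centroids()
        r = np.hypot(cent[:, 0] - c, cent[:, 1] - c)
        assert (r > spec.r_i - 1e-9).all()

    def test_notch_slit_duplicates_only(self, osteon_mesh):
        spec, mesh = osteon_mesh
        # duplicated coordinates occur only on the slit line y = s/2, x < a
        rounded = np.round(mesh.nodes, 9)
        uniq, cnt = np.unique(rounded, axis=0, return_counts=True)
        dups = uniq[cnt > 1]
        assert (np.abs(dups[:, 1] - spec.s / 2.0) < 1e-9).all()
        assert (dups[:, 0] < spec.a_notch).all()
        assert (cnt <= 2).all()

    def test_thin_cement_line_rejected(self):
        with pytest.raises(ValueError, match="cement line"):
            build_single_osteon(SingleOsteonSpec(), h_fine=0.004)

    def test_notch_tip_concentrates_stress(self, osteon_mesh):
        # elastic solve: max principal stress near the tip >> far field
        from osteofrac.fem import FEModel, StaggeredSolver
        from osteofrac.materials import PhaseFieldConfig, baseline_tissue_params

        spec, mesh = osteon_mesh
        model = FEModel(
            mesh=mesh,
            tissues=baseline_tissue_params(),
            pf=PhaseFieldConfig(ell=0.005),
        )
        s = StaggeredSolver(model)
        u = s.solve_displacement(np.zeros(mesh.n_nodes), 1e-3)
        eps = s.strains_pf(u)  # (mp, 4, 3)
        syy = eps[..., 1] * 20192.3 + eps[..., 0] * 8653.8  # plane-strain moduli
        cent = mesh.element_centroids()[s.pf_elems]
        tip = np.array([spec.a_notch, spec.s / 2.0])
        near = np.linalg.norm(cent - tip, axis=1) < 0.01
        far = cent[:, 0] > 0.35
        assert syy[near].max() > 3.0 * syy[far].mean()


class TestSENBMesh:
    def test_reference_density_element_count(self):
        # response-surface specimen at full density: order 200 000 elements
        spec = SENBSpec(L=16.0, h=4.0, a0=1.7, t=2.0, window=("circle", 0.9))
        mesh = build_senb(
            spec, None, h_fine=0.00125, ell=0.0025, corridor_width=0.6,
            fine_extent=0.55, h_max_ratio=64,
        )
        assert 1e5 <= mesh.n_elems <= 5e5

    def test_elastic_beam_crack_compliance_matches_handbook(self):
        # empty microstructure: the added compliance of deepening the notch
        # matches the handbook integral of the edge-crack energy release
        # rate (differencing two depths cancels load-point and shear terms
        # the Euler-Bernoulli formula misses on a stubby span)
        from scipy.integrate import quad

        from osteofrac.fem import FEModel, StaggeredSolver
        from osteofrac.materials import PhaseFieldConfig, TissueParams
        from osteofrac.postprocess import k_factor

        E, nu = 15000.0, 0.3
        Ep = E / (1.0 - nu**2)

        def compliance(a0):
            spec = SENBSpec(
                L=4.0, h=1.0, a0=a0, t=1.0, window=("circle", 0.15),
                window_offset=0.0,
            )
            mesh = build_senb(
                spec, None, h_fine=0.004, ell=0.008, corridor_width=0.12
            )
            model = FEModel(
                mesh=mesh,
                tissues={"matrix": TissueParams("matrix", E, nu, 0.35)},
                pf=PhaseFieldConfig(ell=0.008),
                thickness=spec.t,
            )
            s = StaggeredSolver(model)
            u = s.solve_displacement(np.zeros(mesh.n_nodes), 0.01)
            return 0.01 / s.reaction_force(u)

        dC_fe = compliance(0.5) - compliance(0.3)

        def dCda(a):
            K1 = 4.0 / (1.0 * 1.0**1.5) * k_factor(a / 1.0)
            return 2.0 * K1**2 / Ep

        dC_handbook, _ = quad(dCda, 0.3, 0.5)
        assert dC_fe == pytest.approx(dC_handbook, rel=0.05)

    def test_cmod_zero_at_zero_load(self):
        from osteofrac.fem import FEModel, StaggeredSolver
        from osteofrac.materials import PhaseFieldConfig, TissueParams

        spec = SENBSpec(L=4.0, h=1.0, a0=0.4, t=1.0, window=("circle", 0.2))
        mesh = build_senb(spec, None, h_fine=0.005, ell=0.01, corridor_width=0.1)
        model = FEModel(
            mesh=mesh,
            tissues={"matrix": TissueParams("matrix", 15000.0, 0.3, 0.35)},
            pf=PhaseFieldConfig(ell=0.01),
        )
        s = StaggeredSolver(model)
        u = s.solve_displacement(np.zeros(mesh.n_nodes), 0.0)
        na, nb = mesh.metadata["cmod"]["nodes"]
        assert u[2 * na] == 0.0 and u[2 * nb] == 0.0

    def test_window_tissue_labels_and_elastic_outside(self):
        spec = SENBSpec(L=4.0, h=1.0, a0=0.4, t=1.0, window=("circle", 0.2))
        micro = Microstructure(
            osteons=[Osteon(0.0, 0.55, 0.06, 0.02)], t_cem=0.012
        )
        mesh = build_senb(spec, micro, h_fine=0.005, ell=0.012, corridor_width=0.2)
        names = np.array([mesh.material_names[i] for i in mesh.material_id])
        cent = mesh.element_centroids()
        outside = ~spec.in_window(cent)
        assert (names[outside] == "elastic").all()
        assert not mesh.pf_active[outside].any()
        assert (names == "osteon").sum() > 0
        assert (names == "cement_line").sum() > 0


class TestStripBuilder:
    def test_homogeneous_bar_mesh(self):
        mesh = build_strip(width=0.2, height=0.4, h_fine=0.02, ell=0.04)
        mesh.validate(ell=0.04)
        assert set(mesh.node_sets) >= {"top", "bottom", "pin"}


class TestLayoutSerialisation:
    def test_round_trip(self, tmp_path):
        micro = Microstructure(
            osteons=[Osteon(0.1, 0.2, 0.07, 0.025), Osteon(0.4, 0.2, 0.06, 0.02)],
            t_cem=0.005,
            region=("circle", 0.25, 0.2, 0.3),
        )
        path = tmp_path / "layout.txt"
        write_layout(micro, path)
        back = read_layout(path)
        assert back.t_cem == micro.t_cem
        assert back.region == micro.region
        assert len(back.osteons) == 2
        assert back.osteons[0] == micro.osteons[0]
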