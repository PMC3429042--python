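"""Convection-diffusion-reaction solver: monotonicity, conservation and the
batch-reactor oracle."""

import numpy as np
import pytest

from thromboflow.geometry import AAAGeometry, StructuredGrid, exposure_patches
from thromboflow.hemodynamics import FlowField
from thromboflow.kinetics import (
    MOIETIES,
    SPECIES,
    build_network,
    initial_concentrations,
    simulate_batch,
)
from thromboflow.transport import (
    BoundarySpec,
    CDRSolver,
    DistalMetric,
    TransportConfig,
    distal_accumulation_metric,
    peclet_field,
)

IDX = {s: i for i, s in enumerate(SPECIES)}


def make_grid(nz=30, nr=6, straight=False):
    geo = AAAGeometry(R0=0.01, Rmax=0.01 if straight else 0.022)
    return StructuredGrid(geo, nz=nz, nr=nr)


def zero_fluxes(grid):
    return np.zeros((grid.nz + 1, grid.nr)), np.zeros((grid.nz, grid.nr + 1))


def plug_flow_fluxes(grid, u):
    """Uniform axial plug flow u through every axial face."""
    phi_ax = u * grid.ax_face_area
    phi_rad = np.zeros((grid.nz, grid.nr + 1))
    return phi_ax, phi_rad


@pytest.fixture(scope="module")
def network():
    return build_network()


class TestDegenerateLimits:
    def test_no_flow_no_reaction_uniform_field_unchanged(self):
        grid = make_grid()
        solver = CDRSolver(grid, None, BoundarySpec(closed=True),
                           TransportConfig(), dt=0.05)
        c = np.broadcast_to(initial_concentrations()[:, None, None],
                            (18, grid.nz, grid.nr)).copy()
        phi_ax, phi_rad = zero_fluxes(grid)
        out = c
        for _ in range(20):
            out = solver.advance(out, phi_ax, phi_rad)
        # exactly invariant up to linear-solver round-off
        assert np.allclose(out, c, rtol=1e-12, atol=0)

    def test_no_exposure_keeps_thrombin_zero(self, network):
        # open boundaries and real flow-free chemistry, but no TF:VIIa
        # anywhere: the cascade has no trigger
        grid = make_grid()
        solver = CDRSolver(grid, network, BoundarySpec(),
                           TransportConfig(), dt=0.05)
        c = np.broadcast_to(BoundarySpec().inlet[:, None, None],
                            (18, grid.nz, grid.nr)).copy()
        phi_ax, phi_rad = plug_flow_fluxes(grid, 0.01)
        for _ in range(50):
            c = solver.advance(c, phi_ax, phi_rad)
        assert c[IDX["IIa"]].max() == 0.0
        assert c[IDX["TF:VIIa"]].max() == 0.0


class TestBatchEquivalence:
    def test_flow_free_closed_box_matches_batch_reactor(self, network):
        grid = make_grid(nz=20, nr=5)
        dt, t_end = 0.01, 30.0
        solver = CDRSolver(grid, network, BoundarySpec(closed=True),
                           TransportConfig(reaction_substeps=2), dt=dt)
        c0 = initial_concentrations()
        c = np.broadcast_to(c0[:, None, None], (18, grid.nz, grid.nr)).copy()
        phi_ax, phi_rad = zero_fluxes(grid)
        for _ in range(int(round(t_end / dt))):
            c = solver.advance(c, phi_ax, phi_rad)
        ref = simulate_batch(network, c0, t_end=t_end,
                             extend_to_plateau=False, n_out=4).c[-1]
        scale = np.maximum(np.abs(ref), 1e-4 * np.abs(ref).max())
        err = np.abs(c - ref[:, None, None]) / scale[:, None, None]
        assert err.max() < 1e-4

    def test_cells_remain_identical(self, network):
        grid = make_grid(nz=10, nr=4)
        solver = CDRSolver(grid, network, BoundarySpec(closed=True),
                           TransportConfig(), dt=0.02)
        c = np.broadcast_to(initial_concentrations()[:, None, None],
                            (18, grid.nz, grid.nr)).copy()
        phi_ax, phi_rad = zero_fluxes(grid)
        for _ in range(100):
            c = solver.advance(c, phi_ax, phi_rad)
        assert np.ptp(c.reshape(18, -1), axis=1).max() < 1e-12


class TestConservationAndPositivity:
    def test_closed_box_moiety_conservation(self, network):
        # non-uniform initial state, zero velocity, zero-flux walls:
        # total moles of each moiety must stay constant
        grid = make_grid(nz=16, nr=5)
        solver = CDRSolver(grid, network, BoundarySpec(closed=True),
                           TransportConfig(), dt=0.02)
        rng = np.random.default_rng(8)
        c = initial_concentrations()[:, None, None] * rng.uniform(
            0.5, 1.5, (18, grid.nz, grid.nr))
        phi_ax, phi_rad = zero_fluxes(grid)
        V = grid.volume

        def totals(c):
            return {m: sum((c[IDX[s]] * V).sum() for s in members)
                    for m, members in MOIETIES.items()}

        t0 = totals(c)
        for _ in range(1000):
            c = solver.advance(c, phi_ax, phi_rad)
        t1 = totals(c)
        for m in t0:
            assert abs(t1[m] - t0[m]) < 1e-8 * t0[m]
        assert c.min() >= 0.0

    def test_advected_blob_monotone_and_mass_conserving(self):
        # inert species blob in a plug flow: the monotone scheme creates no
        # new extrema and conserves mass until the blob reaches the outlet
        grid = make_grid(nz=60, nr=5, straight=True)
        cfg = TransportConfig(diffusion=1e-12)
        bc = BoundarySpec(inlet=np.zeros(18))
        u = 0.05
        dt = 0.4 * (grid.geometry.length / grid.nz) / u
        solver = CDRSolver(grid, None, bc, cfg, dt=dt)
        c = np.zeros((18, grid.nz, grid.nr))
        z = grid.zc[:, 0]
        blob = np.exp(-((z - 0.03) / 0.008) ** 2)
        c[0] = blob[:, None]
        phi_ax, phi_rad = plug_flow_fluxes(grid, u)
        mass0 = (c[0] * grid.volume).sum()
        peak0 = c[0].max()
        for _ in range(20):  # blob travels ~0.03 m, still inside
            c = solver.advance(c, phi_ax, phi_rad)
            assert c[0].min() >= 0.0
            assert c[0].max() <= peak0 * (1 + 1e-12)
        mass = (c[0] * grid.volume).sum()
        assert mass == pytest.approx(mass0, rel=1e-10)

    def test_gaussian_advection_converges_under_refinement(self):
        # manufactured solution: advected Gaussian in plug flow vs the
        # closed-form translated profile; upwind error shrinks with h
        u, t_final = 0.05, 0.6
        errors = []
        for nz in (60, 120, 240):
            grid = make_grid(nz=nz, nr=4, straight=True)
            dt = 0.4 * (grid.geometry.length / nz) / u
            steps = int(round(t_final / dt))
            dt = t_final / steps
            solver = CDRSolver(grid, None, BoundarySpec(inlet=np.zeros(18)),
                               TransportConfig(diffusion=1e-12), dt=dt)
            c = np.zeros((18, grid.nz, grid.nr))
            z = grid.zc[:, 0]
            c[0] = np.exp(-((z - 0.04) / 0.01) ** 2)[:, None]
            phi_ax, phi_rad = plug_flow_fluxes(grid, u)
            for _ in range(steps):
                c = solver.advance(c, phi_ax, phi_rad)
            exact = np.exp(-((z - 0.04 - u * t_final) / 0.01) ** 2)
            errors.append(np.abs(c[0][:, 0] - exact).mean())
        assert errors[1] < errors[0]
        assert errors[2] < errors[1]


class TestExposurePatchSource:
    def test_patch_injects_tf_viia_and_triggers_thrombin(self, network):
        grid = StructuredGrid(AAAGeometry(), nz=60, nr=10)
        patch = exposure_patches(grid.geometry, "B")
        solver = CDRSolver(grid, network, BoundarySpec(), TransportConfig(),
                           patch_faces=grid.wall_faces_in(patch), dt=0.01)
        c = np.broadcast_to(BoundarySpec().inlet[:, None, None],
                            (18, grid.nz, grid.nr)).copy()
        phi_ax, phi_rad = zero_fluxes(grid)
        for _ in range(200):
            c = solver.advance(c, phi_ax, phi_rad)
        tf = c[IDX["TF:VIIa"]]
        assert tf.max() > 0
        assert tf.max() <= 1e-6 * (1 + 1e-9)  # bounded by the patch Dirichlet
        # TF:VIIa enters at the patch wall faces
        mask = grid.wall_faces_in(patch)
        assert tf[mask, -1].min() > tf[~mask, 0].max()
        assert c[IDX["IIa"]].max() > 0


class TestPeclet:
    def test_hand_value(self):
        grid = make_grid(nz=10, nr=4, straight=True)
        flow = FlowField(grid, 0.0,
                         u_z=np.full((10, 4), 0.1), u_r=np.zeros((10, 4)),
                         p=np.zeros((10, 4)),
                         phi_ax=np.zeros((11, 4)), phi_rad=np.zeros((10, 5)))
        grid.h = np.full((10, 4), 1e-3)  # forced cell size for the check
        pe = peclet_field(flow, grid, D=1e-8)
        assert np.allclose(pe, 0.1 * 1e-3 / (2 * 1e-8))  # = 5000

    def test_zero_velocity_zero_peclet(self):
        grid = make_grid(nz=8, nr=4)
        flow = FlowField(grid, 0.0, np.zeros((8, 4)), np.zeros((8, 4)),
                         np.zeros((8, 4)), np.zeros((9, 4)), np.zeros((8, 5)))
        assert np.abs(peclet_field(flow, grid, D=1e-8)).max() == 0.0

    def test_halving_d_doubles_peclet(self):
        grid = make_grid(nz=8, nr=4)
        rng = np.random.default_rng(2)
        flow = FlowField(grid, 0.0, rng.uniform(0, 1, (8, 4)),
                         rng.uniform(0, 1, (8, 4)), np.zeros((8, 4)),
                         np.zeros((9, 4)), np.zeros((8, 5)))
        pe1 = peclet_field(flow, grid, D=1e-8)
        pe2 = peclet_field(flow, grid, D=5e-9)
        assert np.allclose(pe2, 2 * pe1)

    def test_nonpositive_d_rejected(self):
        grid = make_grid(nz=8, nr=4)
        flow = FlowField(grid, 0.0, np.zeros((8, 4)), np.zeros((8, 4)),
                         np.zeros((8, 4)), np.zeros((9, 4)), np.zeros((8, 5)))
        with pytest.raises(ValueError):
            peclet_field(flow, grid, D=0.0)


class TestDistalMetric:
    def test_point_mass_at_apex(self):
        grid = StructuredGrid(AAAGeometry(), nz=100, nr=10)
        f = np.zeros((grid.nz, grid.nr))
        i = np.argmin(np.abs(grid.zc[:, 0] - grid.geometry.z_c))
        f[i, 5] = 1.0
        m = distal_accumulation_metric(f, grid)
        assert m.defined
        assert m.centroid_z == pytest.approx(grid.zc[i, 5])
        assert m.distal_fraction in (0.0, 1.0)  # cell-center decides the side

    def test_uniform_field_centroid_is_volume_centroid(self):
        grid = StructuredGrid(AAAGeometry(), nz=120, nr=12)
        f = np.ones((grid.nz, grid.nr))
        m = distal_accumulation_metric(f, grid)
        zc_exact = (grid.volume * grid.zc).sum() / grid.volume.sum()
        assert m.centroid_z == pytest.approx(zc_exact, rel=1e-12)
        # symmetric geometry: volume centroid sits at the domain middle
        assert m.centroid_z == pytest.approx(grid.geometry.length / 2, rel=1e-3)

    def test_all_zero_field_is_undefined_not_an_error(self):
        grid = make_grid()
        m = distal_accumulation_metric(np.zeros((grid.nz, grid.nr)), grid)
        assert m == DistalMetric(False, m.centroid_z, m.distal_fraction)
        assert not m.defined and np.isnan(m.centroid_z)

    def test_negative_field_rejected(self):
        grid = make_grid()
        with pytest.raises(ValueError):
            distal_accumulation_metric(np.full((grid.nz, grid.nr), -1.0), grid)
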