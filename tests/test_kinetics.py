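"""Unit and property tests for the coagulation-cascade reaction network."""

import numpy as np
import pytest

from thromboflow.kinetics import (
    MOIETIES,
    SPECIES,
    RateConstants,
    build_network,
    detect_phases,
    initial_concentrations,
    moiety_totals,
    ode_rhs,
    reaction_rates,
    simulate_batch,
)

IDX = {s: i for i, s in enumerate(SPECIES)}


def naive_rhs(c, k):
    """Independent oracle: one explicit term per reaction arrow, no matrix.

    Written reaction-by-reaction straight from the chemistry; shares no code
    with the implementation under test.
    """
    d = {s: 0.0 for s in SPECIES}
    g = lambda s: c[IDX[s]]

    # IX + TF:VIIa <-> IX:TF:VIIa -> TF:VIIa + IXa
    on = k["k6"] * g("IX") * g("TF:VIIa")
    off = k["k16"] * g("IX:TF:VIIa")
    cat = k["k11"] * g("IX:TF:VIIa")
    d["IX"] += off - on
    d["TF:VIIa"] += off - on + cat
    d["IX:TF:VIIa"] += on - off - cat
    d["IXa"] += cat
    # X + TF:VIIa <-> X:TF:VIIa -> TF:VIIa + Xa
    on = k["k6"] * g("X") * g("TF:VIIa")
    off = k["k17"] * g("X:TF:VIIa")
    cat = k["k12"] * g("X:TF:VIIa")
    d["X"] += off - on
    d["TF:VIIa"] += off - on + cat
    d["X:TF:VIIa"] += on - off - cat
    d["Xa"] += cat
    # X + VIIIa:IXa <-> X:VIIIa:IXa -> VIIIa:IXa + Xa
    on = k["k6"] * g("X") * g("VIIIa:IXa")
    off = k["k18"] * g("X:VIIIa:IXa")
    cat = k["k13"] * g("X:VIIIa:IXa")
    d["X"] += off - on
    d["VIIIa:IXa"] += off - on + cat
    d["X:VIIIa:IXa"] += on - off - cat
    d["Xa"] += cat
    # IX + Xa -> Xa + IXa
    v = k["k15"] * g("IX") * g("Xa")
    d["IX"] -= v
    d["IXa"] += v
    # V + Xa -> Xa + Va
    v = k["k1"] * g("V") * g("Xa")
    d["V"] -= v
    d["Va"] += v
    # VIII + Xa -> Xa + VIIIa
    v = k["k3"] * g("VIII") * g("Xa")
    d["VIII"] -= v
    d["VIIIa"] += v
    # V + IIa -> IIa + Va
    v = k["k2"] * g("V") * g("IIa")
    d["V"] -= v
    d["Va"] += v
    # VIII + IIa -> IIa + VIIIa
    v = k["k4"] * g("VIII") * g("IIa")
    d["VIII"] -= v
    d["VIIIa"] += v
    # II + Va:Xa <-> II:Va:Xa -> Va:Xa + mIIa
    on = k["k6"] * g("II") * g("Va:Xa")
    off = k["k19"] * g("II:Va:Xa")
    cat = k["k14"] * g("II:Va:Xa")
    d["II"] += off - on
    d["Va:Xa"] += off - on + cat
    d["II:Va:Xa"] += on - off - cat
    d["mIIa"] += cat
    # mIIa + Va:Xa -> Va:Xa + IIa
    v = k["k5"] * g("mIIa") * g("Va:Xa")
    d["mIIa"] -= v
    d["IIa"] += v
    # VIIIa + IXa <-> VIIIa:IXa
    on = k["k7"] * g("VIIIa") * g("IXa")
    off = k["k9"] * g("VIIIa:IXa")
    d["VIIIa"] += off - on
    d["IXa"] += off - on
    d["VIIIa:IXa"] += on - off
    # Va + Xa <-> Va:Xa
    on = k["k8"] * g("Va") * g("Xa")
    off = k["k10"] * g("Va:Xa")
    d["Va"] += off - on
    d["Xa"] += off - on
    d["Va:Xa"] += on - off
    return np.array([d[s] for s in SPECIES])


@pytest.fixture(scope="module")
def network():
    return build_network()


@pytest.fixture(scope="module")
def batch(network):
    return simulate_batch(network)


class TestNetworkStructure:
    def test_stoichiometry_shape_and_entries(self, network):
        assert network.S.shape == (18, 16)
        assert set(np.unique(network.S)) <= {-1, 0, 1}

    def test_binding_column_for_ix_tf_viia(self, network):
        col = network.S[:, 0]
        expected = np.zeros(18, dtype=int)
        expected[IDX["IX"]] = -1
        expected[IDX["TF:VIIa"]] = -1
        expected[IDX["IX:TF:VIIa"]] = 1
        assert (col == expected).all()

    def test_catalyst_cancels_in_miia_conversion(self, network):
        col = network.S[:, 13]
        expected = np.zeros(18, dtype=int)
        expected[IDX["mIIa"]] = -1
        expected[IDX["IIa"]] = 1
        assert (col == expected).all()

    def test_moieties_span_left_null_space(self, network):
        for members in MOIETIES.values():
            ind = np.array([s in members for s in SPECIES], dtype=float)
            assert np.abs(ind @ network.S).max() == 0

    def test_nonpositive_constant_rejected(self):
        with pytest.raises(ValueError, match="k14"):
            RateConstants(k14=0.0)
        with pytest.raises(ValueError, match="k6"):
            RateConstants(k6=-1.0)


class TestRates:
    def test_initial_rates_by_hand(self, network):
        r = reaction_rates(network, initial_concentrations())
        assert r[0] == pytest.approx(1e5 * 90e-6 * 1e-6, rel=1e-14)  # IX binding
        assert r[2] == pytest.approx(1e5 * 170e-6 * 1e-6, rel=1e-14)  # X binding
        others = np.delete(r, [0, 2])
        assert np.abs(others).max() == 0.0

    def test_zero_state_gives_zero_rates(self, network):
        assert np.abs(reaction_rates(network, np.zeros(18))).max() == 0.0

    def test_rhs_hand_values(self, network):
        rhs = ode_rhs(network, initial_concentrations())
        assert rhs[IDX["IX"]] == pytest.approx(-9.0e-6, rel=1e-12)
        assert rhs[IDX["TF:VIIa"]] == pytest.approx(-2.6e-5, rel=1e-12)

    def test_negative_concentration_rejected(self, network):
        c = initial_concentrations()
        c[IDX["X"]] = -1e-6
        with pytest.raises(ValueError, match="X"):
            reaction_rates(network, c)

    def test_small_negative_clipped(self, network):
        c = np.zeros(18)
        c[IDX["IX"]] = -1e-13  # within tolerance: treated as zero
        assert np.abs(reaction_rates(network, c)).max() == 0.0

    def test_rhs_matches_bruteforce_oracle(self, network):
        rng = np.random.default_rng(42)
        k = {f"k{i}": getattr(network.constants, f"k{i}") for i in range(1, 20)}
        scale = np.full(18, 1e-4)
        for _ in range(100):
            c = rng.uniform(0, 1, 18) * scale
            got = ode_rhs(network, c)
            want = naive_rhs(c, k)
            assert np.allclose(got, want, rtol=1e-12, atol=1e-25)

    def test_jacobian_matches_finite_differences(self, network):
        rng = np.random.default_rng(7)
        c = rng.uniform(0, 1e-4, 18)
        J = network.jacobian(c)
        eps = 1e-10
        for i in range(18):
            dc = np.zeros(18)
            dc[i] = eps
            col = (network.rhs(c + dc) - network.rhs(c - dc)) / (2 * eps)
            assert np.allclose(J[:, i], col, rtol=5e-5, atol=1e-8)

    def test_vectorized_rates_match_loop(self, network):
        rng = np.random.default_rng(3)
        C = rng.uniform(0, 1e-4, (18, 25))
        R = network.rates(C)
        for j in range(25):
            assert np.allclose(R[:, j], network.rates(C[:, j]), rtol=1e-14)


class TestMoieties:
    def test_initial_totals(self):
        totals = moiety_totals(initial_concentrations())
        assert totals["II"] == pytest.approx(1.4e-3, rel=1e-14)
        assert totals["TF:VIIa"] == pytest.approx(1e-6, rel=1e-14)

    def test_zero_state(self):
        assert all(v == 0.0 for v in moiety_totals(np.zeros(18)).values())


class TestBatchRun:
    def test_thrombin_plateau_equals_initial_prothrombin(self, batch):
        report = detect_phases(batch)
        assert report.plateaued
        assert report.plateau_IIa == pytest.approx(1.4e-3, rel=0.01)

    def test_phase_ordering(self, batch):
        report = detect_phases(batch)
        assert 0 < report.t_lag_end < report.t_plateau_start

    def test_moiety_conservation_along_trajectory(self, batch):
        t0 = moiety_totals(batch.c[0])
        for row in batch.c[:: max(1, len(batch.t) // 50)]:
            for name, v in moiety_totals(row).items():
                assert abs(v - t0[name]) < 1e-6 * t0[name]

    def test_nonnegative_and_thrombin_monotone(self, batch):
        # the stiff integrator may undershoot zero by O(100*atol) where a
        # species depletes; clipping is not applied so that linear moiety
        # invariants stay exactly conserved
        assert batch.c.min() >= -1e-10
        iia = batch.species("IIa")
        assert np.all(np.diff(iia) >= -1e-12 * iia[-1])

    def test_cumulative_xa_activation_monotone(self, batch):
        # Xa + its downstream complexes only grow as X is consumed.
        activated = (batch.species("Xa") + batch.species("Va:Xa")
                     + batch.species("II:Va:Xa"))
        assert np.all(np.diff(activated) >= -1e-10 * activated[-1])

    def test_no_trigger_means_frozen_state(self, network):
        c0 = initial_concentrations({"TF:VIIa": 0.0, "VIIIa": 0.0})
        traj = simulate_batch(network, c0, t_end=50.0, extend_to_plateau=False)
        assert np.allclose(traj.c, c0[None, :], atol=1e-15)

    def test_first_row_is_initial_condition(self, batch):
        assert np.allclose(batch.c[0], initial_concentrations())
        assert np.all(np.diff(batch.t) > 0)

    def test_tolerance_robustness(self, network, batch):
        tight = simulate_batch(network, rtol=5e-9, atol=5e-13)
        a, b = detect_phases(batch), detect_phases(tight)
        assert abs(a.plateau_IIa - b.plateau_IIa) < 1e-3 * a.plateau_IIa
        assert abs(a.t_plateau_start - b.t_plateau_start) < 0.01 * a.t_plateau_start


class TestPhaseDetection:
    def test_flat_zero_trajectory_reports_no_plateau(self):
        from thromboflow.kinetics import BatchTrajectory
        t = np.linspace(0, 10, 50)
        c = np.tile(initial_concentrations(), (50, 1))
        report = detect_phases(BatchTrajectory(t, c))
        assert not report.plateaued
        assert np.isnan(report.t_lag_end)

    def test_unplateaued_ramp_reports_no_plateau(self):
        from thromboflow.kinetics import BatchTrajectory
        t = np.linspace(0, 10, 50)
        c = np.zeros((50, 18))
        c[:, IDX["IIa"]] = np.linspace(0, 1e-3, 50)  # still rising at the end
        assert not detect_phases(BatchTrajectory(t, c)).plateaued
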