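"""Model structure and integrator correctness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from cfekit import (
    BULK_MLE, CELL_MLE, KineticParams, ModelState, ModelVariant, VARIANTS,
    max_rates, rhs, simulate,
)

rates = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)


def test_variant_set_structure():
    assert len(VARIANTS) == 7
    v1 = VARIANTS["V1"]
    assert v1.tx_law == "michaelis_menten"
    assert v1.tl_law == "michaelis_menten"
    assert v1.tsr_degradation == "first_order"
    assert v1.tlr_degradation == "michaelis_menten"
    assert v1.n_active_params == 13
    # every variant drops K-constants exactly when the law is mass action
    for v in VARIANTS.values():
        assert ("K_r" in v.active_params) == (v.tx_law == "michaelis_menten")
        assert ("K_p" in v.active_params) == (v.tl_law == "michaelis_menten")
        assert ("K_l" in v.active_params) == (
            v.tlr_degradation == "michaelis_menten"
        )


def test_negative_parameter_rejected():
    with pytest.raises(ValueError):
        KineticParams(**{**BULK_MLE.as_dict(), "k_r": -1.0})


class TestRhs:
    def test_zero_rates_leave_only_decay_and_maturation(self, bulk_params):
        p = bulk_params.replace(k_r=0.0, k_p=0.0)
        s = ModelState(DNA=3.75, RNA=100.0, TsR=0.5, TlR=0.5,
                       P_dark=10.0, P_mat=5.0)
        d = rhs(s, lagged_rna=100.0, params=p, variant="V1")
        assert d["RNA"] == pytest.approx(-p.delta_r * 100.0)
        assert d["P_mat"] == pytest.approx(p.k_mat * 10.0)
        assert d["P_dark"] == pytest.approx(-p.k_mat * 10.0)

    def test_no_substrate_only_resource_decay(self, bulk_params):
        s = ModelState(DNA=0.0, RNA=0.0, TsR=1.0, TlR=1.0,
                       P_dark=0.0, P_mat=0.0)
        d = rhs(s, lagged_rna=0.0, params=bulk_params, variant="V1")
        assert d["RNA"] == 0.0 and d["P_dark"] == 0.0 and d["P_mat"] == 0.0
        assert d["TsR"] == pytest.approx(-bulk_params.delta_TsR)
        expected_tlr = -bulk_params.delta_TlR / (bulk_params.K_l + 1.0)
        assert d["TlR"] == pytest.approx(expected_tlr)

    def test_initial_transcription_flux_bulk(self, bulk_params):
        # hand evaluation of the saturating transcription law at start
        s = ModelState.initial(dna0=3.75)
        d = rhs(s, lagged_rna=0.0, params=bulk_params, variant="V1")
        assert d["RNA"] == pytest.approx(2894.0 * 3.75 / (3.67 + 3.75))

    def test_mass_action_limit_of_mm(self, bulk_params):
        # MM with K far below substrate approaches the saturated rate
        s = ModelState(DNA=3.75, RNA=500.0, TsR=0.7, TlR=0.7,
                       P_dark=0.0, P_mat=0.0)
        p = bulk_params.replace(K_r=3.75e-8, K_p=5e-6)
        d = rhs(s, 500.0, p, "V1")
        v_tx_sat = p.k_r * 0.7
        assert d["RNA"] + p.delta_r * 500.0 == pytest.approx(
            v_tx_sat, rel=1e-6
        )

    def test_negative_lagged_rna_rejected(self, bulk_params):
        s = ModelState.initial(dna0=1.0)
        with pytest.raises(ValueError):
            rhs(s, lagged_rna=-1.0, params=bulk_params)


class TestSimulate:
    def test_no_source_stays_zero(self, bulk_params):
        p = bulk_params.replace(k_r=0.0)
        traj = simulate(p, "V1", dna0=3.75, rna0=0.0,
                        t_grid=np.linspace(0, 4, 25))
        assert np.all(traj.observed_rna == 0.0)
        assert np.all(traj.observed_protein == 0.0)

    def test_closed_form_birth_death(self, bulk_params):
        # frozen TsR + saturated transcription -> linear birth-death RNA
        p = bulk_params.replace(a=0.0, delta_TsR=0.0, K_r=0.0, k_p=0.0,
                                b=0.0, delta_TlR=0.0, tau_l=0.0)
        t = np.linspace(0, 8, 97)
        traj = simulate(p, "V1", dna0=3.75, t_grid=t)
        expect = p.k_r / p.delta_r * (1 - np.exp(-p.delta_r * t))
        assert traj.rna[1:] == pytest.approx(expect[1:], rel=1e-5)
        # spot check at t = 1/delta_r (faster decay so it lies in-span)
        p2 = p.replace(delta_r=0.5)
        t_star = 1.0 / p2.delta_r
        traj2 = simulate(p2, "V1", dna0=3.75, t_grid=np.linspace(0, 4, 49))
        val = np.interp(t_star, traj2.fine_time, traj2.fine_states[:, 0])
        assert val == pytest.approx(
            p2.k_r / p2.delta_r * (1 - 1 / np.e), rel=1e-5
        )

    def test_delay_zero_matches_plain_ode(self, bulk_params):
        p = bulk_params.replace(tau_d=0.0, tau_l=0.0)
        t = np.linspace(0, 6, 61)
        traj = simulate(p, "V1", dna0=3.75, t_grid=t)

        def odes(t_, y):
            s = ModelState(DNA=3.75, RNA=max(y[0], 0.0),
                           TsR=min(max(y[1], 0.0), 1.0),
                           TlR=min(max(y[2], 0.0), 1.0),
                           P_dark=max(y[3], 0.0), P_mat=max(y[4], 0.0))
            d = rhs(s, s.RNA, p, "V1")
            return [d["RNA"], d["TsR"], d["TlR"], d["P_dark"], d["P_mat"]]

        sol = solve_ivp(odes, (0, 6), [0, 1, 1, 0, 0], t_eval=t,
                        rtol=1e-10, atol=1e-12, method="LSODA")
        for j in range(5):
            scale = max(np.max(np.abs(sol.y[j])), 1e-12)
            assert np.max(np.abs(traj.states[:, j] - sol.y[j])) / scale < 1e-6

    def test_rna_history_feeds_translation_through_delay(self, bulk_params):
        # RNA-template experiment: constant history rna0 means translation
        # starts immediately; protein must be above 0 right after the start
        p = bulk_params.replace(tau_l=0.0)
        traj = simulate(p, "V1", dna0=0.0, rna0=600.0,
                        t_grid=np.linspace(0, 2, 41))
        assert traj.observed_protein[4] > 0.0
        # and with a delay longer than the span and no history, none at all
        p2 = p.replace(tau_d=10.0)
        traj2 = simulate(p2, "V1", dna0=3.75, rna0=0.0,
                         t_grid=np.linspace(0, 2, 41))
        assert np.all(traj2.observed_protein == 0.0)

    def test_measurement_lag_zeroes_early_points(self):
        traj = simulate(CELL_MLE, "V1", dna0=3.5,
                        t_grid=np.linspace(0, 12, 145))
        lagged = traj.time < CELL_MLE.tau_l
        assert lagged.sum() > 0
        assert np.all(traj.observed_protein[lagged] == 0.0)
        assert np.all(traj.observed_rna[~lagged] >= 0.0)

    def test_bad_grid_rejected(self, bulk_params):
        with pytest.raises(ValueError):
            simulate(bulk_params, "V1", dna0=1.0, t_grid=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            simulate(bulk_params, "V1", dna0=-1.0)

    @given(
        k_r=rates, delta_r=st.floats(0, 5), k_p=rates,
        delta_tsr=st.floats(0, 2), delta_tlr=st.floats(0, 2),
        a=st.floats(0, 1e-2), b=st.floats(0, 1e-2),
        tau_d=st.floats(0, 1.0), dna0=st.floats(0, 20),
    )
    def test_resource_boxing_and_monotonicity(
        self, k_r, delta_r, k_p, delta_tsr, delta_tlr, a, b, tau_d, dna0
    ):
        """Resources stay in [0,1] and never increase; mature protein and
        total protein production never decrease."""
        p = KineticParams(
            k_r=k_r, K_r=3.7, delta_r=delta_r, k_p=k_p, K_p=700.0,
            k_mat=2.15, delta_TsR=delta_tsr, delta_TlR=delta_tlr,
            K_l=1e-6, a=a, b=b, tau_d=tau_d, tau_l=0.0,
        )
        traj = simulate(p, "V1", dna0=dna0, t_grid=np.linspace(0, 4, 33))
        Y = traj.fine_states
        eps = 1e-9
        for j in (1, 2):  # TsR, TlR
            assert np.all(Y[:, j] >= -eps) and np.all(Y[:, j] <= 1 + eps)
            assert np.all(np.diff(Y[:, j]) <= eps)
        # monotone up to integration-error scale of each series
        tol_mat = eps + 1e-7 * np.max(Y[:, 4])
        assert np.all(np.diff(Y[:, 4]) >= -tol_mat)        # P_mat
        total = Y[:, 3] + Y[:, 4]
        tol_tot = eps + 1e-7 * np.max(total)
        assert np.all(np.diff(total) >= -tol_tot)          # total produced
        assert np.all(Y[:, 0] >= 0.0)


class TestMaxRates:
    def test_zero_trajectory(self, bulk_params):
        p = bulk_params.replace(k_r=0.0)
        traj = simulate(p, "V1", dna0=0.0, t_grid=np.linspace(0, 2, 21))
        (vtx, ttx), (vtl, ttl) = max_rates(traj)
        assert (vtx, ttx) == (0.0, 0.0)
        assert (vtl, ttl) == (0.0, 0.0)

    def test_transcription_peaks_at_start_translation_later(self, bulk_params):
        traj = simulate(bulk_params.replace(tau_l=0.0), "V1", dna0=3.75,
                        t_grid=np.linspace(0, 8, 97))
        (vtx, ttx), (vtl, ttl) = max_rates(traj)
        assert ttx == 0.0
        assert vtx == pytest.approx(2894.0 * 3.75 / (3.67 + 3.75), rel=1e-9)
        assert 0.0 < ttl < 8.0
        # brute-force scan of the translation flux on a dense grid
        i = np.argmax(traj.fine_vtl)
        assert vtl == pytest.approx(float(traj.fine_vtl[i]))
        assert ttl == pytest.approx(float(traj.fine_time[i]))

    def test_too_few_points_rejected(self, bulk_params):
        traj = simulate(bulk_params, "V1", dna0=1.0,
                        t_grid=np.linspace(0, 1, 11))
        traj2 = type(traj)(
            time=traj.time[:2], dna=traj.dna, rna0=traj.rna0,
            states=traj.states[:2], observed_rna=traj.observed_rna[:2],
            observed_protein=traj.observed_protein[:2],
            params=traj.params, variant=traj.variant,
        )
        with pytest.raises(ValueError):
            max_rates(traj2)


def test_trajectory_frame_schema(bulk_params):
    traj = simulate(bulk_params, "V1", dna0=3.75, t_grid=np.linspace(0, 2, 13))
    df = traj.to_frame()
    assert list(df.columns) == [
        "time_h", "dna_nM", "rna_nM", "tsr", "tlr", "protein_dark_nM",
        "protein_mat_nM", "observed_rna_nM", "observed_protein_nM",
    ]
    assert len(df) == 13
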