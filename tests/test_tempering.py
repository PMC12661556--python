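"""Tempering engines: acceptance algebra, detailed balance, weights, REST2."""

import math

import numpy as np
import pytest

from soltemper.hamiltonian import EnergyDecomposition, reduced_energy, scaled_energy
from soltemper.ladder import LadderSpec, Rung, build_ladder
from soltemper.tempering import (
    TemperState,
    TemperingSchedule,
    attempt_move,
    delta_rung,
    estimate_weights_from_records,
    rest2_pair_delta,
    run_tempering,
    update_weights_averaged,
    update_weights_on_the_fly,
)
from soltemper.toysim import IntegratorConfig, ToySystem, ideal_weights


def _rung(idx, t, t_ref=300.0):
    return Rung(index=idx, temperature=t, beta=1.0 / t, lam=t_ref / t)


REF = _rung(0, 300.0)


def _random_decomps(rng, n):
    vals = rng.normal(0.0, 50.0, size=(n, 4))
    return [EnergyDecomposition(*row) for row in vals]


class TestDeltaRung:
    def test_same_rung_is_zero(self):
        d = EnergyDecomposition(10.0, 1.0, -5.0, -40.0)
        assert delta_rung(d, REF, REF, REF, [0.0], "sst2") == 0.0

    def test_st_equal_betas_leaves_only_weights(self):
        d = EnergyDecomposition(10.0, 1.0, -5.0, -40.0)
        m = _rung(0, 300.0)
        n = _rung(1, 300.0)
        w = [0.2, 0.9]
        assert delta_rung(d, m, n, REF, w, "st") == pytest.approx(0.7, abs=1e-14)

    def test_nonadjacent_rejected(self):
        d = EnergyDecomposition(1.0)
        with pytest.raises(ValueError, match="illegal move"):
            delta_rung(d, _rung(0, 300.0), _rung(2, 400.0), REF, [0, 0, 0], "sst2")

    def test_sst2_closed_form_matches_hamiltonian_route(self, rng):
        """Δ = (β_m−β_n)·epp1 + (√(β_ref β_m)−√(β_ref β_n))·epw + Δw,
        identically equal to −β_ref·[E_n − E_m] + Δw, to 1e-12."""
        m = _rung(0, 300.0)
        n = _rung(1, 322.9)
        w = [0.1, -0.3]
        for d in _random_decomps(rng, 1000):
            closed = (
                (m.beta - n.beta) * d.epp1
                + (math.sqrt(REF.beta * m.beta) - math.sqrt(REF.beta * n.beta)) * d.epw
                + (w[1] - w[0])
            )
            via_h = (
                -REF.beta
                * (scaled_energy(d, n, REF, "sst2") - scaled_energy(d, m, REF, "sst2"))
                + (w[1] - w[0])
            )
            got = delta_rung(d, m, n, REF, w, "sst2")
            assert got == pytest.approx(closed, abs=1e-12 * max(1.0, abs(closed)))
            assert got == pytest.approx(via_h, abs=1e-12 * max(1.0, abs(via_h)))

    @pytest.mark.parametrize("method", ["st", "sst1", "sst2"])
    def test_antisymmetry(self, rng, method):
        m = _rung(0, 280.0)
        n = _rung(1, 300.0)
        w = [0.4, -0.2]
        for d in _random_decomps(rng, 200):
            fwd = delta_rung(d, m, n, REF, w, method)
            bwd = delta_rung(d, n, m, REF, w, method)
            assert fwd == pytest.approx(-bwd, abs=1e-12 * max(1.0, abs(fwd)))

    def test_sst1_solvent_energy_cancels(self, rng):
        """E_ww never enters the SST1 acceptance (it is held at β_ref)."""
        m = _rung(0, 300.0)
        n = _rung(1, 347.5)
        d1 = EnergyDecomposition(5.0, 1.0, -3.0, -100.0)
        d2 = EnergyDecomposition(5.0, 1.0, -3.0, 250.0)
        w = [0.0, 0.0]
        assert delta_rung(d1, m, n, REF, w, "sst1") == pytest.approx(
            delta_rung(d2, m, n, REF, w, "sst1"), rel=1e-12
        )


class TestAttemptMove:
    def _state(self, ladder):
        return TemperState.fresh(ladder)

    def test_determinism(self, cln_ladder):
        d = EnergyDecomposition(100.0, 0.0, -50.0, -200.0)
        recs = []
        for _ in range(2):
            state = self._state(cln_ladder)
            rng = np.random.default_rng(42)
            recs.append(attempt_move(state, d, cln_ladder, rng, "sst2"))
        assert recs[0] == recs[1]

    def test_zero_delta_always_accepted(self):
        # degenerate two-rung ladder at a single temperature: λ = 1 twice
        lad = build_ladder(300.0, 300.0, 300.0, 2)
        assert lad.lambdas == [1.0, 1.0]
        d = EnergyDecomposition(10.0, 0.0, -5.0, -20.0)
        rng = np.random.default_rng(0)
        n_in_range = 0
        state = TemperState.fresh(lad)
        for _ in range(200):
            rec = attempt_move(state, d, lad, rng, "sst2")
            if rec.to_rung != rec.from_rung:
                n_in_range += 1
                assert rec.delta == 0.0 and rec.accepted
        assert n_in_range > 50  # half the proposals point inward

    def test_edge_proposals_auto_rejected(self, cln_ladder):
        d = EnergyDecomposition(0.0, 0.0, 0.0, 0.0)
        state = TemperState.fresh(cln_ladder, start_rung=0)
        rng = np.random.default_rng(1)
        saw_reject = False
        for _ in range(20):
            state.current_rung = 0
            rec = attempt_move(state, d, cln_ladder, rng, "sst2")
            if rec.to_rung == rec.from_rung == 0:
                saw_reject = True
                assert not rec.accepted and rec.delta == -math.inf
        assert saw_reject


class TestDetailedBalance:
    def test_stationary_distribution_matches_boltzmann(self):
        """Exactly enumerable 2-rung × 3-configuration chain.

        The composite kernel (configuration Metropolis sweep, then the
        engine's rung move) has the expanded-ensemble density
        π(m, x) ∝ exp(w_m − g_m(x)) as its stationary vector; the
        leading eigenvector of the exact transition matrix built from
        the implementation's acceptance probabilities must match it to
        1e-10.
        """
        t_ref = 1.0
        lad_rungs = [
            Rung(index=0, temperature=1.0, beta=1.0, lam=1.0),
            Rung(index=1, temperature=1.6, beta=1.0 / 1.6, lam=1.0 / 1.6),
        ]
        ref = lad_rungs[0]
        weights = [0.0, 0.45]
        decomps = [
            EnergyDecomposition(0.3, 0.1, -0.4, 0.2),
            EnergyDecomposition(1.1, 0.0, 0.6, -0.3),
            EnergyDecomposition(-0.5, 0.2, 0.1, 0.4),
        ]
        g = np.array(
            [
                [reduced_energy(d, m, ref, "sst2") for d in decomps]
                for m in lad_rungs
            ]
        )  # shape (2 rungs, 3 configs)

        n_states = 6  # state index = 3*m + x

        def config_kernel():
            p = np.zeros((n_states, n_states))
            for m in range(2):
                for x in range(3):
                    i = 3 * m + x
                    stay = 0.0
                    for x2 in range(3):
                        if x2 == x:
                            continue
                        acc = min(1.0, math.exp(-(g[m, x2] - g[m, x])))
                        p[i, 3 * m + x2] = 0.5 * acc
                        stay += 0.5 * (1.0 - acc)
                    p[i, i] = stay
            return p

        def rung_kernel():
            p = np.zeros((n_states, n_states))
            for m in range(2):
                for x in range(3):
                    i = 3 * m + x
                    stay = 0.0
                    for dm in (-1, 1):
                        n = m + dm
                        if n < 0 or n > 1:
                            stay += 0.5  # out-of-range proposal auto-rejected
                            continue
                        delta = delta_rung(
                            decomps[x], lad_rungs[m], lad_rungs[n], ref, weights, "sst2"
                        )
                        acc = min(1.0, math.exp(delta))
                        p[i, 3 * n + x] = 0.5 * acc
                        stay += 0.5 * (1.0 - acc)
                    p[i, i] += stay
            return p

        P = config_kernel() @ rung_kernel()
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-14)
        evals, evecs = np.linalg.eig(P.T)
        k = np.argmin(np.abs(evals - 1.0))
        pi = np.real(evecs[:, k])
        pi = pi / pi.sum()
        target = np.array(
            [math.exp(weights[m] - g[m, x]) for m in range(2) for x in range(3)]
        )
        target /= target.sum()
        assert np.max(np.abs(pi - target)) < 1e-10


class TestWeightEstimators:
    def test_on_the_fly_st_direct_substitution(self):
        """(β_{m+1} − β_m)·⟨E⟩_m = 2e−4 · 500 = 0.1."""
        beta0 = 1.0 / 300.0
        beta1 = beta0 - 2e-4
        rungs = (
            Rung(index=0, temperature=1 / beta0, beta=beta0, lam=1.0),
            Rung(index=1, temperature=1 / beta1, beta=beta1, lam=beta1 / beta0),
        )
        lad = LadderSpec(
            t_min=rungs[0].temperature,
            t_max=rungs[1].temperature,
            t_ref=rungs[0].temperature,
            n_rungs=2,
            n_below_ref=0,
            rungs=rungs,
        )
        state = TemperState.fresh(lad)
        state.accumulate(0, EnergyDecomposition(500.0, 0.0, 0.0, 0.0))
        update_weights_on_the_fly(state, lad, "st")
        assert state.weights[1] == pytest.approx(-0.1, abs=1e-12)

    def test_on_the_fly_equal_betas_zero_increment(self):
        lad = build_ladder(300.0, 300.0, 300.0, 2)
        state = TemperState.fresh(lad)
        state.accumulate(0, EnergyDecomposition(500.0, 1.0, -3.0, 7.0))
        update_weights_on_the_fly(state, lad, "st")
        assert state.weights[1] == pytest.approx(0.0, abs=1e-14)

    def test_on_the_fly_requires_samples(self, cln_ladder):
        state = TemperState.fresh(cln_ladder)
        with pytest.raises(ValueError, match="insufficient statistics"):
            update_weights_on_the_fly(state, cln_ladder, "sst2")

    def test_averaged_st_with_exact_means_recovers_gaussian_weights(self):
        """Exact ⟨E⟩_m = d/(2β_m) gives w_m = (d/2)·ln(β_m/β_ref) to 1e-3.

        Small solute (d = 2) keeps the trapezoid error of the symmetric
        estimator below the tolerance on this ladder.
        """
        lad = build_ladder(280.0, 540.0, 300.0, 10, n_below_ref=1)
        state = TemperState.fresh(lad)
        for r in lad.rungs:
            # plain tempering samples exp(−β_m U): ⟨½x²⟩ = 1/(2β_m) per dof
            state.accumulate(
                r.index, EnergyDecomposition(2.0 / (2.0 * r.beta), 0.0, 0.0, 0.0)
            )
        update_weights_averaged(state, lad, "st")
        beta_ref = lad.ref_rung.beta
        for r in lad.rungs:
            expected = (2.0 / 2.0) * math.log(r.beta / beta_ref)
            assert state.weights[r.index] == pytest.approx(expected, abs=1e-3)

    def test_averaged_identical_means_equal_betas_zero(self):
        lad = build_ladder(300.0, 300.0, 300.0, 2)
        state = TemperState.fresh(lad)
        d = EnergyDecomposition(5.0, 0.0, -2.0, 1.0)
        state.accumulate(0, d)
        state.accumulate(1, d)
        update_weights_averaged(state, lad, "st")
        assert state.weights[1] == pytest.approx(0.0, abs=1e-14)

    def test_averaged_flags_one_sided_links(self, cln_ladder):
        state = TemperState.fresh(cln_ladder)
        for i in range(5):  # only the cold half has samples
            state.accumulate(i, EnergyDecomposition(100.0, 0.0, -10.0, -50.0))
        update_weights_averaged(state, cln_ladder, "sst2")
        assert 4 in state.fallback_links  # link 4→5 had samples on one side
        assert 7 in state.fallback_links  # link 7→8 had none


class TestRest2PairDelta:
    def test_identical_configurations_are_neutral(self):
        m = _rung(0, 300.0)
        n = _rung(1, 400.0)
        d = EnergyDecomposition(10.0, 3.0, -6.0, -90.0)
        assert rest2_pair_delta(d, d, m, n, REF) == pytest.approx(0.0, abs=1e-14)

    def test_antisymmetry(self, rng):
        """The reverse swap (configurations exchanged, rungs kept) negates Δ."""
        m = _rung(0, 300.0)
        n = _rung(1, 400.0)
        for _ in range(100):
            dm, dn = _random_decomps(rng, 2)
            fwd = rest2_pair_delta(dm, dn, m, n, REF)
            rev = rest2_pair_delta(dn, dm, m, n, REF)
            assert fwd == pytest.approx(-rev, abs=1e-12 * max(1.0, abs(fwd)))
            # relabelling both replicas and configurations changes nothing
            assert rest2_pair_delta(dn, dm, n, m, REF) == pytest.approx(
                fwd, abs=1e-12 * max(1.0, abs(fwd))
            )

    def test_dual_route_against_closed_form(self, rng):
        """Four-energy route equals the pairwise closed form
        (β_n−β_m)[ΔE_pp + √β_ref/(√β_m+√β_n)·ΔE_pw] with
        ΔE = E(X_n) − E(X_m), to 1e-12."""
        m = _rung(0, 300.0)
        n = _rung(1, 347.5)
        for _ in range(100):
            dm, dn = _random_decomps(rng, 2)
            got = rest2_pair_delta(dm, dn, m, n, REF)
            d_pp = dn.solute - dm.solute
            d_pw = dn.epw - dm.epw
            closed = (n.beta - m.beta) * (
                d_pp
                + math.sqrt(REF.beta) / (math.sqrt(m.beta) + math.sqrt(n.beta)) * d_pw
            )
            assert got == pytest.approx(closed, abs=1e-12 * max(1.0, abs(closed)))


class TestRunTempering:
    def test_zero_segments_gives_empty_log(self, harmonic_system, cln_ladder):
        sched = TemperingSchedule(n_segments=0)
        integ = IntegratorConfig(t_ref=300.0, seed=1)
        log = run_tempering(harmonic_system, cln_ladder, sched, integ)
        assert log.empty()
        assert log.header["method"] == "sst2"

    def test_reproducible_from_seed(self, harmonic_system, cln_ladder):
        sched = TemperingSchedule(exchange_interval=20, n_segments=100)
        logs = [
            run_tempering(
                harmonic_system,
                cln_ladder,
                sched,
                IntegratorConfig(timestep=0.1, t_ref=300.0, seed=9),
            )
            for _ in range(2)
        ]
        assert logs[0].records.equals(logs[1].records)
        assert logs[0].weights_history == logs[1].weights_history

    def test_degenerate_ladder_walks_freely(self):
        """Equal-λ two-rung ladder: every in-range move accepted, ~50/50."""
        lad = build_ladder(300.0, 300.0, 300.0, 2)
        sys_ = ToySystem(d_solute=2, d_solvent=2)
        sched = TemperingSchedule(
            exchange_interval=10, n_segments=400, weight_update="fixed"
        )
        log = run_tempering(
            sys_, lad, sched, IntegratorConfig(timestep=0.1, t_ref=300.0, seed=3)
        )
        rec = log.records
        in_range = rec[rec.proposed_rung != rec.rung_index]
        assert (in_range.accepted == 1).all()
        occupancy = rec.rung_index.mean()
        assert 0.35 < occupancy < 0.65

    def test_forward_backward_balance_with_converged_weights(
        self, harmonic_system, cln_ladder
    ):
        """⟨Δ_{m,m+1}⟩ over rung-m frames equals ⟨Δ_{m+1,m}⟩ over
        rung-(m+1) frames within 3 SE once the weights are exact —
        the defining symmetric-typical-delta property."""
        w = ideal_weights(harmonic_system, cln_ladder.lambdas, 300.0)
        sched = TemperingSchedule(
            exchange_interval=40,
            n_segments=3000,
            weight_update="fixed",
            initial_weights=tuple(w),
        )
        log = run_tempering(
            harmonic_system,
            cln_ladder,
            sched,
            IntegratorConfig(timestep=0.1, t_ref=300.0, seed=17),
        )
        rec = log.records.iloc[300:]
        m, n = 4, 5
        ref = cln_ladder.ref_rung

        def deltas(frames, a, b):
            out = []
            for row in frames.itertuples(index=False):
                d = EnergyDecomposition(row.epp1, row.epp2, row.epw, row.eww)
                out.append(
                    delta_rung(
                        d, cln_ladder.rungs[a], cln_ladder.rungs[b], ref, w, "sst2"
                    )
                )
            return np.array(out)

        fwd = deltas(rec[rec.rung_index == m], m, n)
        bwd = deltas(rec[rec.rung_index == n], n, m)
        se = math.hypot(
            np.std(fwd, ddof=1) / math.sqrt(len(fwd)),
            np.std(bwd, ddof=1) / math.sqrt(len(bwd)),
        )
        assert abs(np.mean(fwd) - np.mean(bwd)) < 3.0 * se + 0.05

    def test_double_well_tempering_enhances_sampling(self):
        """Tempering crosses the barrier; an equal-length fixed-λ run
        stays in its starting well (seeded, 10 kT barrier)."""
        sys_ = ToySystem(
            d_solute=1,
            potential_kind="double_well",
            barrier=10.0,
            well_separation=2.0,
        )
        lad = build_ladder(1.0, 10.0 / 3.0, 1.0, 6)
        integ = IntegratorConfig(timestep=0.02, friction=1.0, t_ref=1.0, seed=12)
        sched = TemperingSchedule(
            exchange_interval=50, n_segments=1500, weight_update="averaged",
            weight_refresh_interval=100,
        )
        log = run_tempering(sys_, lad, sched, integ)
        x = log.records.order_param.to_numpy()
        assert (x > 0.5).any() and (x < -0.5).any()

        fixed = TemperingSchedule(
            exchange_interval=50, n_segments=1500, weight_update="fixed",
        )
        lad1 = build_ladder(1.0, 1.0, 1.0, 2)  # λ = 1 throughout
        log_fixed = run_tempering(sys_, lad1, fixed, integ)
        xf = log_fixed.records.order_param.to_numpy()
        assert not ((xf > 0.5).any() and (xf < -0.5).any())

    def test_weight_estimate_from_records_matches_oracle(
        self, harmonic_system, cln_ladder
    ):
        """Averaged weights recomputed from a log converge on the
        analytic (d/2)·ln λ_m offsets."""
        sched = TemperingSchedule(
            exchange_interval=40, n_segments=3000, weight_update="averaged",
            weight_refresh_interval=200,
        )
        log = run_tempering(
            harmonic_system,
            cln_ladder,
            sched,
            IntegratorConfig(timestep=0.1, t_ref=300.0, seed=21),
        )
        w = estimate_weights_from_records(log.records, cln_ladder, "sst2")
        ideal = ideal_weights(harmonic_system, cln_ladder.lambdas, 300.0)
        ideal -= ideal[cln_ladder.ref_index]
        assert np.max(np.abs(w - ideal)) < 0.15
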