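"""Forward simulators: parameterization, limits, and distributional checks."""

import math

import numpy as np
import pytest

from gazeflux.data_model import DwellSequence
from gazeflux.fokker_planck import solve_constant
from gazeflux.simulators import (
    AddmParams,
    HybridPost,
    PdgParams,
    reparameterize_addm,
    simulate_addm_trial,
    simulate_hybrid_trial,
    simulate_pdg_trial,
)

from _oracles import original_addm_trial


def long_dwells(seed, first=0, n=60, mu=-0.8, sd=0.5):
    rng = np.random.default_rng(seed)
    durs = rng.lognormal(mu, sd, n)
    return DwellSequence(items=(np.arange(n) + first) % 2, durations=durs)


class TestReparameterization:
    def test_published_conversion(self):
        kappa, B = reparameterize_addm(0.0002, 0.02, 1.0, 0.001)
        assert round(kappa, 4) == 0.3162
        assert round(B, 4) == 1.5811

    def test_identity_when_unit_noise_and_step(self):
        kappa, B = reparameterize_addm(0.3, 1.0, 1.7, 1.0)
        assert kappa == pytest.approx(0.3)
        assert B == pytest.approx(1.7)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            reparameterize_addm(0.0002, 0.0, 1.0, 0.001)


class TestAddmTrial:
    def test_full_discount_equal_values_symmetric(self):
        """theta = 1 with equal ratings gives zero drift everywhere:
        P(left) within the binomial CI of 0.5."""
        p = AddmParams(theta=1.0)
        rng = np.random.default_rng(1)
        n = 2000
        left = sum(
            simulate_addm_trial(p, "addm_mult", 4, 4, long_dwells(i), rng).choice
            == "left"
            for i in range(n)
        )
        assert abs(left / n - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_total_discount_gaze_held_left(self):
        """theta = 0 and a large kappa with gaze pinned to a valued left
        item drives every choice left."""
        p = AddmParams(kappa=3.0, theta=0.0)
        dwells = DwellSequence(items=[0], durations=[30.0])
        rng = np.random.default_rng(2)
        for _ in range(100):
            st = simulate_addm_trial(p, "addm_mult", 5, 5, dwells, rng)
            assert st.choice == "left"

    def test_rt_decomposition_and_trace(self):
        p = AddmParams()
        st = simulate_addm_trial(
            p, "addm_mult", 4, 2, long_dwells(3), np.random.default_rng(3)
        )
        assert st.rt == pytest.approx(st.decision_time + p.mu_nd)
        assert st.fixations[-1].t_off >= st.rt
        # pre-commitment gaze alternates
        pre = [f.item for f in st.fixations if f.t_off <= st.bound_crossing_time]
        assert all(a != b for a, b in zip(pre, pre[1:]))

    def test_equivalence_with_original_parameterization(self):
        """The unit-variance parameterization (kappa = 0.3162, B = 1.5811,
        theta = 0.3) reproduces the mean RT of the classic per-millisecond
        accumulator (d = 0.0002/ms, sigma = 0.02, bounds +-1) with equal
        dwell sharing and tnd = 0.355 s."""
        rng = np.random.default_rng(4)
        n = 1500
        durs = [0.4] * 60
        items = np.arange(60) % 2
        rts_orig = []
        for _ in range(n):
            _, dtime = original_addm_trial(
                0.0002, 0.02, 0.3, 5, 5, durs, items, rng)
            if not math.isnan(dtime):
                rts_orig.append(dtime + 0.355)
        p = AddmParams(kappa=0.3162, B=1.5811, theta=0.3, mu_nd=0.355)
        dwells = DwellSequence(items=items, durations=durs)
        rng2 = np.random.default_rng(5)
        rts_new = [
            simulate_addm_trial(p, "addm_mult", 5, 5, dwells, rng2).rt
            for _ in range(n)
        ]
        se = math.hypot(np.std(rts_orig) / math.sqrt(len(rts_orig)),
                        np.std(rts_new) / math.sqrt(n))
        assert abs(np.mean(rts_orig) - np.mean(rts_new)) < 3.5 * se

    def test_theta_one_matches_constant_drift_fp(self):
        """With theta = 1 the aDDM is a constant-drift diffusion: the MC
        crossing-time distribution matches the FP solution (KS < 0.02)."""
        p = AddmParams(theta=1.0)
        mu = p.kappa * (7 - 3)  # r_left=3, r_right=7 -> drift toward right
        rng = np.random.default_rng(6)
        n = 4000
        times, sides = [], []
        for i in range(n):
            st = simulate_addm_trial(p, "addm_mult", 3, 7, long_dwells(i + 10), rng)
            times.append(st.decision_time)
            sides.append(st.choice == "right")
        d = solve_constant(mu, 1.0, p.B, dt=5e-4)
        cdf_grid = np.cumsum(d.f_upper + d.f_lower) * d.dt
        emp = np.sort(times)
        theo = np.interp(emp, d.t, cdf_grid)
        ks = np.max(np.abs(theo - (np.arange(1, n + 1) / n)))
        assert ks < 0.04  # MC noise at n=4000 plus Euler step bias
        assert abs(np.mean(sides) - d.p_upper) < 3 * math.sqrt(0.25 / n)


class TestPdgTrial:
    def test_zero_gamma_zero_delta_symmetric(self):
        p = PdgParams(gamma=0.0)
        rng = np.random.default_rng(7)
        n = 2000
        right = sum(
            simulate_pdg_trial(p, 4, 4, long_dwells(i), rng).choice == "right"
            for i in range(n)
        )
        assert abs(right / n - 0.5) < 3 * math.sqrt(0.25 / n)

    def test_choice_and_dt_match_closed_form(self):
        """gamma = 0 with fixed mu, B: P(choice) and mean decision time
        match the logistic / tanh first-passage formulas within MC error."""
        p = PdgParams(kappa=0.25, B=1.2, gamma=0.0)
        mu = p.kappa * (6 - 2)
        rng = np.random.default_rng(8)
        n = 4000
        rights, dts = [], []
        for i in range(n):
            st = simulate_pdg_trial(p, 2, 6, long_dwells(i), rng)
            rights.append(st.choice == "right")
            dts.append(st.decision_time)
        p_theo = 1 / (1 + math.exp(-2 * mu * p.B))
        dt_theo = (p.B / mu) * math.tanh(mu * p.B)
        assert abs(np.mean(rights) - p_theo) < 3 * math.sqrt(p_theo * (1 - p_theo) / n)
        assert abs(np.mean(dts) - dt_theo) < 3 * np.std(dts) / math.sqrt(n) + 2e-3

    def test_deterministic_latency_ordering(self):
        """With sigma_e = 0, mu_e = 0.35 and a constant motor delay of 0.5 s
        the gaze shift always completes before the report, so the last
        pre-report fixation is always the chosen item."""
        p = PdgParams(mu_e=0.35, sigma_e=0.0, mu_nd=0.8, sigma_nd=0.0, tau_s=0.3)
        rng = np.random.default_rng(9)
        for i in range(200):
            st = simulate_pdg_trial(p, 3, 5, long_dwells(i), rng)
            pre = [f for f in st.fixations if f.t_on < st.rt]
            assert pre[-1].item == st.choice

    def test_attention_causally_inert(self):
        """Permuting the dwell sequence leaves choice and decision time
        unchanged under the same noise stream."""
        p = PdgParams()
        a = simulate_pdg_trial(p, 2, 6, long_dwells(1, first=0),
                               np.random.default_rng(11))
        b = simulate_pdg_trial(p, 2, 6, long_dwells(99, first=1),
                               np.random.default_rng(11))
        assert a.choice == b.choice
        assert a.decision_time == pytest.approx(b.decision_time)

    def test_gaze_at_crossing_unbiased(self):
        """P(gaze on the chosen item at the moment of bound crossing) is
        within the binomial CI of 0.5: attention does not cause the choice."""
        p = PdgParams()
        rng = np.random.default_rng(12)
        n = 2000
        hits = 0
        for i in range(n):
            dwells = long_dwells(i + 500)
            st = simulate_pdg_trial(p, 3, 5, dwells, rng)
            edges = np.concatenate(([0.0], np.cumsum(dwells.durations)))
            idx = np.searchsorted(edges, st.bound_crossing_time, side="right") - 1
            idx = min(idx, dwells.items.size - 1)
            item = "left" if dwells.items[idx] == 0 else "right"
            hits += item == st.choice
        assert abs(hits / n - 0.5) < 3 * math.sqrt(0.25 / n)


class TestHybridTrial:
    def test_infinite_shift_latency_reduces_to_pure_addm(self):
        """mu_e -> infinity disables the post-commitment shift: the gaze
        trace equals the pure aDDM trace under the same rng stream."""
        params = AddmParams()
        post = HybridPost(tau_s=0.0, mu_e=1e9, sigma_e=0.0)
        dwells = long_dwells(13)
        a = simulate_hybrid_trial(params, 4, 2, dwells,
                                  np.random.default_rng(14), post=post)
        b = simulate_addm_trial(params, "addm_mult", 4, 2, dwells,
                                np.random.default_rng(14))
        assert a.choice == b.choice
        assert a.fixations == b.fixations

    def test_default_post_parameters(self):
        post = HybridPost()
        assert (post.tau_s, post.mu_e, post.sigma_e) == (0.25, 0.2, 0.05)

    def test_shift_raises_last_fixation_consistency(self):
        """With a deterministic early shift, the chosen item is the final
        pre-report fixation more often than in the matched pure-aDDM run."""
        params = AddmParams(mu_nd=0.5)
        post = HybridPost(tau_s=0.0, mu_e=0.2, sigma_e=0.0)
        n = 400
        hit_h = hit_a = 0
        for i in range(n):
            dwells = long_dwells(i + 900)
            h = simulate_hybrid_trial(params, 4, 3, dwells,
                                      np.random.default_rng(i), post=post)
            a = simulate_addm_trial(params, "addm_mult", 4, 3, dwells,
                                    np.random.default_rng(i))
            pre_h = [f for f in h.fixations if f.t_on < h.rt]
            pre_a = [f for f in a.fixations if f.t_on < a.rt]
            hit_h += pre_h[-1].item == h.choice
            hit_a += pre_a[-1].item == a.choice
        assert hit_h > hit_a
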