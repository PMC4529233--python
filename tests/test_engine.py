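"""Metropolis rule, replica swaps, trajectory bookkeeping, campaign selection."""

import logging
import math

import numpy as np
import pytest

import pepmc
from pepmc.backends import ReplayBackend, ScoreSample, flat_landscape
from pepmc.engine import (
    MOVE_MUTATION,
    MOVE_SWAP,
    ReplicaState,
    Trajectory,
    attempt_swap,
    metropolis_accept,
    run_campaign,
    run_remc,
    select_best_final,
)
from pepmc.sequence import make_peptide


class TestMetropolis:
    def test_equal_and_lower_scores_always_accepted(self, rng):
        for _ in range(200):
            assert metropolis_accept(-10.0, -10.0, 0.6, rng)
            assert metropolis_accept(-10.0, -10.0 - 50 * rng.random(), 0.2, rng)

    def test_uphill_acceptance_matches_closed_form(self, rng):
        """ΔS=+0.6 at kBT=0.6: empirical rate ≈ exp(−1)."""
        n = 20_000
        hits = sum(metropolis_accept(-10.0, -9.4, 0.6, rng) for _ in range(n))
        p = math.exp(-1.0)
        assert abs(hits / n - p) < 4 * math.sqrt(p * (1 - p) / n)

    def test_acceptance_monotone_in_temperature(self, rng):
        """For fixed ΔS>0, hotter replicas accept at least as often."""
        n = 20_000
        rates = []
        for kBT in (0.2, 0.4, 0.6):
            r = np.random.default_rng(7)
            rates.append(
                sum(metropolis_accept(-10.0, -9.7, kBT, r) for _ in range(n)) / n
            )
        assert rates == sorted(rates)
        del rng

    def test_rejects_nonfinite_scores_and_bad_temperature(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(float("inf"), -1.0, 0.6, rng)
        with pytest.raises(ValueError):
            metropolis_accept(-1.0, -2.0, 0.0, rng)

    def test_consumes_exactly_one_uniform(self):
        """Draw order is decision-independent: one uniform per call."""
        a = np.random.default_rng(3)
        b = np.random.default_rng(3)
        metropolis_accept(-10.0, -12.0, 0.6, a)  # downhill
        metropolis_accept(-10.0, -9.0, 0.6, b)  # uphill
        assert a.random() == b.random()


def _state(score, kBT, seq="AAAA", idx=0):
    return ReplicaState(
        peptide=make_peptide(seq), score=score, kBT=kBT, replica_index=idx
    )


class TestSwap:
    def test_equal_scores_always_accepted(self, rng):
        for _ in range(200):
            assert attempt_swap(_state(-10, 0.2), _state(-10, 0.6), rng)

    def test_better_score_moves_cold_always_accepted(self, rng):
        """Hot replica holding the lower score swaps with probability 1."""
        for _ in range(200):
            a = _state(-9.0, 0.2, "AAAA")
            b = _state(-12.0, 0.6, "GGGG")
            assert attempt_swap(a, b, rng)
            assert a.peptide.sequence == "GGGG" and a.score == -12.0
            assert b.peptide.sequence == "AAAA" and b.score == -9.0
            assert (a.kBT, b.kBT) == (0.2, 0.6), "kBT slots are kept"

    def test_unfavorable_swap_rate_matches_closed_form(self, rng):
        """Cold better by 0.3 on the 0.2/0.6 rungs: rate = exp(−1)."""
        n = 20_000
        hits = sum(
            attempt_swap(_state(-10.3, 0.2), _state(-10.0, 0.6), rng)
            for _ in range(n)
        )
        p = math.exp(-1.0)
        assert abs(hits / n - p) < 4 * math.sqrt(p * (1 - p) / n)

    def test_same_temperature_pair_rejected(self, rng):
        with pytest.raises(ValueError):
            attempt_swap(_state(-10, 0.4), _state(-11, 0.4), rng)


class TestRunRemc:
    def test_trajectory_record_counts_for_reference_protocol(self):
        """3 replicas × 100 steps: 3×101 state records plus 100 swap records."""
        backend = flat_landscape(8, -11.0, noise_sd=1.0)
        traj = run_remc(
            make_peptide("AAAAAAAA"),
            [0.2, 0.4, 0.6],
            100,
            backend,
            pepmc.DockingConfig(),
            seed=1,
        )
        non_swap = [r for r in traj.records if r[4] != MOVE_SWAP]
        swaps = [r for r in traj.records if r[4] == MOVE_SWAP]
        assert len(non_swap) == 3 * 101
        assert len(swaps) == 100
        per_step = {}
        for r in traj.records:
            if r[4] == MOVE_MUTATION:
                per_step.setdefault(r[1], set()).add(r[2])
        assert all(v == {0, 1, 2} for v in per_step.values())

    def test_same_seed_bitwise_reproducible(self):
        backend = flat_landscape(4, -10.0, noise_sd=1.0)
        kwargs = dict(
            start=make_peptide("AAAA"),
            ladder=[0.2, 0.6],
            n_steps=50,
            backend=backend,
            config=pepmc.DockingConfig(),
            seed=9,
        )
        assert run_remc(**kwargs).records == run_remc(**kwargs).records

    def test_greedy_limit_is_downhill_only(self, small_landscape):
        """Noise 0 and kBT→0⁺: the recorded score never increases."""
        traj = run_remc(
            make_peptide("AAA", small_landscape.alphabet),
            [1e-9],
            300,
            small_landscape,
            pepmc.DockingConfig(),
            seed=2,
        )
        scores = [r[6] for r in traj.records if r[4] != MOVE_SWAP]
        assert all(b <= a + 1e-12 for a, b in zip(scores, scores[1:]))

    def test_zero_steps_returns_scored_start(self, caplog):
        backend = flat_landscape(4, -10.0, noise_sd=0.0)
        with caplog.at_level(logging.WARNING):
            traj = run_remc(
                make_peptide("AAAA"),
                [0.2, 0.6],
                0,
                backend,
                pepmc.DockingConfig(),
                seed=0,
            )
        assert "n_steps=0" in caplog.text
        sel = select_best_final(traj)
        assert sel.peptide.sequence == "AAAA" and sel.score == -10.0

    def test_backend_failure_is_a_rejection_not_a_crash(self, caplog):
        # single replica: init scores -10, then fail / accept -12 / fail
        backend = ReplayBackend([-10.0, "fail", -12.0, "fail"])
        with caplog.at_level(logging.WARNING):
            traj = run_remc(
                make_peptide("AAAA"),
                [0.6],
                3,
                backend,
                pepmc.DockingConfig(),
                seed=4,
            )
        assert "backend failure" in caplog.text
        rows = [r for r in traj.records if r[4] == MOVE_MUTATION]
        assert [r[7] for r in rows] == [False, True, False]
        assert rows[0][5] == "AAAA" and rows[0][6] == -10.0
        assert rows[1][6] == -12.0
        assert rows[2][6] == -12.0, "failed proposal keeps the incumbent state"

    def test_ladder_validation(self):
        backend = flat_landscape(4, -10.0)
        p = make_peptide("AAAA")
        for bad in ([], [0.2, 0.2], [-0.1, 0.4]):
            with pytest.raises(ValueError):
                run_remc(p, bad, 5, backend, pepmc.DockingConfig(), seed=0)


class TestCampaign:
    def test_selects_lowest_final_score(self):
        traj = Trajectory(run_index=0, ladder=(0.2, 0.4, 0.6), n_steps=1,
                          seed_entropy=(0,))
        final = {0.2: ("AAAA", -12.0), 0.4: ("GGGG", -16.0), 0.6: ("CCCC", -14.0)}
        for idx, (kBT, (seq, score)) in enumerate(final.items()):
            traj.records.append((0, 1, idx, kBT, MOVE_MUTATION, seq, score, True))
        sel = select_best_final(traj)
        assert sel.peptide.sequence == "GGGG" and sel.score == -16.0

    def test_tie_breaks_prefer_colder_then_lexicographic(self):
        traj = Trajectory(run_index=0, ladder=(0.2, 0.6), n_steps=1,
                          seed_entropy=(0,))
        traj.records.append((0, 1, 0, 0.6, MOVE_MUTATION, "GGGG", -16.0, True))
        traj.records.append((0, 1, 1, 0.2, MOVE_MUTATION, "CCCC", -16.0, True))
        sel = select_best_final(traj)
        assert sel.kBT == 0.2 and sel.peptide.sequence == "CCCC"

    def test_campaign_returns_one_selection_per_run(self):
        backend = flat_landscape(4, -10.0, noise_sd=1.0)
        result = run_campaign(
            9, make_peptide("AAAA"), [0.2, 0.4, 0.6], 10, backend,
            pepmc.DockingConfig(), seed=6,
        )
        assert len(result.selected) == 9
        assert len(result.trajectories) == 9
        assert {t.run_index for t in result.trajectories} == set(range(9))
        assert result.best.score == min(s.score for s in result.selected)

    def test_runs_use_distinct_derived_seeds(self):
        backend = flat_landscape(4, -10.0, noise_sd=1.0)
        result = run_campaign(
            3, make_peptide("AAAA"), [0.2, 0.6], 20, backend,
            pepmc.DockingConfig(), seed=6,
        )
        t0, t1 = result.trajectories[0], result.trajectories[1]
        assert t0.records != [
            (0,) + r[1:] for r in t1.records
        ], "different runs must not replay the same stream"


class TestReplicaExchangeBenefit:
    def test_remc_escapes_decoy_basin_more_often_than_cold_chain(self):
        """Two-basin landscape with a deep decoy: REMC reaches the optimum at
        least as often as equal-budget single-temperature runs at the coldest
        kBT (50 runs each)."""

        class TwoBasin:
            alphabet = "AG"

            def score(self, p, config, rng, step_index=-1, run_index=-1):
                h = sum(r == "G" for r in p.sequence)
                if h == 6:
                    v = -11.0
                elif h == 0:
                    v = -9.2
                else:
                    v = -9.2 + 0.8 * min(h, 6 - h)
                return ScoreSample(
                    value=v, site_label=config.site_label, pose_id="x",
                    step_index=step_index, run_index=run_index,
                )

        backend = TwoBasin()
        start = make_peptide("AAAAAA", "AG")
        cfg = pepmc.DockingConfig()
        remc = run_campaign(50, start, [0.2, 0.4, 0.6], 100, backend, cfg, seed=5)
        cold = run_campaign(50, start, [0.2], 300, backend, cfg, seed=6)
        remc_hits = sum(s.peptide.sequence == "GGGGGG" for s in remc.selected)
        cold_hits = sum(s.peptide.sequence == "GGGGGG" for s in cold.selected)
        assert remc_hits >= cold_hits
        assert remc_hits >= 25, "exchange moves should rescue most runs here"
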