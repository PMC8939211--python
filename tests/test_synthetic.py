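"""The generator's statistical contracts: imbalance, segment structure,
error injection, and the inference pipeline's power and calibration."""

import collections

import numpy as np
import pytest

from sskit.core import SS8_STATES
from sskit.metrics import UNDEFINED, evaluate_residue_level, evaluate_sequence_level
from sskit.stats import guarded_test
from sskit.synthetic import (
    DEFAULT_RUN_LENGTHS,
    DEFAULT_SS8_FREQS,
    ErrorProfile,
    GeneratorConfig,
    gapped_chain_fixture,
    generate_features,
    generate_predictions,
    generate_truth,
    solve_transition_matrix,
)


class TestTransitionSolver:
    def test_default_preset_is_feasible_and_stationary(self):
        T = solve_transition_matrix(DEFAULT_SS8_FREQS, DEFAULT_RUN_LENGTHS)
        pi = np.array([DEFAULT_SS8_FREQS[s] for s in SS8_STATES])
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(pi @ T, pi, atol=1e-8)
        for j, s in enumerate(SS8_STATES):
            assert T[j, j] == pytest.approx(1 - 1 / DEFAULT_RUN_LENGTHS[s])

    def test_infeasible_combination_rejected(self):
        # a dominant class with run length 1 cannot receive enough inflow
        freqs = dict(DEFAULT_SS8_FREQS)
        runs = dict(DEFAULT_RUN_LENGTHS)
        runs["H"] = 1.0  # H leaves every step but holds 35% of mass
        with pytest.raises(ValueError, match="infeasible"):
            solve_transition_matrix(freqs, runs)


class TestGenerateTruth:
    def test_frequencies_converge_to_targets(self):
        cfg = GeneratorConfig(n_chains=10_000, length_min=30, length_max=150,
                              length_mean=90, seed=2)
        records = generate_truth(cfg)
        counts = collections.Counter("".join(r.ss8 for r in records))
        total = sum(counts.values())
        for s in SS8_STATES:
            assert counts[s] / total == pytest.approx(cfg.freqs[s], abs=0.01)

    def test_run_lengths_are_geometric(self):
        runs = dict(DEFAULT_RUN_LENGTHS)
        runs["H"] = 10.0  # self-transition 0.9 -> mean run 10
        cfg = GeneratorConfig(n_chains=3000, run_lengths=runs, seed=4)
        records = generate_truth(cfg)
        h_runs = []
        for r in records:
            n = 0
            for ch in r.ss8 + "$":
                if ch == "H":
                    n += 1
                elif n:
                    h_runs.append(n)
                    n = 0
        assert np.mean(h_runs) == pytest.approx(10.0, rel=0.1)

    def test_seed_determinism_is_byte_identical(self):
        cfg = GeneratorConfig(n_chains=50, seed=9)
        a, b = generate_truth(cfg), generate_truth(cfg)
        assert [(r.id, r.sequence, r.ss8, r.neff) for r in a] == [
            (r.id, r.sequence, r.ss8, r.neff) for r in b
        ]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GeneratorConfig(freqs={s: 0.5 for s in SS8_STATES})
        with pytest.raises(ValueError, match="run lengths"):
            GeneratorConfig(run_lengths={**DEFAULT_RUN_LENGTHS, "H": 0.5})


class TestGeneratePredictions:
    def test_perfect_recall_reproduces_truth(self, small_truth):
        preds = generate_predictions(
            small_truth, ErrorProfile(recall={s: 1.0 for s in SS8_STATES}), seed=1
        )
        report = evaluate_residue_level(small_truth, preds)
        assert report.q_accuracy == 1.0

    def test_zero_recall_class_scores_zero_agm(self, medium_truth):
        profile = ErrorProfile(recall={s: (0.0 if s == "B" else 0.9) for s in SS8_STATES})
        preds = generate_predictions(medium_truth, profile, seed=2)
        per_chain = evaluate_sequence_level(medium_truth, preds, "agm:B")
        with_b = [v for cid, v in per_chain.items() if v is not UNDEFINED]
        assert with_b and all(v == 0.0 for v in with_b)

    def test_constant_h_accuracy_equals_h_frequency(self, medium_truth):
        preds = generate_predictions(medium_truth, ErrorProfile(constant="H"), seed=3)
        report = evaluate_residue_level(medium_truth, preds)
        assert report.q_accuracy == pytest.approx(DEFAULT_SS8_FREQS["H"], abs=0.02)

    def test_invalid_recall_rejected(self):
        with pytest.raises(ValueError, match="recall"):
            ErrorProfile(recall={"H": 1.2})

    def test_rows_are_stochastic_and_peaked(self, small_truth):
        preds = generate_predictions(
            small_truth, ErrorProfile(temperature=0.2), seed=5
        )
        p = next(iter(preds.values())).probs8
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert p.max() > 0.9


class TestGenerateFeatures:
    def test_contact_entries_clipped(self, small_truth):
        recs = generate_features(small_truth[:5], noise=2.0, seed=6)
        for r in recs:
            cw = r.features.contact_window
            assert cw.min() >= 0.0 and cw.max() <= 1.0

    def test_determinism(self, small_truth):
        a = generate_features(small_truth[:3], seed=8)
        b = generate_features(small_truth[:3], seed=8)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.features.pssm, rb.features.pssm)


class TestGappedChains:
    def test_many_gaps(self, small_truth):
        # 8 gaps removing 54 of 152 residues leaves 98
        rec = next(r for r in generate_truth(
            GeneratorConfig(n_chains=20, length_min=152, length_max=152,
                            length_mean=152, seed=10)
        ))
        gaps = [(0, 5), (20, 7), (40, 6), (60, 8), (80, 7), (100, 7),
                (120, 7), (140, 7)]
        assert sum(g[1] for g in gaps) == 54
        out = gapped_chain_fixture(rec, gaps)
        assert len(out) == 98
        assert len(out.ss8) == 98

    def test_single_gap(self, small_truth):
        rec = next(r for r in generate_truth(
            GeneratorConfig(n_chains=1, length_min=204, length_max=204,
                            length_mean=204, seed=11)
        ))
        out = gapped_chain_fixture(rec, [(50, 34)])
        assert len(out) == 170

    def test_empty_spec_is_identity(self, small_truth):
        rec = small_truth[0]
        out = gapped_chain_fixture(rec, [])
        assert out.sequence == rec.sequence and out.ss8 == rec.ss8

    def test_overlapping_gaps_rejected(self, small_truth):
        with pytest.raises(ValueError, match="overlap"):
            gapped_chain_fixture(small_truth[0], [(0, 5), (3, 4)])

    def test_out_of_range_rejected(self, small_truth):
        with pytest.raises(ValueError, match="outside"):
            gapped_chain_fixture(small_truth[0], [(0, 10_000)])


def _macro_agm_pairs(records, preds_a, preds_b):
    va = evaluate_sequence_level(records, preds_a, "macro_agm")
    vb = evaluate_sequence_level(records, preds_b, "macro_agm")
    return {cid: (va[cid], vb[cid]) for cid in va}


class TestInferencePipeline:
    def test_injected_effect_recovered_with_high_power(self):
        """Recall gap delta = 0.1 on 200 chains: detected at p < 0.01 in
        >= 95% of replicate datasets."""
        base = ErrorProfile(recall={s: 0.7 for s in SS8_STATES})
        better = base.shifted(0.1)
        detected = 0
        n_reps = 100
        for rep in range(n_reps):
            records = generate_truth(GeneratorConfig(n_chains=200, seed=1000 + rep))
            pa = generate_predictions(records, better, seed=2000 + rep)
            pb = generate_predictions(records, base, seed=3000 + rep)
            result = guarded_test(
                _macro_agm_pairs(records, pa, pb),
                alternative="greater", r=999, seed=rep,
            )
            detected += result.p_value < 0.01
        assert detected >= 95

    def test_null_comparison_is_calibrated(self):
        """Same error profile for both predictors: rejection rate at
        alpha = 0.01 stays inside a binomial 99% band (quick check; the
        full-scale calibration runs in the acceptance suite)."""
        from scipy.stats import binom

        profile = ErrorProfile(recall={s: 0.8 for s in SS8_STATES})
        n_reps, alpha = 200, 0.01
        rejections = 0
        for rep in range(n_reps):
            records = generate_truth(GeneratorConfig(n_chains=100, seed=5000 + rep))
            pa = generate_predictions(records, profile, seed=6000 + rep)
            pb = generate_predictions(records, profile, seed=7000 + rep)
            result = guarded_test(
                _macro_agm_pairs(records, pa, pb),
                alternative="greater", r=999, seed=rep,
            )
            rejections += result.p_value < alpha
        lo, hi = binom.ppf([0.005, 0.995], n_reps, alpha)
        assert lo <= rejections <= hi
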