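"""AGM and friends: formula checks against a brute-force oracle,
definedness rules and aggregation levels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sskit.core import SS8_STATES, ProteinRecord
from sskit.metrics import (
    UNDEFINED,
    BinaryConfusion,
    agm,
    confusion_counts,
    evaluate_residue_level,
    evaluate_sequence_level,
    f1,
    gm,
    macro_average,
    precision,
    q_accuracy,
    report_to_tsv,
    sensitivity,
    specificity,
)
from sskit.synthetic import ErrorProfile, GeneratorConfig, generate_predictions, generate_truth


def agm_oracle(tp, fp, fn, tn):
    """Direct transcription of the defining equations, kept independent
    of the implementation under test."""
    if tp + fn == 0:
        return UNDEFINED
    sens = tp / (tp + fn)
    if sens == 0:
        return 0.0
    prec = tp / (tp + fp) if tp + fp else None
    spec = tn / (tn + fp) if tn + fp else None
    n_n = (tn + fp) / (tp + fp + fn + tn)
    if n_n == 0:
        return math.sqrt(prec * sens)
    if prec is None or spec is None:
        return UNDEFINED
    return (math.sqrt(prec * sens) + spec * n_n) / (1 + n_n)


confusions = st.builds(
    BinaryConfusion,
    tp=st.integers(0, 50), fp=st.integers(0, 50),
    fn=st.integers(0, 50), tn=st.integers(0, 50),
)


class TestConfusionCounts:
    def test_position_by_position_enumeration(self):
        c = confusion_counts("HHCC", "HCCC", "H")
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 0, 2)

    def test_perfect_prediction_has_no_errors(self):
        for cls in "HEC":
            c = confusion_counts("HHEC", "HHEC", cls)
            assert c.fp == 0 and c.fn == 0

    def test_absent_class_is_all_negatives(self):
        c = confusion_counts("HHCC", "HCCC", "I")
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts("HH", "H", "H")


class TestRatios:
    def test_sensitivity(self):
        assert sensitivity(BinaryConfusion(tp=3, fn=1)) == 0.75

    def test_precision_undefined_on_zero_denominator(self):
        assert precision(BinaryConfusion(tp=0, fp=0, fn=2, tn=3)) is UNDEFINED

    def test_specificity(self):
        assert specificity(BinaryConfusion(tn=5, fp=1)) == pytest.approx(5 / 6)

    def test_gm_of_equal_factors(self):
        # precision = sensitivity = 0.75 -> gm = sqrt(0.5625) = 0.75
        c = BinaryConfusion(tp=3, fn=1, fp=1, tn=5)
        assert gm(c) == pytest.approx(0.75)

    def test_gm_zero_sensitivity(self):
        assert gm(BinaryConfusion(tp=0, fn=3, fp=2, tn=5)) == 0.0

    def test_f1_equal_factors(self):
        c = BinaryConfusion(tp=3, fn=1, fp=1, tn=5)
        assert f1(c) == pytest.approx(0.75)


class TestAgm:
    def test_hand_evaluated_example(self):
        # GM = 0.75, spec = 5/6, N_n = 0.6 -> (0.75 + 0.5) / 1.6
        assert agm(BinaryConfusion(tp=3, fn=1, fp=1, tn=5)) == pytest.approx(0.78125)

    def test_zero_sensitivity_branch(self):
        assert agm(BinaryConfusion(tp=0, fn=4, fp=0, tn=6)) == 0.0

    def test_perfect_prediction(self):
        assert agm(BinaryConfusion(tp=4, fn=0, fp=0, tn=6)) == 1.0

    def test_class_absent_from_truth_is_undefined(self):
        assert agm(BinaryConfusion(tp=0, fn=0, fp=2, tn=6)) is UNDEFINED

    @given(confusions)
    @settings(max_examples=300, deadline=None)
    def test_matches_oracle_and_stays_in_unit_interval(self, c):
        got = agm(c)
        want = agm_oracle(c.tp, c.fp, c.fn, c.tn)
        if want is UNDEFINED:
            assert got is UNDEFINED
        else:
            assert got == pytest.approx(want, abs=1e-12)
            assert 0.0 <= got <= 1.0
            # zero iff zero sensitivity among defined cases
            assert (got == 0.0) == (c.tp == 0)

    def test_reduces_to_gm_without_negatives(self):
        c = BinaryConfusion(tp=3, fn=1, fp=0, tn=0)
        assert agm(c) == pytest.approx(gm(c))

    def test_nondecreasing_in_tn(self):
        for tp, fp, fn in [(3, 1, 1), (1, 4, 2), (5, 0, 0), (2, 2, 5)]:
            vals = [agm(BinaryConfusion(tp=tp, fp=fp, fn=fn, tn=tn)) for tn in range(40)]
            oracle = [agm_oracle(tp, fp, fn, tn) for tn in range(40)]
            assert vals == pytest.approx(oracle)
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestAggregation:
    def test_macro_average_skips_undefined(self):
        assert macro_average({"H": 0.8, "E": 0.6, "C": 0.7}) == (pytest.approx(0.7), 3)
        assert macro_average({"H": 0.8, "I": UNDEFINED}) == (pytest.approx(0.8), 1)
        assert macro_average({"H": UNDEFINED}) == (UNDEFINED, 0)

    def test_q_accuracy(self):
        assert q_accuracy("HHCC", "HCCC") == 0.75
        assert q_accuracy("HHCC", "HHCC") == 1.0
        with pytest.raises(ValueError):
            q_accuracy("", "")

    def _records(self, labels):
        return [
            ProteinRecord(id=f"c{i}", sequence="A" * len(s), ss8=s)
            for i, s in enumerate(labels)
        ]

    def test_residue_level_pools_confusions_additively(self):
        truths = ["HHEEC", "HECCC"]
        preds = {"c0": "HHECC", "c1": "HHCCC"}
        report = evaluate_residue_level(self._records(truths), preds)
        joint = evaluate_residue_level(
            self._records(["".join(truths)]), {"c0": "HHECCHHCCC"}
        )
        for cls in SS8_STATES:
            a, b = report.per_class[cls], joint.per_class[cls]
            assert a.agm == b.agm and a.f1 == b.f1

    def test_perfect_prediction_report(self):
        truths = ["HHEEC", "GTTSC"]
        preds = {"c0": "HHEEC", "c1": "GTTSC"}
        report = evaluate_residue_level(self._records(truths), preds)
        assert report.q_accuracy == 1.0
        for cls in "HEGSTC":
            assert report.per_class[cls].agm == 1.0

    def test_globally_absent_class_renders_as_dash(self):
        report = evaluate_residue_level(self._records(["HHEC"]), {"c0": "HHEC"})
        assert report.per_class["I"].agm is UNDEFINED
        tsv = report_to_tsv(report)
        row = [l for l in tsv.splitlines() if l.startswith("I\t")][0]
        assert "\t-\t" in row

    def test_sequence_level_equals_residue_level_for_single_chain(self):
        recs = self._records(["HHEECC"])
        preds = {"c0": "HHECCC"}
        seq = evaluate_sequence_level(recs, preds, "macro_agm")
        res = evaluate_residue_level(recs, preds)
        assert seq["c0"] == pytest.approx(res.macro_agm)

    def test_mean_over_chains_differs_from_pooled(self):
        # chains of different lengths: unweighted chain mean != pooled Q8
        recs = self._records(["HH", "EEEEEEEE"])
        preds = {"c0": "HC", "c1": "EEEEEEEE"}
        seq = evaluate_sequence_level(recs, preds, "q8")
        chain_mean = np.mean(list(seq.values()))  # (0.5 + 1.0) / 2
        pooled = evaluate_residue_level(recs, preds).q_accuracy  # 9/10
        assert chain_mean == pytest.approx(0.75)
        assert pooled == pytest.approx(0.9)
        assert chain_mean != pooled

    def test_chain_without_class_has_undefined_entry(self):
        recs = self._records(["HHEC", "BBEC"])
        preds = {"c0": "HHEC", "c1": "BBEC"}
        seq = evaluate_sequence_level(recs, preds, "agm:B")
        assert seq["c0"] is UNDEFINED
        assert seq["c1"] == 1.0

    def test_unmatched_id_rejected(self):
        with pytest.raises(KeyError):
            evaluate_sequence_level(self._records(["HH"]), {"zzz": "HH"})


class TestAccuracyParadox:
    def test_constant_h_beats_constant_g_on_q8_but_not_macro_agm(self):
        cfg = GeneratorConfig(n_chains=150, seed=13)
        records = generate_truth(cfg)
        const_h = generate_predictions(records, ErrorProfile(constant="H"), seed=1)
        const_g = generate_predictions(records, ErrorProfile(constant="G"), seed=1)
        rep_h = evaluate_residue_level(records, const_h)
        rep_g = evaluate_residue_level(records, const_g)
        # overall accuracy rewards predicting the dominant class...
        assert rep_h.q_accuracy > 5 * rep_g.q_accuracy
        # ...but per-class AGM exposes it: every non-predicted class scores 0
        for cls in SS8_STATES:
            if cls != "H":
                assert rep_h.per_class[cls].agm == 0.0
        assert rep_h.macro_agm == pytest.approx(
            rep_h.per_class["H"].agm / rep_h.macro_agm_classes
        )
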