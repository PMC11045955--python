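"""LOSO evaluation, metrics arithmetic, selection and personalization."""

import numpy as np
import pytest

from gaitdtw import (
    AugmentationSpec,
    DEFAULT_SIGNAL_CHANNELS,
    GeneratorSpec,
    Mode,
    audit_loso_hygiene,
    build_all_template_sets,
    compare_personalized,
    forward_select,
    forward_selection_spec,
    loso_evaluate,
    make_benchmark,
    prefix_sweep,
)
from gaitdtw.errors import ParameterError
from oracles import macro_f1_from_confusion


class TestMetricsArithmetic:
    def test_pooled_accuracy_is_confusion_trace_over_total(self, corpus9_snr30, channels6):
        cycles, _ = corpus9_snr30
        rep = loso_evaluate(cycles, channels6, prefix_fraction=0.3)
        cm = rep.confusion
        assert rep.overall_accuracy_pct == pytest.approx(100.0 * np.trace(cm) / cm.sum())
        # per-subject confusion rows sum to that subject's cycle count
        for sid, m in rep.per_subject.items():
            n = sum(1 for c in cycles if c.subject_id == sid and c.mode is not None)
            assert m.confusion.sum() == n
        # summed per-subject confusions equal the pooled one
        assert np.array_equal(sum(m.confusion for m in rep.per_subject.values()), cm)

    def test_macro_f1_matches_by_definition_recomputation(self, corpus9_snr30, channels6):
        cycles, _ = corpus9_snr30
        rep = loso_evaluate(cycles, channels6, prefix_fraction=0.2)
        assert rep.overall_macro_f1 == pytest.approx(
            macro_f1_from_confusion(rep.confusion), abs=1e-12
        )

    def test_hand_confusion_example(self):
        # [[8,2,0],[1,9,0],[0,0,10]] -> pooled accuracy 27/30 = 90.0%
        cm = np.array([[8, 2, 0], [1, 9, 0], [0, 0, 10]])
        assert 100.0 * np.trace(cm) / cm.sum() == pytest.approx(90.0)
        # macro F1 from per-class precision/recall by hand:
        # LW: P=8/9, R=8/10, F1=16/19; SC: P=9/11, R=9/10, F1=6/7; SD: F1=1
        expected = (16 / 19 + 6 / 7 + 1.0) / 3
        assert macro_f1_from_confusion(cm) == pytest.approx(expected)


class TestLoso:
    def test_separable_noiseless_corpus_is_perfect(self, corpus9_noiseless, channels6):
        cycles, _ = corpus9_noiseless
        rep = loso_evaluate(cycles, channels6, prefix_fraction=0.3, keep_outcomes=False)
        assert rep.overall_accuracy_pct == 100.0

    def test_needs_two_subjects(self, corpus9_noiseless, channels6):
        cycles, _ = corpus9_noiseless
        only_one = [c for c in cycles if c.subject_id == "S01"]
        with pytest.raises(ParameterError):
            loso_evaluate(only_one, channels6)

    def test_own_subject_never_votes(self, corpus9_snr30, channels6):
        cycles, _ = corpus9_snr30
        rep = loso_evaluate(cycles, channels6, prefix_fraction=0.5, keep_outcomes=True)
        for sid, fold in rep.fold_provenance.items():
            assert sid not in fold["voter_subjects"]
            assert len(fold["voter_subjects"]) == 8
        for o in rep.outcomes:
            assert o.subject_id not in {v.subject_id for v in o.prediction.per_voter}

    def test_hygiene_audit_with_augmented_queries(self, corpus9_snr30, channels6):
        cycles, _ = corpus9_snr30
        rep = loso_evaluate(
            cycles,
            channels6,
            prefix_fraction=0.3,
            augment_spec=AugmentationSpec(seed=9),
            keep_outcomes=False,
        )
        assert audit_loso_hygiene(rep, cycles)

    def test_hygiene_audit_catches_contamination(self, corpus9_snr30, channels6):
        cycles, _ = corpus9_snr30
        rep = loso_evaluate(cycles, channels6, prefix_fraction=0.3, keep_outcomes=False)
        rep.fold_provenance["S01"]["voter_subjects"].append("S01")
        assert not audit_loso_hygiene(rep, cycles)


class TestPrefixSweep:
    def test_single_fraction_equals_plain_loso(self, corpus9_snr30, channels6):
        cycles, _ = corpus9_snr30
        [swept] = prefix_sweep(cycles, channels6, [1.0], keep_outcomes=False)
        plain = loso_evaluate(cycles, channels6, prefix_fraction=1.0, keep_outcomes=False)
        assert swept.overall_accuracy_pct == plain.overall_accuracy_pct
        assert np.array_equal(swept.confusion, plain.confusion)

    def test_empty_fraction_list(self, corpus9_snr30, channels6):
        cycles, _ = corpus9_snr30
        assert prefix_sweep(cycles, channels6, []) == []

    def test_invalid_fraction_rejected(self, corpus9_snr30, channels6):
        cycles, _ = corpus9_snr30
        with pytest.raises(ParameterError):
            prefix_sweep(cycles, channels6, [0.0, 0.5])

    def test_accuracy_non_decreasing_with_prefix(self, corpus9_snr30, channels6):
        cycles, _ = corpus9_snr30
        fractions = [0.1, 0.3, 0.6, 1.0]
        reps = prefix_sweep(cycles, channels6, fractions, keep_outcomes=False)
        accs = [r.overall_accuracy_pct for r in reps]
        assert all(b >= a - 2.0 for a, b in zip(accs, accs[1:]))


class TestForwardSelect:
    def test_recovers_the_two_informative_channels(self):
        spec = forward_selection_spec(seed=11, n_subjects=5, n_cycles=15, noise_snr_db=35.0)
        cycles, _ = make_benchmark(spec)
        informative = {spec.channels[0], spec.channels[1]}
        trace = forward_select(cycles, list(spec.channels), prefix_fraction=0.3)
        assert set(trace.channels[:2]) == informative
        assert len(trace.channels) == 2
        assert trace.stopped_because == "no_improvement"
        assert trace.steps[1].accuracy_pct > trace.steps[0].accuracy_pct

    def test_single_candidate_one_step_trace(self, corpus9_snr30, channels6):
        cycles, _ = corpus9_snr30
        trace = forward_select(cycles, channels6[:1], prefix_fraction=0.3)
        assert len(trace.steps) == 1

    def test_pure_noise_channels_stay_at_chance(self):
        spec = GeneratorSpec(
            n_subjects=4,
            n_cycles=12,
            noise_snr_db=35.0,
            seed=13,
            informative={ch: frozenset() for ch in DEFAULT_SIGNAL_CHANNELS},
        )
        cycles, _ = make_benchmark(spec)
        trace = forward_select(cycles, list(spec.channels)[:4], prefix_fraction=0.3)
        majority = max(
            sum(1 for c in cycles if c.mode is m) for m in Mode
        ) / len(cycles)
        # no channel carries mode information: accuracy stays near the
        # majority-class rate however many channels selection adds
        assert trace.steps[-1].accuracy_pct <= 100.0 * majority + 15.0

    def test_empty_candidates_rejected(self, corpus9_snr30):
        cycles, _ = corpus9_snr30
        with pytest.raises(ParameterError):
            forward_select(cycles, [])


class TestPersonalization:
    def _corpus(self, deviant):
        spec = GeneratorSpec(
            n_subjects=4,
            n_cycles=16,
            noise_snr_db=35.0,
            seed=2,
            min_cycles_per_mode=4,
            deviant_subjects=(0,) if deviant else (),
            deviant_sd=0.8,
        )
        return make_benchmark(spec)[0]

    def test_deviant_subject_benefits_from_personal_templates(self):
        cycles = self._corpus(deviant=True)
        subj = [c for c in cycles if c.subject_id == "S01"]
        others = [c for c in cycles if c.subject_id != "S01"]
        sets = list(build_all_template_sets(others).values())
        df = compare_personalized(subj, sets, fractions=[0.3])
        personal = df[df.model == "personalized"].accuracy_pct.iloc[0]
        generic = df[df.model == "user_independent"].accuracy_pct.iloc[0]
        assert personal > generic

    def test_homogeneous_subject_gains_little(self):
        cycles = self._corpus(deviant=False)
        subj = [c for c in cycles if c.subject_id == "S01"]
        others = [c for c in cycles if c.subject_id != "S01"]
        sets = list(build_all_template_sets(others).values())
        df = compare_personalized(subj, sets, fractions=[0.3])
        personal = df[df.model == "personalized"].accuracy_pct.iloc[0]
        generic = df[df.model == "user_independent"].accuracy_pct.iloc[0]
        assert abs(personal - generic) <= 15.0

    def test_single_cycle_per_mode_rejected(self, corpus9_snr30):
        cycles, _ = corpus9_snr30
        subj = [c for c in cycles if c.subject_id == "S01"]
        one_per_mode = []
        seen = set()
        for c in subj:
            if c.mode not in seen:
                seen.add(c.mode)
                one_per_mode.append(c)
        with pytest.raises(ParameterError):
            compare_personalized(one_per_mode, [], fractions=[0.5])


class TestPlotting:
    def test_sweep_and_confusion_figures_render(self, corpus9_snr30, channels6):
        import matplotlib

        matplotlib.use("Agg")
        from gaitdtw import sweep_frame
        from gaitdtw.plotting import plot_confusion, plot_prefix_sweep

        cycles, _ = corpus9_snr30
        reports = prefix_sweep(cycles, channels6, [0.2, 0.4], keep_outcomes=False)
        ax = plot_prefix_sweep(sweep_frame(reports))
        assert ax.get_xlabel().startswith("progression")
        ax2 = plot_confusion(reports[0].confusion)
        assert ax2 is not None
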