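"""Leave-one-subject-out evaluation, prefix sweeps, forward channel
selection, and personalized-vs-user-independent comparison.

"Overall accuracy" is pooled (micro) accuracy over all evaluated cycles;
F1 is macro-averaged over the three classes, chosen because the transition
classes are heavily outnumbered by level walking (a weighted F1 would
collapse onto accuracy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, f1_score

from .augment import AugmentationSpec, augment_class
from .classify import ClassifierConfig, Prediction, predict_voted
from .errors import ParameterError
from .templates import TemplateSet, build_template_set
from .types import MODE_ORDER, ChannelId, GaitCycle, Mode, root_id

log = logging.getLogger(__name__)

_MODE_LABELS = [m.value for m in MODE_ORDER]


@dataclass
class CycleOutcome:
    """One evaluated query cycle with its full voted prediction."""

    subject_id: str
    cycle_id: str
    true_mode: Mode
    prediction: Prediction


@dataclass
class SubjectMetrics:
    accuracy_pct: float
    macro_f1: float
    confusion: np.ndarray  # 3x3 counts, rows = true, cols = predicted


@dataclass
class EvaluationReport:
    per_subject: dict[str, SubjectMetrics]
    overall_accuracy_pct: float
    overall_macro_f1: float
    confusion: np.ndarray
    prefix_fraction: float
    channels: list[ChannelId]
    strategy: str
    outcomes: list[CycleOutcome] = field(default_factory=list)
    fold_provenance: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-subject table (plus a pooled row) for plotting/export."""
        rows = [
            {
                "subject": s,
                "prefix_fraction": self.prefix_fraction,
                "accuracy_pct": m.accuracy_pct,
                "macro_f1": m.macro_f1,
            }
            for s, m in self.per_subject.items()
        ]
        rows.append(
            {
                "subject": "pooled",
                "prefix_fraction": self.prefix_fraction,
                "accuracy_pct": self.overall_accuracy_pct,
                "macro_f1": self.overall_macro_f1,
            }
        )
        return pd.DataFrame(rows)


def _metrics(true: list[Mode], pred: list[Mode]) -> SubjectMetrics:
    t = [m.value for m in true]
    p = [m.value for m in pred]
    cm = confusion_matrix(t, p, labels=_MODE_LABELS)
    acc = 100.0 * np.trace(cm) / cm.sum()
    f1 = f1_score(t, p, labels=_MODE_LABELS, average="macro", zero_division=0)
    return SubjectMetrics(accuracy_pct=float(acc), macro_f1=float(f1), confusion=cm)


def _group_by_subject(cycles: list[GaitCycle]) -> dict[str, list[GaitCycle]]:
    out: dict[str, list[GaitCycle]] = {}
    for c in cycles:
        if c.mode is None:
            continue
        out.setdefault(c.subject_id, []).append(c)
    return out


def build_all_template_sets(
    cycles: list[GaitCycle], robust: bool = False
) -> dict[str, TemplateSet]:
    """One template set per subject (subjects lacking a mode are skipped
    with a warning and excluded from voting pools)."""
    sets: dict[str, TemplateSet] = {}
    for sid, subj_cycles in sorted(_group_by_subject(cycles).items()):
        try:
            sets[sid] = build_template_set(subj_cycles, sid, robust=robust)
        except Exception as exc:  # incomplete mode coverage
            log.warning("subject %s excluded from voting pool: %s", sid, exc)
    return sets


def loso_evaluate(
    cycles: list[GaitCycle],
    channels: list[ChannelId],
    prefix_fraction: float = 1.0,
    strategy: str = "dependent",
    prefix_mode: str = "prefix",
    augment_spec: AugmentationSpec | None = None,
    keep_outcomes: bool = True,
) -> EvaluationReport:
    """Leave-one-subject-out evaluation of the voted mDTW classifier.

    For each held-out subject, voting template sets are built from the RAW
    cycles of all other subjects, and every labelled cycle of the held-out
    subject is classified at the given prefix fraction. If ``augment_spec``
    is given, the held-out subject's transitional query cycles are expanded
    by augmentation before classification (templates stay raw). Augmented
    cycles never cross the subject boundary: splitting is by subject, which
    subsumes original/derived pairing.
    """
    by_subject = _group_by_subject(cycles)
    if len(by_subject) < 2:
        raise ParameterError("LOSO needs at least 2 subjects")
    raw = [c for c in cycles if c.origin == "raw"]
    sets = build_all_template_sets(raw)

    per_subject: dict[str, SubjectMetrics] = {}
    outcomes: list[CycleOutcome] = []
    provenance: dict[str, dict] = {}
    all_true: list[Mode] = []
    all_pred: list[Mode] = []
    for sid in sorted(by_subject):
        voters = [sets[v] for v in sorted(sets) if v != sid]
        if not voters:
            raise ParameterError("no voting template sets available")
        cfg = ClassifierConfig(
            channels=tuple(channels),
            strategy=strategy,
            prefix_fraction=prefix_fraction,
            prefix_mode=prefix_mode,
        )
        queries = list(by_subject[sid])
        if augment_spec is not None:
            trans = [c for c in queries if c.mode is not Mode.LW and c.origin == "raw"]
            if trans:
                aug = augment_class(trans, augment_spec)
                derived = [c for c in aug if c.origin != "raw"]
                queries = queries + derived
        true: list[Mode] = []
        pred: list[Mode] = []
        for q in queries:
            p = predict_voted(q, voters, cfg)
            true.append(q.mode)
            pred.append(p.final)
            if keep_outcomes:
                outcomes.append(CycleOutcome(sid, q.cycle_id, q.mode, p))
        per_subject[sid] = _metrics(true, pred)
        all_true += true
        all_pred += pred
        provenance[sid] = {
            "voter_subjects": [v.subject_id for v in voters],
            "template_cycle_ids": sorted(
                set().union(*(v.source_cycle_ids() for v in voters))
            ),
        }

    pooled = _metrics(all_true, all_pred)
    log.info(
        "LOSO @ prefix %.2f: pooled accuracy %.2f%%, macro F1 %.4f (%d cycles)",
        prefix_fraction,
        pooled.accuracy_pct,
        pooled.macro_f1,
        len(all_true),
    )
    return EvaluationReport(
        per_subject=per_subject,
        overall_accuracy_pct=pooled.accuracy_pct,
        overall_macro_f1=pooled.macro_f1,
        confusion=pooled.confusion,
        prefix_fraction=prefix_fraction,
        channels=list(channels),
        strategy=strategy,
        outcomes=outcomes,
        fold_provenance=provenance,
    )


def audit_loso_hygiene(report: EvaluationReport, cycles: list[GaitCycle]) -> bool:
    """Provenance audit: no held-out subject's cycles — raw or augmented —
    may contribute to any template set that voted on that subject."""
    by_subject: dict[str, set[str]] = {}
    for c in cycles:
        by_subject.setdefault(c.subject_id, set()).update({c.cycle_id, root_id(c)})
    for sid, fold in report.fold_provenance.items():
        if sid in fold["voter_subjects"]:
            return False
        own = by_subject.get(sid, set())
        if own & set(fold["template_cycle_ids"]):
            return False
    return True


def prefix_sweep(
    cycles: list[GaitCycle],
    channels: list[ChannelId],
    fractions: list[float],
    **kwargs,
) -> list[EvaluationReport]:
    """One LOSO report per prefix fraction (early-recognition curve)."""
    if any(not 0 < f <= 1 for f in fractions):
        raise ParameterError("prefix fractions must lie in (0, 1]")
    return [
        loso_evaluate(cycles, channels, prefix_fraction=f, **kwargs) for f in fractions
    ]


def sweep_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Concatenated tidy table of a prefix sweep."""
    return pd.concat([r.to_frame() for r in reports], ignore_index=True)


@dataclass
class SelectionStep:
    channel: ChannelId
    accuracy_pct: float
    macro_f1: float


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    stopped_because: str  # "no_improvement" | "max_channels" | "exhausted"
    rejected: SelectionStep | None = None  # best candidate that failed to improve

    @property
    def channels(self) -> list[ChannelId]:
        return [s.channel for s in self.steps]


def forward_select(
    cycles: list[GaitCycle],
    candidate_channels: list[ChannelId],
    prefix_fraction: float = 1.0,
    max_channels: int | None = None,
    strategy: str = "dependent",
) -> SelectionTrace:
    """Greedy forward channel selection by pooled LOSO accuracy.

    Starts from the best single channel; each iteration adds the channel
    that maximises pooled accuracy and stops as soon as no candidate
    STRICTLY improves it (ties stop), or when ``max_channels`` is reached.
    The best rejected candidate is recorded so a non-strict reading of the
    stopping rule can be inspected from the trace.
    """
    if not candidate_channels:
        raise ParameterError("forward_select needs at least one candidate")
    max_channels = max_channels or len(candidate_channels)
    selected: list[ChannelId] = []
    steps: list[SelectionStep] = []
    best_acc = -np.inf
    remaining = list(candidate_channels)
    stopped = "exhausted"
    rejected: SelectionStep | None = None
    while remaining and len(selected) < max_channels:
        scored: list[SelectionStep] = []
        for ch in remaining:
            rep = loso_evaluate(
                cycles,
                selected + [ch],
                prefix_fraction=prefix_fraction,
                strategy=strategy,
                keep_outcomes=False,
            )
            scored.append(
                SelectionStep(ch, rep.overall_accuracy_pct, rep.overall_macro_f1)
            )
        best = max(scored, key=lambda s: s.accuracy_pct)
        if best.accuracy_pct <= best_acc:
            stopped = "no_improvement"
            rejected = best
            break
        selected.append(best.channel)
        remaining.remove(best.channel)
        steps.append(best)
        best_acc = best.accuracy_pct
        log.info(
            "forward selection step %d: +%s -> %.2f%%",
            len(steps),
            best.channel,
            best.accuracy_pct,
        )
    if len(selected) >= max_channels and stopped == "exhausted" and remaining:
        stopped = "max_channels"
    return SelectionTrace(steps=steps, stopped_because=stopped, rejected=rejected)


def compare_personalized(
    subject_cycles: list[GaitCycle],
    other_sets: list[TemplateSet],
    fractions: list[float],
    split_ratio: float = 0.5,
    strategy: str = "dependent",
) -> pd.DataFrame:
    """Personalized vs user-independent accuracy for one subject.

    Half of the subject's cycles (per mode, in recording order) build a
    personalized template set; the other half are classified twice — once
    against the personalized set alone and once against the other subjects'
    sets with voting — at each prefix fraction.
    """
    by_mode: dict[Mode, list[GaitCycle]] = {}
    for c in subject_cycles:
        if c.mode is not None:
            by_mode.setdefault(c.mode, []).append(c)
    train: list[GaitCycle] = []
    test: list[GaitCycle] = []
    for mode, mode_cycles in by_mode.items():
        k = int(round(len(mode_cycles) * split_ratio))
        if k < 1 or len(mode_cycles) - k < 1:
            raise ParameterError(
                f"subject needs >= 2 cycles per mode to split (mode {mode.value})"
            )
        train += mode_cycles[:k]
        test += mode_cycles[k:]
    sid = subject_cycles[0].subject_id
    personal = build_template_set(train, sid)
    channels = list(other_sets[0].channel_ids) if other_sets else list(personal.channel_ids)

    rows = []
    for frac in fractions:
        cfg = ClassifierConfig(
            channels=tuple(channels), strategy=strategy, prefix_fraction=frac
        )
        for name, sets in (("personalized", [personal]), ("user_independent", other_sets)):
            true = [q.mode for q in test]
            pred = [predict_voted(q, sets, cfg).final for q in test]
            m = _metrics(true, pred)
            rows.append(
                {
                    "model": name,
                    "prefix_fraction": frac,
                    "accuracy_pct": m.accuracy_pct,
                    "macro_f1": m.macro_f1,
                }
            )
    return pd.DataFrame(rows)
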