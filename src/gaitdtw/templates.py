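"""Template generation: per-subject, per-mode reference cycles.

A template is built by resampling all of a subject's cycles of one mode to
their average length (linear interpolation) and averaging sample by sample.
A subject's :class:`TemplateSet` holds one template per mode plus the
per-channel z-score statistics fitted on the contributing cycles, so queries
can be normalised into the same space as the templates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .augment import resample_1d
from .errors import IncompleteSetError, ParameterError
from .preprocess import NormalizationParams
from .types import MODE_ORDER, ChannelId, GaitCycle, Mode

log = logging.getLogger(__name__)


@dataclass
class Template:
    """Averaged reference cycle of one (subject, mode)."""

    subject_id: str
    mode: Mode
    channel_ids: list[ChannelId]
    values: np.ndarray          # d x L
    n_cycles: int
    source_cycle_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ParameterError("template contains NaN")

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def select_channels(self, channels: list[ChannelId]) -> np.ndarray:
        rows = [self.channel_ids.index(c) for c in channels]
        return self.values[rows]


def build_template(
    cycles: list[GaitCycle],
    subject_id: str | None = None,
    mode: Mode | None = None,
    robust: bool = False,
) -> Template:
    """Average cycles into a template at the rounded mean cycle length.

    All cycles must share channel ordering; ``robust=True`` uses the
    elementwise median instead of the mean (off by default).
    """
    if not cycles:
        raise ParameterError("cannot build a template from zero cycles")
    channels = cycles[0].channels
    for c in cycles[1:]:
        if c.channels != channels:
            raise ParameterError("cycles disagree on channel ordering")
    subject_id = subject_id if subject_id is not None else cycles[0].subject_id
    mode = mode if mode is not None else cycles[0].mode
    L = int(round(float(np.mean([c.n_samples for c in cycles]))))
    stack = np.stack(
        [np.vstack([resample_1d(row, L) for row in c.data]) for c in cycles]
    )
    values = np.median(stack, axis=0) if robust else stack.mean(axis=0)
    return Template(
        subject_id=subject_id,
        mode=mode,
        channel_ids=list(channels),
        values=values,
        n_cycles=len(cycles),
        source_cycle_ids=[c.cycle_id for c in cycles],
    )


@dataclass
class TemplateSet:
    """One subject's full voter: a template per mode + normalisation stats.

    ``norm`` maps each channel to the z-score statistics fitted on the
    contributing cycles; templates are stored in normalised space.
    """

    subject_id: str
    templates: dict[Mode, Template]
    channel_ids: list[ChannelId]
    norm: dict[ChannelId, NormalizationParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [m for m in MODE_ORDER if m not in self.templates]
        if missing:
            raise IncompleteSetError(
                f"template set for {self.subject_id} missing modes: "
                + ", ".join(m.value for m in missing)
            )
        for t in self.templates.values():
            if t.channel_ids != self.channel_ids:
                raise ParameterError("templates disagree on channel ordering")

    @property
    def n_series(self) -> int:
        """Number of per-channel template series (channels x modes)."""
        return len(self.channel_ids) * len(self.templates)

    def source_cycle_ids(self) -> set[str]:
        out: set[str] = set()
        for t in self.templates.values():
            out.update(t.source_cycle_ids)
        return out

    def normalize_query(self, data: np.ndarray, channels: list[ChannelId]) -> np.ndarray:
        """Apply the set's training statistics to query channel rows."""
        out = np.empty_like(data, dtype=float)
        for r, ch in enumerate(channels):
            p = self.norm[ch]
            out[r] = (data[r] - p.mean) / p.std
        return out


def build_template_set(
    cycles: list[GaitCycle],
    subject_id: str,
    normalize: bool = True,
    robust: bool = False,
) -> TemplateSet:
    """Build a subject's 3-mode template set from their labelled cycles.

    Per-channel z-score statistics are fitted on all contributing cycles
    (pooled over modes) and applied before averaging, so a 37-channel
    configuration yields 111 normalised per-channel template series.
    Raises :class:`IncompleteSetError` when a mode has no cycles.
    """
    cycles = [c for c in cycles if c.subject_id == subject_id and c.mode is not None]
    if not cycles:
        raise ParameterError(f"no labelled cycles for subject {subject_id}")
    channels = cycles[0].channels

    norm: dict[ChannelId, NormalizationParams] = {}
    if normalize:
        for r, ch in enumerate(channels):
            pooled = np.concatenate([c.data[r] for c in cycles])
            sd = float(np.std(pooled, ddof=1))
            if sd <= 0:
                sd = 1.0  # constant channel: pass through centred
                log.warning("constant channel %s for %s; std forced to 1", ch, subject_id)
            norm[ch] = NormalizationParams(
                mean=float(np.mean(pooled)), std=sd, scope="per_training_corpus"
            )

    def _prep(c: GaitCycle) -> GaitCycle:
        if not normalize:
            return c
        data = np.vstack(
            [(c.data[r] - norm[ch].mean) / norm[ch].std for r, ch in enumerate(channels)]
        )
        return GaitCycle(
            subject_id=c.subject_id,
            mode=c.mode,
            channels=list(channels),
            data=data,
            fs=c.fs,
            source_span=c.source_span,
            cycle_id=c.cycle_id,
            parent_id=c.parent_id,
            origin=c.origin,
        )

    templates: dict[Mode, Template] = {}
    for mode in MODE_ORDER:
        mode_cycles = [c for c in cycles if c.mode is mode]
        if not mode_cycles:
            raise IncompleteSetError(
                f"template set for {subject_id} missing modes: {mode.value}"
            )
        templates[mode] = build_template(
            [_prep(c) for c in mode_cycles], subject_id, mode, robust=robust
        )
    log.info(
        "built template set for %s: %d channels x %d modes from %d cycles",
        subject_id,
        len(channels),
        len(templates),
        len(cycles),
    )
    return TemplateSet(
        subject_id=subject_id,
        templates=templates,
        channel_ids=list(channels),
        norm=norm,
    )
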