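"""Nearest-template mDTW classification with multi-subject majority voting.

Each subject's template set is one voter: it normalises the query with its
own training statistics, measures the mDTW distance to its LW / LW-SC / LW-SD
templates and votes for the nearest. The final label is the plurality vote;
a tie among top modes is broken by the smallest mean distance across all
voters. For early (partial-cycle) recognition the query prefix is compared
against the same fraction of each template ("prefix" matching, the default),
or against the full template with a free endpoint ("open_end").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dtw import cumulative_matrix, distance_matrix, dtw_distance_only
from .errors import ParameterError
from .templates import TemplateSet
from .types import MODE_ORDER, ChannelId, GaitCycle, Mode

log = logging.getLogger(__name__)

MIN_PREFIX_SAMPLES = 4


@dataclass(frozen=True)
class ClassifierConfig:
    """Channels, mDTW strategy and prefix fraction for classification."""

    channels: tuple[ChannelId, ...]
    strategy: str = "dependent"          # or "independent"
    prefix_fraction: float = 1.0         # fraction of cycle available, (0, 1]
    prefix_mode: str = "prefix"          # or "open_end"
    distance_weighted: bool = False      # distance-weighted voting (off = paper scheme)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ParameterError("classifier needs at least one channel")
        if not 0 < self.prefix_fraction <= 1:
            raise ParameterError("prefix_fraction must be in (0, 1]")
        if self.strategy not in ("dependent", "independent"):
            raise ParameterError(f"unknown strategy {self.strategy!r}")
        if self.prefix_mode not in ("prefix", "open_end"):
            raise ParameterError(f"unknown prefix_mode {self.prefix_mode!r}")


@dataclass
class VoterRecord:
    subject_id: str
    voted_mode: Mode
    distances: dict[Mode, float]


@dataclass
class Prediction:
    final: Mode
    per_voter: list[VoterRecord]
    tie_broken: bool
    prefix_fraction: float


def _prefix(data: np.ndarray, fraction: float) -> np.ndarray:
    n = int(round(data.shape[1] * fraction))
    if n < MIN_PREFIX_SAMPLES:
        raise ParameterError(
            f"prefix of {n} samples (< {MIN_PREFIX_SAMPLES}) is too short "
            f"for fraction {fraction}"
        )
    return data[:, :n]


def predict_single_set(
    query: GaitCycle, template_set: TemplateSet, cfg: ClassifierConfig
) -> tuple[Mode, dict[Mode, float]]:
    """One voter's prediction: argmin mDTW distance over the three modes.

    The query prefix (first ``round(prefix_fraction * len)`` samples of the
    configured channels, normalised with the set's training statistics) is
    compared against each template's prefix of the same fraction. Argmin
    ties are broken by the fixed mode order LW, LW-SC, LW-SD.
    """
    channels = list(cfg.channels)
    qdata = query.select_channels(channels)
    qdata = template_set.normalize_query(qdata, channels)
    qpre = _prefix(qdata, cfg.prefix_fraction)

    distances: dict[Mode, float] = {}
    for mode in MODE_ORDER:
        tdata = template_set.templates[mode].select_channels(channels)
        if cfg.prefix_mode == "prefix":
            tpre = _prefix(tdata, cfg.prefix_fraction)
            distances[mode] = dtw_distance_only(qpre, tpre, cfg.strategy)
        else:  # open_end: free endpoint on the (full) template
            C = cumulative_matrix(distance_matrix(qpre, tdata))
            distances[mode] = float(C[-1].min())
    voted = min(MODE_ORDER, key=lambda m: (distances[m], MODE_ORDER.index(m)))
    return voted, distances


def predict_voted(
    query: GaitCycle,
    template_sets: list[TemplateSet],
    cfg: ClassifierConfig,
) -> Prediction:
    """Majority vote across template sets with average-distance tie-break.

    Every set votes independently; the plurality mode wins. When several
    modes tie for the most votes, the tied mode with the smallest mean
    distance across ALL voters is chosen and the tie is flagged.
    """
    if not template_sets:
        raise ParameterError("predict_voted needs at least one template set")
    records: list[VoterRecord] = []
    for ts in template_sets:
        voted, dists = predict_single_set(query, ts, cfg)
        records.append(VoterRecord(ts.subject_id, voted, dists))

    if cfg.distance_weighted:
        weights = {m: 0.0 for m in MODE_ORDER}
        for r in records:
            weights[r.voted_mode] += 1.0 / (1.0 + r.distances[r.voted_mode])
        counts = weights
    else:
        counts = {m: 0.0 for m in MODE_ORDER}
        for r in records:
            counts[r.voted_mode] += 1.0

    top = max(counts.values())
    tied = [m for m in MODE_ORDER if counts[m] == top]
    if len(tied) == 1:
        final, tie_broken = tied[0], False
    else:
        mean_dist = {
            m: float(np.mean([r.distances[m] for r in records])) for m in tied
        }
        final = min(tied, key=lambda m: (mean_dist[m], MODE_ORDER.index(m)))
        tie_broken = True
        log.debug(
            "vote tie among %s broken by mean distance -> %s",
            [m.value for m in tied],
            final.value,
        )
    return Prediction(
        final=final,
        per_voter=records,
        tie_broken=tie_broken,
        prefix_fraction=cfg.prefix_fraction,
    )
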