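"""Readers and writers for recordings, cycles, templates and predictions.

On-disk formats are deliberately inspectable: a recording is a long-form CSV
(``time, channel, value``) plus a JSON sidecar carrying the sampling rate,
channel order, gait events and mode labels; cycles, templates and
predictions are single JSON documents. All writers round-trip exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import Prediction
from .errors import DataError, FormatError, SchemaError
from .preprocess import NormalizationParams
from .templates import Template, TemplateSet
from .types import ChannelId, GaitCycle, GaitEvent, GaitRecording, Mode

log = logging.getLogger(__name__)


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording(recording: GaitRecording, csv_path: str | Path) -> None:
    """Long-form CSV + JSON sidecar; values at full float precision."""
    csv_path = Path(csv_path)
    n = recording.n_samples
    t = np.arange(n) / recording.sampling_rate
    frames = []
    for r, ch in enumerate(recording.channels):
        frames.append(
            pd.DataFrame(
                {"time": t, "channel": str(ch), "value": recording.data[r]}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        csv_path, index=False, float_format="%.17g"
    )
    sidecar = {
        "subject_id": recording.subject_id,
        "sampling_rate": recording.sampling_rate,
        "channels": [str(c) for c in recording.channels],
        "events": [[int(i), e.value] for i, e in recording.events],
        "labels": [[int(a), int(b), m.value] for a, b, m in recording.labels],
    }
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))
    log.info("wrote recording %s: %d channels x %d samples", csv_path, len(recording.channels), n)


def read_recording(
    csv_path: str | Path,
    schema: dict | None = None,
) -> GaitRecording:
    """Read a long-form CSV recording with its JSON sidecar.

    ``schema`` may declare ``required_channels`` (strings), a
    ``sampling_rate`` overriding the sidecar, and ``max_nan_gap`` (samples;
    longer NaN runs raise :class:`DataError`; shorter runs are
    linearly interpolated).
    """
    csv_path = Path(csv_path)
    schema = schema or {}
    side = _sidecar_path(csv_path)
    if not side.exists():
        raise SchemaError(f"missing sidecar {side}")
    try:
        meta = json.loads(side.read_text())
        df = pd.read_csv(csv_path, float_precision="round_trip")
    except (json.JSONDecodeError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse {csv_path}: {exc}") from exc
    for col in ("time", "channel", "value"):
        if col not in df.columns:
            raise FormatError(f"{csv_path} lacks column {col!r}")

    fs = float(schema.get("sampling_rate", meta["sampling_rate"]))
    channels = [ChannelId.parse(c) for c in meta["channels"]]
    present = set(df["channel"].unique())
    for ch in schema.get("required_channels", meta["channels"]):
        if str(ch) not in present:
            raise SchemaError(f"declared channel {ch} missing from {csv_path}")

    rows = []
    for ch in channels:
        sub = df[df["channel"] == str(ch)]
        if sub.empty:
            raise SchemaError(f"declared channel {ch} missing from {csv_path}")
        tvals = sub["time"].to_numpy()
        if np.any(np.diff(tvals) <= 0):
            raise FormatError(f"non-monotonic time column for channel {ch}")
        vals = sub["value"].to_numpy(dtype=float)
        if np.isnan(vals).any():
            vals = _fill_nan(vals, int(schema.get("max_nan_gap", 0)), str(ch))
        rows.append(vals)
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"channels of unequal length in {csv_path}")

    return GaitRecording(
        subject_id=meta["subject_id"],
        sampling_rate=fs,
        channels=channels,
        data=np.vstack(rows),
        events=[(int(i), GaitEvent(e)) for i, e in meta.get("events", [])],
        labels=[(int(a), int(b), Mode(m)) for a, b, m in meta.get("labels", [])],
    )


def _fill_nan(x: np.ndarray, max_gap: int, label: str) -> np.ndarray:
    isnan = np.isnan(x)
    # longest run of NaNs
    run = best = 0
    for v in isnan:
        run = run + 1 if v else 0
        best = max(best, run)
    if best > max_gap:
        raise DataError(f"NaN run of {best} samples (> {max_gap}) in channel {label}")
    idx = np.arange(x.size)
    x = x.copy()
    x[isnan] = np.interp(idx[isnan], idx[~isnan], x[~isnan])
    return x


# ---------------------------------------------------------------- cycles ----

def _cycle_to_dict(c: GaitCycle) -> dict:
    return {
        "subject_id": c.subject_id,
        "mode": c.mode.value if c.mode is not None else None,
        "data": c.data.tolist(),
        "fs": float(c.fs),
        "source_span": [int(v) for v in c.source_span] if c.source_span else None,
        "cycle_id": c.cycle_id,
        "parent_id": c.parent_id,
        "origin": c.origin,
    }


def write_cycles(path: str | Path, cycles: list[GaitCycle]) -> None:
    """JSON cycle container; refuses mixed channel orderings."""
    channels: list[str] | None = None
    for c in cycles:
        cur = [str(ch) for ch in c.channels]
        if channels is None:
            channels = cur
        elif cur != channels:
            raise SchemaError("cycles have mixed channel orderings; refusing to write")
    doc = {"channels": channels or [], "cycles": [_cycle_to_dict(c) for c in cycles]}
    Path(path).write_text(json.dumps(doc))
    log.info("wrote %d cycles to %s", len(cycles), path)


def read_cycles(path: str | Path) -> list[GaitCycle]:
    try:
        doc = json.loads(Path(path).read_text())
        channels = [ChannelId.parse(c) for c in doc["channels"]]
        out = []
        for d in doc["cycles"]:
            out.append(
                GaitCycle(
                    subject_id=d["subject_id"],
                    mode=Mode(d["mode"]) if d["mode"] is not None else None,
                    channels=list(channels),
                    data=np.asarray(d["data"], dtype=float),
                    fs=float(d["fs"]),
                    source_span=tuple(d["source_span"]) if d["source_span"] else None,
                    cycle_id=d["cycle_id"],
                    parent_id=d["parent_id"],
                    origin=d["origin"],
                )
            )
        return out
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"cannot parse cycle file {path}: {exc}") from exc


# ------------------------------------------------------------- templates ----

def write_template_sets(path: str | Path, sets: list[TemplateSet]) -> None:
    doc = []
    for ts in sets:
        doc.append(
            {
                "subject_id": ts.subject_id,
                "channels": [str(c) for c in ts.channel_ids],
                "norm": {
                    str(ch): {"mean": p.mean, "std": p.std, "scope": p.scope}
                    for ch, p in ts.norm.items()
                },
                "templates": {
                    mode.value: {
                        "values": t.values.tolist(),
                        "n_cycles": t.n_cycles,
                        "source_cycle_ids": t.source_cycle_ids,
                    }
                    for mode, t in ts.templates.items()
                },
            }
        )
    Path(path).write_text(json.dumps(doc))
    log.info("wrote %d template sets to %s", len(sets), path)


def read_template_sets(path: str | Path) -> list[TemplateSet]:
    try:
        doc = json.loads(Path(path).read_text())
        out = []
        for d in doc:
            channels = [ChannelId.parse(c) for c in d["channels"]]
            templates = {
                Mode(mv): Template(
                    subject_id=d["subject_id"],
                    mode=Mode(mv),
                    channel_ids=list(channels),
                    values=np.asarray(td["values"], dtype=float),
                    n_cycles=int(td["n_cycles"]),
                    source_cycle_ids=list(td["source_cycle_ids"]),
                )
                for mv, td in d["templates"].items()
            }
            norm = {
                ChannelId.parse(ch): NormalizationParams(
                    mean=p["mean"], std=p["std"], scope=p["scope"]
                )
                for ch, p in d["norm"].items()
            }
            out.append(
                TemplateSet(
                    subject_id=d["subject_id"],
                    templates=templates,
                    channel_ids=channels,
                    norm=norm,
                )
            )
        return out
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"cannot parse template file {path}: {exc}") from exc


# ----------------------------------------------------------- predictions ----

def write_predictions(path: str | Path, predictions: list[Prediction]) -> None:
    doc = [
        {
            "final": p.final.value,
            "tie_broken": p.tie_broken,
            "prefix_fraction": p.prefix_fraction,
            "per_voter": [
                {
                    "subject_id": v.subject_id,
                    "voted_mode": v.voted_mode.value,
                    "distances": {m.value: d for m, d in v.distances.items()},
                }
                for v in p.per_voter
            ],
        }
        for p in predictions
    ]
    Path(path).write_text(json.dumps(doc, indent=1))


def load_config(path: str | Path) -> dict:
    """YAML pipeline configuration (filter, kalman, detector, classifier keys)."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise FormatError(f"config {path} must be a mapping")
    return doc
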