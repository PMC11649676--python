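"""Recording and configuration I/O.

Three on-disk forms are supported:

* ``.npz`` — lossless container; bit-exact round trips.
* ``.edf`` — European Data Format (16-bit); signal values are quantized to
  the stored physical range, events ride in a ``*_events.tsv`` sidecar.
  Reading goes through :func:`mne.io.read_raw_edf`.
* events alone as TSV with columns
  ``onset_sample  cue_sample  movement_sample  side  condition``.

Session/generator configurations map 1:1 onto YAML files with ``session``,
``mrcp``, ``erd`` and ``noise`` sections.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    ErdParams,
    MrcpParams,
    NoiseParams,
    Recording,
    SessionConfig,
    TrialEvent,
)

__all__ = [
    "write_recording",
    "read_recording",
    "write_events_tsv",
    "read_events_tsv",
    "load_config",
    "save_config",
]

_EVENT_COLUMNS = ["onset_sample", "cue_sample", "movement_sample",
                  "side", "condition"]


def write_events_tsv(events: list[TrialEvent], path) -> None:
    df = pd.DataFrame(
        [
            {
                "onset_sample": ev.cue_sample,
                "cue_sample": ev.cue_sample,
                "movement_sample": ev.movement_sample,
                "side": ev.side,
                "condition": ev.condition,
            }
            for ev in events
        ],
        columns=_EVENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[TrialEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        TrialEvent(
            cue_sample=int(r.cue_sample),
            movement_sample=int(r.movement_sample),
            side=str(r.side),
            condition=str(r.condition),
        )
        for r in df.itertuples()
    ]


def _events_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + "_events.tsv")


def write_recording(rec: Recording, path, format: str | None = None) -> None:
    """Write a recording; format inferred from the suffix unless given."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "npz":
        np.savez(
            path,
            data=rec.data,
            srate=np.float64(rec.srate),
            channel_names=np.array(rec.channel_names),
            cue_samples=np.array([e.cue_sample for e in rec.events], int),
            movement_samples=np.array(
                [e.movement_sample for e in rec.events], int),
            sides=np.array([e.side for e in rec.events]),
            conditions=np.array([e.condition for e in rec.events]),
        )
    elif fmt == "edf":
        _write_edf(rec, path)
        write_events_tsv(rec.events, _events_sidecar(path))
    else:
        raise IOError(f"unsupported recording format {fmt!r} for {path}")


def read_recording(path) -> Recording:
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    try:
        if fmt == "npz":
            with np.load(path, allow_pickle=False) as z:
                events = [
                    TrialEvent(int(c), int(m), str(s), str(cond))
                    for c, m, s, cond in zip(
                        z["cue_samples"], z["movement_samples"],
                        z["sides"], z["conditions"])
                ]
                return Recording(
                    z["data"], float(z["srate"]),
                    [str(c) for c in z["channel_names"]], events,
                )
        if fmt == "edf":
            import mne

            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
            data = raw.get_data() * 1e6  # mne works in volts
            sidecar = _events_sidecar(path)
            events = read_events_tsv(sidecar) if sidecar.exists() else []
            return Recording(data, float(raw.info["sfreq"]),
                             list(raw.ch_names), events)
    except (OSError, KeyError, ValueError) as exc:
        raise IOError(f"failed to read recording {path}: {exc}") from exc
    raise IOError(f"unsupported recording format {fmt!r} for {path}")


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: Path) -> None:
    """Minimal EDF writer: 16-bit signals, 1-second data records.

    The final record is zero-padded if the recording length is not a whole
    number of seconds, so durations may be rounded up on read.
    """
    srate = rec.srate
    if abs(srate - round(srate)) > 1e-9:
        raise IOError(
            f"EDF export requires an integer sampling rate, got {srate}")
    spr = int(round(srate))  # samples per 1 s record
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / spr))

    phys_max = float(np.max(np.abs(rec.data)))
    phys_max = max(np.ceil(phys_max), 1.0)
    dig_max, dig_min = 32767, -32768

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field(datetime.date(2000, 1, 1).strftime("%d.%m.%y"), 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_ch), 8),
        _edf_field("EDF", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    header += b"".join(_edf_field(c, 16) for c in rec.channel_names)
    header += b"".join(_edf_field("AgAgCl electrode", 80)
                       for _ in range(n_ch))
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(-phys_max, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(phys_max, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(spr, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    scale = (dig_max - dig_min) / (2.0 * phys_max)
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, : rec.n_samples] = rec.data
    digital = np.clip(np.round(padded * scale), dig_min, dig_max).astype(
        "<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * spr: (r + 1) * spr].tobytes())


_SECTIONS = {
    "session": SessionConfig,
    "mrcp": MrcpParams,
    "erd": ErdParams,
    "noise": NoiseParams,
}


def _coerce(cls, mapping: dict):
    # YAML gives lists where the dataclasses want tuples (band edges)
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in mapping.items():
        if key not in fields:
            raise IOError(f"unknown {cls.__name__} field {key!r}")
        kwargs[key] = tuple(value) if isinstance(value, list) else value
    return cls(**kwargs)


def load_config(path):
    """Read a YAML session configuration.

    Returns ``(SessionConfig, MrcpParams, ErdParams, NoiseParams)``; missing
    sections fall back to defaults.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out = []
    for name, cls in _SECTIONS.items():
        out.append(_coerce(cls, doc.get(name, {}) or {}))
    return tuple(out)


def save_config(path, session: SessionConfig = SessionConfig(),
                mrcp: MrcpParams = MrcpParams(),
                erd: ErdParams = ErdParams(),
                noise: NoiseParams = NoiseParams()) -> None:
    doc = {}
    for name, obj in zip(_SECTIONS, (session, mrcp, erd, noise)):
        d = dataclasses.asdict(obj)
        doc[name] = {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in d.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
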