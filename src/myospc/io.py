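"""Session, feature and report I/O.

Recording sessions are stored as delimited text (one column per channel
plus the two label columns) with a YAML sidecar holding the metadata
(sampling rate, channel map, events, seed, day), or as EDF (European
Data Format, one 16-bit signal per channel with μV physical dimension).

The EDF writer/reader here implement the minimal plain-EDF subset the
testbed needs: fixed-field ASCII header, one data-record per second,
little-endian int16 samples scaled between physical min/max. Events stay
in the YAML sidecar rather than EDF+ annotation streams.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import Event, RecordingSession

__all__ = [
    "write_session_text",
    "read_session_text",
    "write_session_edf",
    "read_edf",
    "read_session_edf",
    "write_features_text",
]


# -- delimited text ----------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _meta_doc(session: RecordingSession) -> dict:
    return {
        "format": "myospc-session-v1",
        "fs_hz": float(session.fs),
        "channel_types": list(session.channel_types),
        "channel_names": list(session.channel_names),
        "day": int(session.day),
        "seed": session.seed,
        "events": [
            {"kind": e.kind, "start_s": float(e.start_s),
             "stop_s": float(e.stop_s)}
            for e in session.events
        ],
    }


def write_session_text(session: RecordingSession, path) -> None:
    path = Path(path)
    df = pd.DataFrame(session.signal.T, columns=list(session.channel_names))
    df.insert(0, "t_s", np.arange(session.signal.shape[1]) / session.fs)
    df["label_x"] = session.labels[:, 0]
    df["label_y"] = session.labels[:, 1]
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(_meta_doc(session), fh, sort_keys=True)


def read_session_text(path) -> RecordingSession:
    path = Path(path)
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh)
    df = pd.read_csv(path, sep="\t")
    names = meta["channel_names"]
    return RecordingSession(
        signal=df[names].to_numpy().T,
        fs=meta["fs_hz"],
        channel_types=tuple(meta["channel_types"]),
        labels=df[["label_x", "label_y"]].to_numpy(),
        events=tuple(Event(e["kind"], e["start_s"], e["stop_s"])
                     for e in meta["events"]),
        day=meta["day"],
        seed=meta["seed"],
        channel_names=tuple(names),
    )


# -- EDF ---------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_session_edf(session: RecordingSession, path) -> None:
    """Write the signal channels as plain EDF (labels/events go to the
    YAML sidecar). The recording is zero-padded to whole 1 s records."""
    x = session.signal
    ns = x.shape[0]
    spr = int(round(session.fs))  # samples per record (1 s records)
    n_rec = int(np.ceil(x.shape[1] / spr))
    padded = np.zeros((ns, n_rec * spr))
    padded[:, : x.shape[1]] = x

    pmax = max(float(np.max(np.abs(padded))), 1.0)
    pmin = -pmax
    dmin, dmax = -32768, 32767

    hdr = b"".join([
        _pad("0", 8),
        _pad("synthetic subject", 80),
        _pad("myospc synthetic recording", 80),
        _pad("01.01.00", 8), _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    fields = [
        (16, [f"EMG {n}" for n in session.channel_names]),
        (80, ["synthetic EMG" for _ in range(ns)]),
        (8, ["uV"] * ns),
        (8, [f"{pmin:.1f}" for _ in range(ns)]),
        (8, [f"{pmax:.1f}" for _ in range(ns)]),
        (8, [str(dmin)] * ns),
        (8, [str(dmax)] * ns),
        (80, [""] * ns),
        (8, [str(spr)] * ns),
        (32, [""] * ns),
    ]
    for width, vals in fields:
        hdr += b"".join(_pad(v, width) for v in vals)

    scale = (dmax - dmin) / (pmax - pmin)
    dig = np.clip(np.round((padded - pmin) * scale + dmin), dmin, dmax
                  ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            fh.write(dig[:, r * spr: (r + 1) * spr].tobytes())
    meta = _meta_doc(session)
    meta["n_samples"] = int(x.shape[1])
    with open(_sidecar(Path(path)), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_edf(path):
    """Minimal plain-EDF reader: returns (signal channels × samples in
    physical units, fs, channel labels)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_rec = int(head[236:244].decode().strip())
        rec_dur = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())
        sig_hdr = fh.read(256 * ns)

        def col(offset, width):
            base = offset * ns
            return [sig_hdr[base + i * width: base + (i + 1) * width]
                    .decode().strip() for i in range(ns)]

        labels = col(0, 16)
        # per-signal field offsets in bytes within the signal header
        off = np.cumsum([0, 16, 80, 8, 8, 8, 8, 8, 80, 8]) * ns

        def fcol(block, width):
            return [float(sig_hdr[block + i * width: block + (i + 1) * width])
                    for i in range(ns)]

        pmin = fcol(off[3], 8)
        pmax = fcol(off[4], 8)
        dmin = fcol(off[5], 8)
        dmax = fcol(off[6], 8)
        spr = [int(v) for v in fcol(off[8], 8)]
        data = fh.read()

    total = sum(spr)
    out = [np.empty(n_rec * s) for s in spr]
    raw = np.frombuffer(data, dtype="<i2", count=n_rec * total)
    pos = 0
    for r in range(n_rec):
        for c, s in enumerate(spr):
            out[c][r * s: (r + 1) * s] = raw[pos: pos + s]
            pos += s
    sig = np.vstack([
        (o - dmin[c]) * (pmax[c] - pmin[c]) / (dmax[c] - dmin[c]) + pmin[c]
        for c, o in enumerate(out)
    ])
    fs = spr[0] / rec_dur
    return sig, fs, labels


def read_session_edf(path) -> RecordingSession:
    """Read an EDF written by :func:`write_session_edf` plus its sidecar."""
    sig, fs, _ = read_edf(path)
    with open(_sidecar(Path(path))) as fh:
        meta = yaml.safe_load(fh)
    n = meta.get("n_samples", sig.shape[1])
    sig = sig[:, :n]
    labels = np.zeros((n, 2))
    return RecordingSession(
        signal=sig, fs=meta["fs_hz"],
        channel_types=tuple(meta["channel_types"]),
        labels=labels,
        events=tuple(Event(e["kind"], e["start_s"], e["stop_s"])
                     for e in meta["events"]),
        day=meta["day"], seed=meta["seed"],
        channel_names=tuple(meta["channel_names"]),
    )


def write_features_text(features, path) -> None:
    features.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6f")
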