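"""Linear-regression decoding for simultaneous proportional 2-DoF control.

A single linear map estimates both wrist DoFs (flexion/extension and
radial/ulnar deviation) at once from windowed RMS features:

    y_hat = W x + b,   W: 2 × n_channels, b: 2-vector

trained by ordinary least squares on a cued calibration session where the
visual cue trajectory provides the labels y. One decoder is trained per
electrode type, on that type's channels only. An optional ridge penalty
is available for ill-conditioned feature sets but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .conditioning import FeatureMatrix
from .protocols import CueProtocol

__all__ = [
    "LinearDecoder",
    "build_labels",
    "train_decoder",
    "decode",
    "r_squared",
]


@dataclass(frozen=True)
class LinearDecoder:
    W: np.ndarray  # 2 × n_channels
    bias: np.ndarray  # 2-vector
    channel_order: tuple
    trained_on: str = ""

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        b = np.asarray(self.bias, dtype=float)
        if W.ndim != 2 or W.shape[0] != 2 or b.shape != (2,):
            raise ValueError("W must be 2 × n_channels and bias a 2-vector")
        if len(self.channel_order) != W.shape[1]:
            raise ValueError("channel_order length must match W columns")
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
            raise ValueError("decoder weights must be finite")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "bias", b)

    # -- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "format": "myospc-decoder-v1",
            "W": self.W.tolist(),
            "bias": self.bias.tolist(),
            "channel_order": list(self.channel_order),
            "trained_on": self.trained_on,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "LinearDecoder":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(np.array(doc["W"]), np.array(doc["bias"]),
                   tuple(doc["channel_order"]), doc.get("trained_on", ""))


def build_labels(protocol: CueProtocol, window_center_times: np.ndarray,
                 tolerance_s: float = 0.5) -> np.ndarray:
    """Per-window 2-DoF labels sampled from the cue trapezoids.

    ``window_center_times`` must fall inside the protocol (within a small
    tolerance for the trailing partial window).
    """
    t = np.asarray(window_center_times, dtype=float)
    if t.size == 0 or t[-1] > protocol.duration_s + tolerance_s:
        raise ValueError("window timing does not match the protocol duration")
    labels, _ = protocol.sample(np.clip(t, 0.0, protocol.duration_s))
    return labels


def _check_rank(xa: np.ndarray, channel_order) -> None:
    rank = np.linalg.matrix_rank(xa)
    if rank < xa.shape[1]:
        bad = [str(channel_order[i]) for i in range(xa.shape[1] - 1)
               if np.std(xa[:, i]) < 1e-12]
        corr = np.corrcoef(xa[:, :-1], rowvar=False)
        pairs = [
            f"{channel_order[i]}~{channel_order[j]}"
            for i in range(corr.shape[0]) for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 1 - 1e-9
        ]
        raise np.linalg.LinAlgError(
            "rank-deficient feature matrix; "
            f"constant channels: {bad or 'none'}; "
            f"collinear pairs: {pairs or 'none'}"
        )


def train_decoder(features: FeatureMatrix | np.ndarray, labels: np.ndarray,
                  channel_order=None, ridge: float = 0.0,
                  trained_on: str = "") -> LinearDecoder:
    """Least-squares fit of (W, b) minimizing ||y - Wx - b||^2.

    Deterministic for fixed inputs. Raises on a rank-deficient feature
    matrix, naming constant or collinear channels.
    """
    if isinstance(features, FeatureMatrix):
        x = features.values
        channel_order = channel_order or features.channel_names
    else:
        x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels must have the same window count")
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more windows than channels to fit the decoder")
    channel_order = tuple(channel_order or range(x.shape[1]))

    xa = np.hstack([x, np.ones((x.shape[0], 1))])
    if ridge > 0:
        pen = ridge * np.eye(xa.shape[1])
        pen[-1, -1] = 0.0  # never shrink the intercept
        coef = np.linalg.solve(xa.T @ xa + pen, xa.T @ y)
    else:
        _check_rank(xa, channel_order)
        coef, *_ = np.linalg.lstsq(xa, y, rcond=None)
    return LinearDecoder(coef[:-1].T, coef[-1], channel_order, trained_on)


def decode(decoder: LinearDecoder, x: np.ndarray) -> np.ndarray:
    """Apply the decoder: W x + b. ``x`` is one feature vector or a
    windows × channels matrix; output is unclipped (the task layer owns
    workspace limits)."""
    x = np.asarray(x, dtype=float)
    n_ch = decoder.W.shape[1]
    if x.shape[-1] != n_ch:
        raise ValueError(f"expected {n_ch} features, got {x.shape[-1]}")
    return x @ decoder.W.T + decoder.bias


def r_squared(decoder: LinearDecoder, features, labels: np.ndarray) -> np.ndarray:
    """Coefficient of determination per DoF."""
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    y = np.asarray(labels, dtype=float)
    pred = decode(decoder, x)
    ss_res = np.sum((y - pred) ** 2, axis=0)
    ss_tot = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
    return 1.0 - ss_res / ss_tot
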