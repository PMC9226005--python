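"""Model surface: encoding, configuration, training, prediction, persistence.

Sequence pairs are one-hot encoded into 4 x 30 (small RNA) and 4 x 60
(target site) matrices with fixed row order (A, T, C, G); an ambiguous N
becomes a uniform 0.25 column. Longer sequences are trimmed and shorter
ones N-padded at the 3' end, preserving the 5' seed region, which is the
most target-determining part of a miRNA.

Model artifacts are single JSON files with a version-stamped header and
all parameters embedded, so a round trip reproduces predictions
bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EncodingError, ModelIOError, ParameterError
from .nn import Adam, InteractionNet

_FORMAT = "isomirnet-model-v1"

_ROW_ORDER = "ATCG"
_COLUMNS = {
    "A": np.array([1.0, 0.0, 0.0, 0.0]),
    "T": np.array([0.0, 1.0, 0.0, 0.0]),
    "C": np.array([0.0, 0.0, 1.0, 0.0]),
    "G": np.array([0.0, 0.0, 0.0, 1.0]),
    "N": np.array([0.25, 0.25, 0.25, 0.25]),
}


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters (published defaults)."""

    mirna_len: int = 30
    site_len: int = 60
    n_kernels: int = 10
    kernel_len: int = 8
    pool_size: int = 4
    conv_stride: int = 1
    pool_stride: int = 1
    lstm_units_per_direction: int = 10
    dense_units: int = 100
    dropout_merge: float = 0.25
    dropout_lstm: float = 0.50
    dropout_dense: float = 0.50
    l1_penalty: float = 0.01
    learning_rate: float = 0.001
    batch_size: int = 100
    epochs: int = 500
    decision_threshold: float = 0.5
    batchnorm_after_conv: bool = False
    seed: int = 0

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "ModelConfig":
        """Published architecture with regularization disabled for small runs.

        The published dropout rates and L1 coefficient are calibrated to
        the full-scale regime (~10^5 training pairs, 500 epochs). In
        short desk-scale runs (a few thousand pairs, tens of epochs) the
        L1 penalty at its published value drives every convolution and
        dense weight toward zero before any feature can form, yielding
        the constant classifier; dropout similarly consumes most of the
        tiny step budget. This constructor keeps every architectural
        setting identical and switches off the overfitting controls,
        which have nothing to regularize at that scale.
        """
        kwargs = dict(
            seed=seed, l1_penalty=0.0,
            dropout_merge=0.0, dropout_lstm=0.0, dropout_dense=0.0,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def __post_init__(self) -> None:
        if self.conv_stride != 1 or self.pool_stride != 1:
            raise ParameterError("only stride 1 is supported (as published)")
        if min(self.mirna_len, self.site_len) < self.kernel_len:
            raise ParameterError("input lengths must be >= kernel_len")
        for r in (self.dropout_merge, self.dropout_lstm, self.dropout_dense):
            if not 0.0 <= r < 1.0:
                raise ParameterError("rates must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 0:
            raise ParameterError("batch_size >= 1 and epochs >= 0 required")


def encode(seq: str, target_len: int) -> np.ndarray:
    """One-hot encode a sequence into a 4 x target_len matrix.

    Row order (A, T, C, G); U read as T; N as a uniform column. Longer
    sequences are trimmed at the 3' end, shorter ones N-padded at the 3'
    end. Every column sums to 1.
    """
    s = seq.upper().replace("U", "T")
    out = np.zeros((4, target_len))
    for i in range(target_len):
        if i < len(s):
            ch = s[i]
            col = _COLUMNS.get(ch)
            if col is None:
                raise EncodingError(f"invalid character {ch!r} at position {i}")
        else:
            col = _COLUMNS["N"]
        out[:, i] = col
    return out


def decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`encode` on unambiguous columns (N for uniform)."""
    out = []
    for col in matrix.T:
        if np.allclose(col, 0.25):
            out.append("N")
        else:
            out.append(_ROW_ORDER[int(np.argmax(col))])
    return "".join(out)


def encode_pairs(pairs: pd.DataFrame, config: ModelConfig):
    """Encode a pairs table into (X_mirna, X_site, labels-or-None)."""
    xm = np.stack([encode(s, config.mirna_len) for s in pairs["small_rna_seq"]])
    xs = np.stack([encode(s, config.site_len) for s in pairs["site_seq"]])
    y = pairs["label"].to_numpy(dtype=float) if "label" in pairs.columns else None
    return xm, xs, y


def build_model(config: ModelConfig | None = None) -> "Predictor":
    """Construct an untrained predictor from a configuration."""
    config = config or ModelConfig()
    net = InteractionNet(
        mirna_len=config.mirna_len, site_len=config.site_len,
        n_kernels=config.n_kernels, kernel_len=config.kernel_len,
        pool_size=config.pool_size,
        lstm_units=config.lstm_units_per_direction,
        dense_units=config.dense_units,
        dropout_merge=config.dropout_merge, dropout_lstm=config.dropout_lstm,
        dropout_dense=config.dropout_dense, l1_penalty=config.l1_penalty,
        batchnorm_after_conv=config.batchnorm_after_conv, seed=config.seed,
    )
    return Predictor(config=config, net=net)


@dataclass
class Predictor:
    config: ModelConfig
    net: InteractionNet
    history: list[float] = field(default_factory=list)

    def shape_chain(self) -> dict[str, tuple[int, ...]]:
        return self.net.shape_chain()

    # -- training ------------------------------------------------------------

    def fit(
        self,
        pairs: pd.DataFrame,
        epochs: int | None = None,
        verbose: bool = False,
    ) -> list[float]:
        """Mini-batch Adam training on an encoded pairs table.

        Returns (and appends to) the per-epoch mean training loss history.
        A single-class training set is accepted with a warning since the
        loss remains well defined, but ranking metrics downstream will not
        be.
        """
        import logging

        epochs = self.config.epochs if epochs is None else epochs
        xm, xs, y = encode_pairs(pairs, self.config)
        if y is None:
            raise ParameterError("training requires a label column")
        if len(np.unique(y)) < 2:
            logging.getLogger(__name__).warning(
                "training set contains a single class"
            )
        rng = np.random.default_rng(self.config.seed + 1)
        opt = Adam(self.net.params, lr=self.config.learning_rate)
        n = len(y)
        bs = self.config.batch_size
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                prob, cache = self.net.forward(xm[idx], xs[idx], train=True)
                losses.append(self.net.loss(prob, y[idx]))
                grads = self.net.backward(cache, y[idx])
                opt.step(self.net.params, grads)
            mean_loss = float(np.mean(losses))
            if not np.isfinite(mean_loss):
                raise ParameterError(f"training diverged at epoch {epoch}")
            self.history.append(mean_loss)
            if verbose:
                print(f"epoch {epoch + 1}/{epochs}  loss {mean_loss:.4f}")
        return self.history

    # -- inference -----------------------------------------------------------

    def predict_proba(self, pairs: pd.DataFrame, batch_size: int = 500) -> np.ndarray:
        xm, xs, _ = encode_pairs(pairs, self.config)
        return self.predict_encoded(xm, xs, batch_size)

    def predict_encoded(self, xm, xs, batch_size: int = 500) -> np.ndarray:
        out = []
        for start in range(0, len(xm), batch_size):
            prob, _ = self.net.forward(
                xm[start:start + batch_size], xs[start:start + batch_size], train=False
            )
            out.append(prob)
        return np.concatenate(out) if out else np.zeros(0)

    def predict(self, pairs: pd.DataFrame) -> pd.DataFrame:
        """(probability, binary) per pair; binary = prob >= threshold."""
        prob = self.predict_proba(pairs)
        return pd.DataFrame({
            "probability": prob,
            "binary": (prob >= self.config.decision_threshold).astype(int),
        })

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a single portable JSON artifact with config and weights."""
        payload = {
            "format": _FORMAT,
            "config": asdict(self.config),
            "history": self.history,
            "params": {k: v.tolist() for k, v in self.net.params.items()},
        }
        if self.net.batchnorm:
            payload["bn_running"] = {
                br: [m.tolist(), v.tolist()] for br, (m, v) in self.net.bn_running.items()
            }
        Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> Predictor:
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"model file {path} does not exist")
    try:
        payload = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelIOError(f"corrupt model file {path}: {exc}") from exc
    if payload.get("format") != _FORMAT:
        raise ModelIOError(
            f"incompatible model format {payload.get('format')!r} (expected {_FORMAT})"
        )
    config = ModelConfig(**payload["config"])
    predictor = build_model(config)
    for k, v in payload["params"].items():
        arr = np.array(v, dtype=float)
        if arr.shape != predictor.net.params[k].shape:
            raise ModelIOError(f"parameter {k} has wrong shape in {path}")
        predictor.net.params[k] = arr
    if "bn_running" in payload and predictor.net.batchnorm:
        predictor.net.bn_running = {
            br: (np.array(m), np.array(v)) for br, (m, v) in payload["bn_running"].items()
        }
    predictor.history = list(payload.get("history", []))
    return predictor
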