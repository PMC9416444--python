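"""Recurrent sequence regressors for articulation-to-speech and voice conversion.

Two model families share one implementation:

* the **ATS regressor** maps 54-dim articulatory features to 80-dim log-mel
  frames with a stack of unidirectional LSTM layers (causal, streamable:
  outputs for a prefix depend only on that prefix);
* the **VC regressor** maps 80-dim log-mel frames of a source speaker to the
  target speaker's frames with bidirectional LSTM layers (no real-time
  constraint).

Training follows a whole-sentence-per-batch protocol: mean-squared-error on
output frames, Adam, gradients clipped to a global norm of 5, one optimiser
step per sentence, sentence order reshuffled each epoch with a seeded
generator.  The returned model carries the parameters of the epoch with the
lowest validation loss together with the full training log.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from ._recurrent import lstm_backward, lstm_forward

GRAD_CLIP_NORM = 5.0


@dataclass(frozen=True)
class RegressorSpec:
    """Topology and optimisation settings of one regressor."""

    kind: str  # {"ats_sd", "ats_si", "vc"}
    input_dim: int
    output_dim: int
    hidden: int
    depth: int
    bidirectional: bool
    learning_rate: float
    max_epochs: int
    clip_norm: float = GRAD_CLIP_NORM


#: Published topologies: 3-layer LSTM/BLSTM, whole-sentence batches, Adam.
DEFAULT_SPECS = {
    "ats_sd": RegressorSpec("ats_sd", 54, 80, 256, 3, False, 3e-4, 50),
    "ats_si": RegressorSpec("ats_si", 54, 80, 256, 3, False, 1e-5, 30),
    "vc": RegressorSpec("vc", 80, 80, 128, 3, True, 5e-5, 30),
}


def default_spec(kind: str) -> RegressorSpec:
    if kind not in DEFAULT_SPECS:
        raise ValueError(f"unknown regressor kind {kind!r}")
    return DEFAULT_SPECS[kind]


def reduced_spec(kind: str, hidden: int = 64, depth: int = 1,
                 max_epochs: int = 10, learning_rate: float = 2e-3) -> RegressorSpec:
    """Desk-scale variant of a published spec (small net, short training).

    Used for simulation studies where the full topology would be needlessly
    expensive; dimensions and architecture class are unchanged.
    """
    return replace(default_spec(kind), hidden=hidden, depth=depth,
                   max_epochs=max_epochs, learning_rate=learning_rate)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

def _init_lstm(rng: np.random.Generator, d_in: int, hidden: int) -> dict[str, np.ndarray]:
    s_in = 1.0 / np.sqrt(d_in)
    s_h = 1.0 / np.sqrt(hidden)
    p = {
        "W": rng.uniform(-s_in, s_in, size=(d_in, 4 * hidden)),
        "U": rng.uniform(-s_h, s_h, size=(hidden, 4 * hidden)),
        "b": np.zeros(4 * hidden),
    }
    p["b"][hidden : 2 * hidden] = 1.0  # forget-gate bias
    return p


def _init_params(spec: RegressorSpec, rng: np.random.Generator) -> list[dict[str, np.ndarray]]:
    dir_mult = 2 if spec.bidirectional else 1
    params: list[dict[str, np.ndarray]] = []
    d_in = spec.input_dim
    for _ in range(spec.depth):
        layer = {"fwd": _init_lstm(rng, d_in, spec.hidden)}
        if spec.bidirectional:
            layer["bwd"] = _init_lstm(rng, d_in, spec.hidden)
        params.append(layer)
        d_in = spec.hidden * dir_mult
    s = 1.0 / np.sqrt(d_in)
    params.append({"proj": {
        "V": rng.uniform(-s, s, size=(d_in, spec.output_dim)),
        "c": np.zeros(spec.output_dim),
    }})
    return params


def _forward(spec: RegressorSpec, params: list[dict], X: np.ndarray,
             want_cache: bool = False):
    caches = []
    h = X
    for layer in params[:-1]:
        cache_l = {}
        pf = layer["fwd"]
        out_f = lstm_forward(h, pf["W"], pf["U"], pf["b"])
        if spec.bidirectional:
            pb = layer["bwd"]
            out_b = lstm_forward(h[::-1].copy(), pb["W"], pb["U"], pb["b"])
            h_next = np.concatenate([out_f[0], out_b[0][::-1]], axis=1)
        else:
            out_b = None
            h_next = out_f[0]
        if want_cache:
            cache_l.update({"in": h, "fwd": out_f, "bwd": out_b})
            caches.append(cache_l)
        h = h_next
    proj = params[-1]["proj"]
    Y = h @ proj["V"] + proj["c"]
    if want_cache:
        caches.append({"in": h})
        return Y, caches
    return Y


def _backward(spec: RegressorSpec, params: list[dict], caches: list[dict],
              dY: np.ndarray) -> list[dict]:
    grads: list[dict] = [None] * len(params)  # type: ignore[list-item]
    proj = params[-1]["proj"]
    h_last = caches[-1]["in"]
    grads[-1] = {"proj": {"V": h_last.T @ dY, "c": dY.sum(axis=0)}}
    dh = dY @ proj["V"].T
    for li in range(len(params) - 2, -1, -1):
        layer = params[li]
        cache = caches[li]
        X_in = cache["in"]
        pf = layer["fwd"]
        Hs, gi, gf, gg, go, cs, tc = cache["fwd"]
        if spec.bidirectional:
            dh_f = dh[:, : spec.hidden]
            dh_b = dh[:, spec.hidden :]
            dX_f, dWf, dUf, dbf = lstm_backward(
                X_in, pf["W"], pf["U"], Hs, gi, gf, gg, go, cs, tc, dh_f)
            pb = layer["bwd"]
            Hsb, gib, gfb, ggb, gob, csb, tcb = cache["bwd"]
            dX_b, dWb, dUb, dbb = lstm_backward(
                X_in[::-1].copy(), pb["W"], pb["U"],
                Hsb, gib, gfb, ggb, gob, csb, tcb, dh_b[::-1].copy())
            grads[li] = {"fwd": {"W": dWf, "U": dUf, "b": dbf},
                         "bwd": {"W": dWb, "U": dUb, "b": dbb}}
            dh = dX_f + dX_b[::-1]
        else:
            dX, dW, dU, db = lstm_backward(
                X_in, pf["W"], pf["U"], Hs, gi, gf, gg, go, cs, tc, dh)
            grads[li] = {"fwd": {"W": dW, "U": dU, "b": db}}
            dh = dX
    return grads


def _iter_arrays(tree):
    """Yield (container, key) for every ndarray leaf of a params/grads tree."""
    for block in tree:
        for sub in block.values():
            for k in sub:
                yield sub, k


class _Adam:
    def __init__(self, params: list[dict], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {name: {k: np.zeros_like(v) for k, v in sub.items()}
             for name, sub in block.items()}
            for block in params
        ]
        self.v = copy.deepcopy(self.m)

    def step(self, params: list[dict], grads: list[dict]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for bi, block in enumerate(params):
            for name, sub in block.items():
                for k in sub:
                    g = grads[bi][name][k]
                    m = self.m[bi][name][k]
                    v = self.v[bi][name][k]
                    m *= self.b1
                    m += (1 - self.b1) * g
                    v *= self.b2
                    v += (1 - self.b2) * g * g
                    sub[k] -= lr_t * m / (np.sqrt(v) + self.eps)


def _clip_global_norm(grads: list[dict], max_norm: float) -> None:
    total = 0.0
    for sub, k in _iter_arrays(grads):
        total += float(np.sum(sub[k] ** 2))
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / norm
        for sub, k in _iter_arrays(grads):
            sub[k] *= scale


# ---------------------------------------------------------------------------
# Public training / prediction API
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    spec: RegressorSpec
    params: list[dict]
    train_log: list[dict] = field(default_factory=list)
    selected_epoch: int = -1


def _check_pairs(spec: RegressorSpec, pairs, what: str) -> None:
    if not pairs:
        raise ValueError(f"empty {what} set")
    for x, y in pairs:
        if x.shape[0] != y.shape[0]:
            raise ValueError(f"{what}: paired sequences must share length")
        if x.shape[1] != spec.input_dim or y.shape[1] != spec.output_dim:
            raise ValueError(
                f"{what}: dims ({x.shape[1]}, {y.shape[1]}) do not match spec "
                f"({spec.input_dim}, {spec.output_dim})"
            )


def _mean_loss(spec: RegressorSpec, params: list[dict], pairs) -> float:
    losses = [float(np.mean((_forward(spec, params, x) - y) ** 2)) for x, y in pairs]
    return float(np.mean(losses))


def train_regressor(spec: RegressorSpec, train_pairs, val_pairs, seed: int = 0) -> TrainedModel:
    """Train a regressor on (input, output) sequence pairs.

    ``train_pairs``/``val_pairs`` are lists of ``(X, Y)`` arrays of equal
    per-pair length.  One whole sentence per optimisation step; the model
    state returned is the one with the lowest validation loss.
    """
    _check_pairs(spec, train_pairs, "training")
    _check_pairs(spec, val_pairs, "validation")
    rng = np.random.default_rng(seed)
    params = _init_params(spec, rng)
    opt = _Adam(params, spec.learning_rate)
    log: list[dict] = []
    best_val = np.inf
    best_params = copy.deepcopy(params)
    best_epoch = -1
    for epoch in range(spec.max_epochs):
        order = rng.permutation(len(train_pairs))
        epoch_loss = 0.0
        for idx in order:
            x, y = train_pairs[idx]
            pred, caches = _forward(spec, params, x, want_cache=True)
            err = pred - y
            epoch_loss += float(np.mean(err**2))
            dY = 2.0 * err / err.size
            grads = _backward(spec, params, caches, dY)
            _clip_global_norm(grads, spec.clip_norm)
            opt.step(params, grads)
        val_loss = _mean_loss(spec, params, val_pairs)
        log.append({"epoch": epoch, "train_loss": epoch_loss / len(train_pairs),
                    "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_params = copy.deepcopy(params)
            best_epoch = epoch
    return TrainedModel(spec=spec, params=best_params, train_log=log,
                        selected_epoch=best_epoch)


def predict_sequence(model: TrainedModel, input_frames: np.ndarray) -> np.ndarray:
    """Frame-synchronous prediction: T input frames → T output frames."""
    X = np.atleast_2d(np.asarray(input_frames, dtype=np.float64))
    if X.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"input dim {X.shape[1]} does not match spec {model.spec.input_dim}")
    return _forward(model.spec, model.params, X)


def untrained_model(spec: RegressorSpec, seed: int = 0) -> TrainedModel:
    """Freshly initialised model (baseline for smoke comparisons)."""
    return TrainedModel(spec=spec, params=_init_params(spec, np.random.default_rng(seed)))
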