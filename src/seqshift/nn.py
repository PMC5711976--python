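"""Feedforward refiner network: 143 inputs, 50 tanh hidden nodes, one output.

Inputs encode a 7-residue secondary-structure window (3 state indicators plus
a terminal indicator per position) and a 5-residue sequence window (23
BLOSUM-62 derived nodes per position). One network is trained per atom type on
secondary-shift targets, with Adam minimizing the mean squared error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .idp import PredictionTable, _atom_applicable
from .kernel import KernelModel
from .residues import ALPHABET23, blosum_vector

logger = logging.getLogger(__name__)

SS_WINDOW = 7  # residues in the secondary-structure window
SEQ_WINDOW = 5  # residues in the sequence window
N_SS_NODES = SS_WINDOW * 4
N_SEQ_NODES = SEQ_WINDOW * len(ALPHABET23)
N_INPUT = N_SS_NODES + N_SEQ_NODES  # 143
N_HIDDEN = 50

_STATE_SLOT = {"H": 0, "E": 1, "C": 2}


def encode(seq_keys, q3_labels, center: int) -> np.ndarray:
    """143-float input vector for the residue at 0-based ``center``.

    SS nodes: for each of the 7 window positions, three state indicators and a
    terminal indicator (1 outside the chain, where the state nodes are zero).
    Sequence nodes: for each of the 5 window positions, the 23-slot BLOSUM-62
    encoding of the residue category (zeros outside the chain).
    """
    n = len(seq_keys)
    if not 0 <= center < n:
        raise ValueError("center index outside sequence")
    x = np.zeros(N_INPUT)
    half_ss = SS_WINDOW // 2
    for k in range(SS_WINDOW):
        pos = center - half_ss + k
        base = 4 * k
        if 0 <= pos < n:
            x[base + _STATE_SLOT[q3_labels[pos]]] = 1.0
        else:
            x[base + 3] = 1.0
    half_seq = SEQ_WINDOW // 2
    for k in range(SEQ_WINDOW):
        pos = center - half_seq + k
        base = N_SS_NODES + 23 * k
        if 0 <= pos < n and seq_keys[pos] is not None:
            x[base : base + 23] = blosum_vector(seq_keys[pos])
    return x


@dataclass
class NNModel:
    """Weights plus input/target standardization for one atom type."""

    atom: str
    W1: np.ndarray  # (143, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_std: float

    def __post_init__(self):
        if self.W1.shape[0] != N_INPUT:
            raise ValueError("input dimension mismatch")
        for arr in (self.W1, self.b1, self.w2, self.x_mean, self.x_scale):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite weights")


def forward(x, model: NNModel):
    """De-standardized network output for one encoding or a batch of them."""
    arr = np.asarray(x, dtype=float)
    single = arr.ndim == 1
    if arr.shape[-1] != N_INPUT:
        raise ValueError(f"expected {N_INPUT} inputs, got {arr.shape[-1]}")
    z = (arr - model.x_mean) / model.x_scale
    h = np.tanh(z @ model.W1 + model.b1)
    out = h @ model.w2 + model.b2
    out = out * model.y_std + model.y_mean
    return float(out) if single else out


@dataclass
class TrainConfig:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    epochs: int = 200
    batch_size: int = 64
    hidden: int = N_HIDDEN
    seed: int = 0
    val_fraction: float = 0.0  # >0 enables early stopping on a held-out split
    patience: int = 10


def train_network(X, y, atom: str, config: TrainConfig | None = None) -> NNModel:
    """Fit one refiner network by Adam on the MSE; deterministic given the seed."""
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_INPUT:
        raise ValueError(f"X must be (n, {N_INPUT})")
    if len(y) != len(X) or len(y) == 0:
        raise ValueError("need at least one (encoding, shift) pair")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0.0] = 1.0
    y_mean = float(y.mean())
    y_std = float(y.std())
    if y_std == 0.0:
        logger.warning("degenerate constant targets for %s", atom)
        y_std = 1.0
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_std

    rng = np.random.default_rng(config.seed)

    x_val = y_val = None
    if config.val_fraction > 0.0 and len(Xs) >= 10:
        split = rng.permutation(len(Xs))
        n_val = max(1, int(round(config.val_fraction * len(Xs))))
        x_val, y_val = Xs[split[:n_val]], ys[split[:n_val]]
        Xs, ys = Xs[split[n_val:]], ys[split[n_val:]]

    h = config.hidden
    params = {
        "W1": rng.normal(0.0, 1.0 / np.sqrt(N_INPUT), size=(N_INPUT, h)),
        "b1": np.zeros(h),
        "w2": rng.normal(0.0, 1.0 / np.sqrt(h), size=h),
        "b2": np.zeros(1),
    }
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    t = 0
    n = len(Xs)
    best_val = np.inf
    best_params = None
    stall = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, tb = Xs[idx], ys[idx]
            hid = np.tanh(xb @ params["W1"] + params["b1"])
            out = hid @ params["w2"] + params["b2"][0]
            err = out - tb
            dout = 2.0 * err / len(idx)
            grads = {
                "w2": hid.T @ dout,
                "b2": np.array([dout.sum()]),
            }
            dh = np.outer(dout, params["w2"]) * (1.0 - hid * hid)
            grads["W1"] = xb.T @ dh
            grads["b1"] = dh.sum(axis=0)
            t += 1
            corr1 = 1.0 - config.beta1**t
            corr2 = 1.0 - config.beta2**t
            for k in params:
                m[k] = config.beta1 * m[k] + (1.0 - config.beta1) * grads[k]
                v[k] = config.beta2 * v[k] + (1.0 - config.beta2) * grads[k] ** 2
                params[k] -= config.lr * (m[k] / corr1) / (np.sqrt(v[k] / corr2) + config.eps)
        if x_val is not None:
            val_out = np.tanh(x_val @ params["W1"] + params["b1"]) @ params["w2"] + params["b2"][0]
            val_mse = float(np.mean((val_out - y_val) ** 2))
            if val_mse < best_val - 1e-6:
                best_val = val_mse
                best_params = {k: p.copy() for k, p in params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
    if best_params is not None:
        params = best_params

    return NNModel(
        atom=atom,
        W1=params["W1"],
        b1=params["b1"],
        w2=params["w2"],
        b2=float(params["b2"][0]),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_std=y_std,
    )


def training_mse(model: NNModel, X, y) -> float:
    pred = forward(np.asarray(X, dtype=float), model)
    return float(np.mean((pred - np.asarray(y, dtype=float)) ** 2))


# ---------------------------------------------------------------------------
# dataset assembly and prediction


def build_training_set(entries, coil_model: KernelModel, atom: str, q3_map=None):
    """(X, y) pairs for one atom: encodings vs secondary-shift targets.

    ``q3_map`` optionally overrides the Q3 labels used on the input side (e.g.
    predicted or corrupted labels); targets always use the observed shifts.
    """
    xs, ys = [], []
    for entry in entries:
        labels = (q3_map or {}).get(entry.entry_id)
        if labels is None:
            if entry.q3 is None:
                continue
            labels = "".join(entry.q3)
        keys = [None if r is None else r.key for r in entry.sequence]
        for rec in entry.records:
            if rec.atom != atom:
                continue
            coil = coil_model.expectation(atom, rec.residue.key)
            if coil is None:
                continue
            xs.append(encode(keys, labels, rec.residue_index - 1))
            ys.append(rec.shift - coil)
    if not xs:
        raise ValueError(f"no training pairs for atom {atom}")
    return np.asarray(xs), np.asarray(ys)


def train_refiner(entries, coil_model: KernelModel, atoms, config=None, q3_map=None) -> dict:
    """Train one network per atom; returns {atom: NNModel}."""
    out = {}
    for atom in atoms:
        X, y = build_training_set(entries, coil_model, atom, q3_map=q3_map)
        out[atom] = train_network(X, y, atom, config)
    return out


def predict_nn(sequence, q3_labels, nn_models: dict, coil_model: KernelModel, atoms=None):
    """Refiner prediction: coil expectation plus the network's secondary shift."""
    if isinstance(q3_labels, str):
        labels = q3_labels
    else:
        labels = "".join(q3_labels.labels if hasattr(q3_labels, "labels") else q3_labels)
    if len(labels) != len(sequence):
        raise ValueError("Q3 labels and sequence differ in length")
    keys = [None if r is None else r.key for r in sequence]
    atoms = list(atoms) if atoms is not None else sorted(nn_models)
    rows = []
    for pos, key in enumerate(keys):
        if key is None:
            continue
        x = None
        for atom in atoms:
            model = nn_models.get(atom)
            if model is None or not _atom_applicable(atom, key):
                continue
            coil = coil_model.expectation(atom, key)
            if coil is None:
                continue
            if x is None:
                x = encode(keys, labels, pos)
            sec = forward(x, model)
            rows.append(
                {
                    "res_index": pos + 1,
                    "res": key,
                    "atom": atom,
                    "shift": coil + sec,
                    "primary": coil,
                    "correction": sec,
                    "flags": "",
                }
            )
    return PredictionTable(
        pd.DataFrame(
            rows, columns=["res_index", "res", "atom", "shift", "primary", "correction", "flags"]
        )
    )


# ---------------------------------------------------------------------------
# serialization


def nn_to_dict(model: NNModel) -> dict:
    return {
        "atom": model.atom,
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2,
        "x_mean": model.x_mean.tolist(),
        "x_scale": model.x_scale.tolist(),
        "y_mean": model.y_mean,
        "y_std": model.y_std,
    }


def nn_from_dict(d: dict) -> NNModel:
    return NNModel(
        atom=d["atom"],
        W1=np.asarray(d["W1"]),
        b1=np.asarray(d["b1"]),
        w2=np.asarray(d["w2"]),
        b2=d["b2"],
        x_mean=np.asarray(d["x_mean"]),
        x_scale=np.asarray(d["x_scale"]),
        y_mean=d["y_mean"],
        y_std=d["y_std"],
    )
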