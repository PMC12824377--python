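"""ClassNet and EdgeNet: the two neural classifiers of the pipeline.

ClassNet is a per-pulse 1-D CNN (two conv/ReLU/max-pool stages, two fully
connected layers, softmax over 8 chemicals + background).  EdgeNet is a
per-pixel set classifier: each of the 8 (zero-padded) pulse rows is
linearly embedded, passed through a 4-layer pre-norm transformer encoder
with 8 attention heads and *no positional encoding*, mean-pooled over the
sequence axis and projected to Edge/Other probabilities.  Without
positional information and with mean pooling, EdgeNet is exactly
invariant to any permutation of its pulse rows, which is the point: the
arrival order of reflections is treated as unknown.

Both models are trained from scratch with Adam (lr 1e-3, batch 64,
cross-entropy), seeded and single-threaded for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import nn
from .config import ClassNetConfig, EdgeNetConfig, TrainConfig, to_dict
from .nn import Tensor


class ModelError(ValueError):
    pass


def _softmax_np(z: np.ndarray) -> np.ndarray:
    # float64: saturated probabilities must stay ordered by logit margin,
    # or the winner-takes-all fusion degenerates into index-order ties
    z = np.asarray(z, dtype=np.float64)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class ClassNet:
    """Per-pulse chemical classifier (9-way CNN).

    Input segments are amplitude-normalized (divided by their peak
    |amplitude|) before the convolutional stack: the chemical information
    lives in the pulse *shape* (absorption ring-down), which stays
    consistent under edge scattering, partial beam overlap and cover
    attenuation, whereas raw amplitude varies with all of them.  Amplitude
    cues remain available to the edge detector, which sees raw pulses.
    """

    def __init__(self, cfg: ClassNetConfig | None = None, seed: int = 0):
        self.cfg = cfg or ClassNetConfig()
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
        c1, k1 = self.cfg.conv1
        c2, k2 = self.cfg.conv2
        pool = self.cfg.pool
        l1 = (self.cfg.input_len - k1 + 1) // pool
        l2 = (l1 - k2 + 1) // pool
        self.flat = c2 * l2
        self.params: Dict[str, Tensor] = {
            "w1": nn.he_init(rng, (c1, 1, k1), k1),
            "b1": nn.zeros((c1,)),
            "w2": nn.he_init(rng, (c2, c1, k2), c1 * k2),
            "b2": nn.zeros((c2,)),
            "wf1": nn.he_init(rng, (self.flat, self.cfg.hidden), self.flat),
            "bf1": nn.zeros((self.cfg.hidden,)),
            # final layer zero-initialized: the untrained network outputs the
            # uniform distribution
            "wf2": nn.zeros((self.cfg.hidden, self.cfg.n_classes)),
            "bf2": nn.zeros((self.cfg.n_classes,)),
        }

    def logits(self, x: np.ndarray) -> Tensor:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[-1] != self.cfg.input_len:
            raise ModelError(
                f"expected segments of length {self.cfg.input_len}, got {x.shape[-1]}")
        if not np.all(np.isfinite(x)):
            raise ModelError("non-finite input")
        peak = np.abs(x).max(axis=-1, keepdims=True)
        x = x / np.where(peak > 0, peak, 1.0)
        p = self.params
        t = Tensor(x[:, None, :])  # B, 1, L
        t = nn.maxpool1d(nn.relu(nn.conv1d(t, p["w1"], p["b1"])), self.cfg.pool)
        t = nn.maxpool1d(nn.relu(nn.conv1d(t, p["w2"], p["b2"])), self.cfg.pool)
        t = nn.reshape(t, (x.shape[0], self.flat))
        t = nn.relu(nn.add(nn.matmul(t, p["wf1"]), p["bf1"]))
        return nn.add(nn.matmul(t, p["wf2"]), p["bf2"])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax_np(self.logits(x).data)


def classnet_forward(segment: np.ndarray, model: ClassNet) -> np.ndarray:
    """Probability simplex over the 9 classes for one 650-sample pulse."""
    return model.predict_proba(np.asarray(segment)[None, :])[0]


class EdgeNet:
    """Per-pixel set transformer for binary edge detection."""

    def __init__(self, cfg: EdgeNetConfig | None = None, seed: int = 0):
        self.cfg = cfg or EdgeNetConfig()
        if self.cfg.d_model % self.cfg.n_heads:
            raise ModelError("d_model must be divisible by n_heads")
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
        d, h = self.cfg.d_model, self.cfg.n_heads
        L = self.cfg.input_len
        m = self.cfg.mlp_dim
        p: Dict[str, Tensor] = {
            "embed_w": nn.xavier_init(rng, (L, d), L, d),
            "embed_b": nn.zeros((d,)),
        }
        for i in range(self.cfg.n_layers):
            p[f"ln1g_{i}"] = nn.ones((d,))
            p[f"ln1b_{i}"] = nn.zeros((d,))
            for name in ("q", "k", "v", "o"):
                p[f"w{name}_{i}"] = nn.xavier_init(rng, (d, d), d, d)
                p[f"b{name}_{i}"] = nn.zeros((d,))
            p[f"ln2g_{i}"] = nn.ones((d,))
            p[f"ln2b_{i}"] = nn.zeros((d,))
            p[f"mlp1w_{i}"] = nn.he_init(rng, (d, m), d)
            p[f"mlp1b_{i}"] = nn.zeros((m,))
            p[f"mlp2w_{i}"] = nn.xavier_init(rng, (m, d), m, d)
            p[f"mlp2b_{i}"] = nn.zeros((d,))
        p["lnfg"] = nn.ones((d,))
        p["lnfb"] = nn.zeros((d,))
        p["head_w"] = nn.zeros((d, self.cfg.n_classes))
        p["head_b"] = nn.zeros((self.cfg.n_classes,))
        self.params = p

    def _attention(self, x: Tensor, i: int) -> Tensor:
        p = self.params
        d, h = self.cfg.d_model, self.cfg.n_heads
        dh = d // h
        B, T = x.shape[0], x.shape[1]

        def split(name):
            t = nn.add(nn.matmul(x, p[f"w{name}_{i}"]), p[f"b{name}_{i}"])
            return nn.transpose(nn.reshape(t, (B, T, h, dh)), (0, 2, 1, 3))

        q, k, v = split("q"), split("k"), split("v")
        scores = nn.mul(nn.matmul(q, nn.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
        att = nn.matmul(nn.softmax(scores, axis=-1), v)  # B,h,T,dh
        att = nn.reshape(nn.transpose(att, (0, 2, 1, 3)), (B, T, d))
        return nn.add(nn.matmul(att, p[f"wo_{i}"]), p[f"bo_{i}"])

    def logits(self, x: np.ndarray) -> Tensor:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, :, :]
        if x.shape[1:] != (self.cfg.set_size, self.cfg.input_len):
            raise ModelError(
                f"expected pulse sets of shape "
                f"({self.cfg.set_size}, {self.cfg.input_len}), got {x.shape[1:]}")
        p = self.params
        t = nn.add(nn.matmul(Tensor(x), p["embed_w"]), p["embed_b"])  # B,T,d
        for i in range(self.cfg.n_layers):
            normed = nn.layer_norm(t, p[f"ln1g_{i}"], p[f"ln1b_{i}"])
            t = nn.add(t, self._attention(normed, i))
            normed = nn.layer_norm(t, p[f"ln2g_{i}"], p[f"ln2b_{i}"])
            ff = nn.relu(nn.add(nn.matmul(normed, p[f"mlp1w_{i}"]), p[f"mlp1b_{i}"]))
            ff = nn.add(nn.matmul(ff, p[f"mlp2w_{i}"]), p[f"mlp2b_{i}"])
            t = nn.add(t, ff)
        t = nn.layer_norm(t, p["lnfg"], p["lnfb"])
        pooled = nn.mean(t, axis=1)  # B,d -- permutation-invariant
        return nn.add(nn.matmul(pooled, p["head_w"]), p["head_b"])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax_np(self.logits(x).data)


def edgenet_forward(pulse_set: np.ndarray, model: EdgeNet) -> np.ndarray:
    """Probability simplex {Edge, Other} for one 8 x 650 pulse stack."""
    return model.predict_proba(np.asarray(pulse_set)[None, :, :])[0]


# ---------------------------------------------------------------------------
# training


@dataclass
class SupervisedDataset:
    """Training arrays with scene-level grouping for leakage-free splits."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray  # scene id per sample


def split_by_scene(ds: SupervisedDataset, fraction: float, seed: int
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean (train, val) masks splitting whole scenes, never samples."""
    scenes = np.unique(ds.groups)
    n_val = int(round(fraction * scenes.size))
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    val_scenes = set(rng.permutation(scenes)[:n_val].tolist())
    val = np.isin(ds.groups, list(val_scenes)) if val_scenes else np.zeros(
        ds.y.shape, dtype=bool)
    return ~val, val


def _balanced_batches(y: np.ndarray, idx_pool: np.ndarray, per_class: int,
                      batch: int, rng: np.random.Generator) -> List[np.ndarray]:
    classes = np.unique(y[idx_pool])
    chosen = []
    for c in classes:
        pool_c = idx_pool[y[idx_pool] == c]
        chosen.append(rng.choice(pool_c, size=per_class, replace=True))
    order = rng.permutation(np.concatenate(chosen))
    return [order[i:i + batch] for i in range(0, order.size, batch)]


def train_model(ds: SupervisedDataset, model, cfg: TrainConfig
                ) -> Tuple[object, pd.DataFrame]:
    """Train ClassNet or EdgeNet with Adam + cross-entropy.

    The validation split is by scene; per-class balanced resampling
    counteracts the heavy background majority.  Returns the model and a
    per-epoch history (loss, validation loss/accuracy)."""
    cfg.validate()
    if np.unique(ds.y).size < 2:
        raise ModelError("training dataset contains a single class")
    train_mask, val_mask = split_by_scene(ds, cfg.split_fraction, cfg.seed)
    train_idx = np.flatnonzero(train_mask)
    val_idx = np.flatnonzero(val_mask)
    if np.unique(ds.y[train_idx]).size < 2:
        raise ModelError("training split contains a single class")
    X = np.asarray(ds.X, dtype=np.float32)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(4,)))
    opt = nn.Adam(model.params, lr=cfg.lr)
    history = []
    for epoch in range(cfg.epochs):
        if cfg.balanced:
            batches = _balanced_batches(ds.y, train_idx, cfg.samples_per_class,
                                        cfg.batch, rng)
        else:
            order = rng.permutation(train_idx)
            batches = [order[i:i + cfg.batch] for i in range(0, order.size, cfg.batch)]
        losses = []
        for bidx in batches:
            opt.zero_grad()
            loss = nn.cross_entropy(model.logits(X[bidx]), ds.y[bidx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_idx.size:
            vloss, vacc = evaluate_model(model, X[val_idx], ds.y[val_idx])
            rec["val_loss"] = vloss
            rec["val_accuracy"] = vacc
        history.append(rec)
    return model, pd.DataFrame(history)


def evaluate_model(model, X: np.ndarray, y: np.ndarray,
                   batch: int = 256) -> Tuple[float, float]:
    """(mean cross-entropy, accuracy) without gradient bookkeeping."""
    losses, correct = [], 0
    for i in range(0, len(y), batch):
        xb, yb = X[i:i + batch], y[i:i + batch]
        p = model.predict_proba(xb)
        eps = np.finfo(np.float32).tiny
        losses.append(-np.log(p[np.arange(len(yb)), yb] + eps))
        correct += int((p.argmax(axis=1) == yb).sum())
    return float(np.concatenate(losses).mean()), correct / len(y)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model, train_cfg: Optional[TrainConfig], path) -> None:
    meta = {
        "kind": type(model).__name__,
        "net_cfg": to_dict(model.cfg),
        "train_cfg": to_dict(train_cfg) if train_cfg else None,
    }
    arrays = {k: p.data for k, p in model.params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path):
    z = np.load(path)
    meta = json.loads(bytes(z["__meta__"]).decode())
    cfg_d = meta["net_cfg"]
    if meta["kind"] == "ClassNet":
        cfg_d = dict(cfg_d)
        cfg_d["conv1"] = tuple(cfg_d["conv1"])
        cfg_d["conv2"] = tuple(cfg_d["conv2"])
        model = ClassNet(ClassNetConfig(**cfg_d))
    elif meta["kind"] == "EdgeNet":
        model = EdgeNet(EdgeNetConfig(**cfg_d))
    else:
        raise ModelError(f"unknown checkpoint kind {meta['kind']}")
    for k in model.params:
        model.params[k].data = z[k]
    return model
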