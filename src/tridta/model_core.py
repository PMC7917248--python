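"""The three-tunnel affinity model.

Architecture
------------
* Drug tunnel: a four-layer MLP on the 1024-bit fingerprint with layer
  widths 1024 -> 256 -> 64 -> 256 and ReLU activations.
* Protein tunnel: three 1-D convolutions (32 filters each, ReLU) over the
  1000 x 26 one-hot sequence matrix, then global max pooling over positions.
* Both tunnel outputs pass through a learned affine projection into one
  shared metric space (default 256-d) so that Euclidean distances between
  protein and drug representations are well-defined.
* Regression head: the protein (anchor) and drug embeddings are
  concatenated and fed through fully connected layers (1024, 1024, 512, 1)
  with dropout after the first two; the scalar output is the predicted pKd.

The negative tunnel shares weights with the drug tunnel: the same encoder
is applied to the record's drug and to the sampled negative drug. During
training the protein/drug/negative embeddings of each *positive* record
form a triplet whose loss

    L = max(||a - p||^2 - ||a - n||^2 + M, 0),   M = 1 by default,

pulls strong binders toward their protein and pushes the weak binder away.
The training objective is MSE(predicted pKd, true pKd) over the whole batch
plus ``triplet_weight`` times the mean triplet loss over the batch's
positive records (zero when the batch has none).
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .featurization import FP_BITS, FP_RADIUS, PROTEIN_MAX_LEN, PROTEIN_VOCAB

__all__ = ["ModelConfig", "ThreeTunnelModel", "triplet_loss", "load_model"]


@dataclass
class ModelConfig:
    """Hyperparameters of the three-tunnel model and its training loop."""

    mlp_widths: list[int] = field(default_factory=lambda: [1024, 256, 64, 256])
    cnn_filters: list[int] = field(default_factory=lambda: [32, 32, 32])
    cnn_kernel_lengths: list[int] = field(default_factory=lambda: [4, 8, 12])
    shared_dim: int = 256
    fc_widths: list[int] = field(default_factory=lambda: [1024, 1024, 512])
    dropout_rates: list[float] = field(default_factory=lambda: [0.1, 0.1])
    margin: float = 1.0
    triplet_weight: float = 1.0
    learning_rate: float = 1e-4
    batch_size: int = 256
    epochs: int = 100
    seed: int = 0
    prot_max_len: int = PROTEIN_MAX_LEN
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.triplet_weight < 0:
            raise ValueError("triplet_weight must be non-negative")
        if any(not (0 <= r < 1) for r in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")
        if len(self.cnn_filters) != len(self.cnn_kernel_lengths):
            raise ValueError("cnn_filters and cnn_kernel_lengths lengths differ")
        if len(self.mlp_widths) < 2:
            raise ValueError("drug MLP needs at least input and output widths")

    @classmethod
    def literal_kernels(cls, **kwargs) -> "ModelConfig":
        """Preset reading the kernel spec literally as lengths 1, 2, 3."""
        kwargs.setdefault("cnn_kernel_lengths", [1, 2, 3])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def triplet_loss(anchor, positive, negative, margin: float = 1.0):
    """``max(||a - p||^2 - ||a - n||^2 + margin, 0)`` per triplet.

    Accepts single vectors (returns a float) or ``(batch, dim)`` arrays
    (returns a per-row array). Distances are squared Euclidean.
    """
    a = np.asarray(anchor, dtype=float)
    p = np.asarray(positive, dtype=float)
    n = np.asarray(negative, dtype=float)
    if not (a.shape == p.shape == n.shape):
        raise ValueError(
            f"triplet vectors must share a shape, got {a.shape}, {p.shape}, {n.shape}"
        )
    d_ap = np.sum((a - p) ** 2, axis=-1)
    d_an = np.sum((a - n) ** 2, axis=-1)
    loss = np.maximum(d_ap - d_an + margin, 0.0)
    return float(loss) if a.ndim == 1 else loss


class ThreeTunnelModel:
    """Drug MLP + protein CNN + shared projection + regression head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        dtype = np.dtype(config.dtype)
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        w = config.mlp_widths
        self.drug_layers = [
            _nn.Dense(w[i], w[i + 1], rng, dtype) for i in range(len(w) - 1)
        ]
        filters = config.cnn_filters
        kernels = config.cnn_kernel_lengths
        chans = [len(PROTEIN_VOCAB)] + list(filters)
        self.prot_layers = [
            _nn.Conv1d(kernels[i], chans[i], chans[i + 1], rng, dtype)
            for i in range(len(filters))
        ]
        self.proj_drug = _nn.Dense(w[-1], config.shared_dim, rng, dtype)
        self.proj_prot = _nn.Dense(filters[-1], config.shared_dim, rng, dtype)
        fc = [2 * config.shared_dim] + list(config.fc_widths) + [1]
        self.head_layers = [
            _nn.Dense(fc[i], fc[i + 1], rng, dtype) for i in range(len(fc) - 1)
        ]
        self._layers = (
            self.drug_layers
            + self.prot_layers
            + [self.proj_drug, self.proj_prot]
            + self.head_layers
        )

    # ---- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [p for lay in self._layers for p in lay.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for lay in self._layers for g in lay.grads]

    def zero_grads(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    # ---- tunnels ------------------------------------------------------------

    def _cast(self, x) -> np.ndarray:
        return np.ascontiguousarray(np.asarray(x), dtype=self.dtype)

    def _drug_forward(self, fp: np.ndarray):
        h = self._cast(fp)
        if h.shape[1] != self.config.mlp_widths[0]:
            raise ValueError(
                f"fingerprint length {h.shape[1]} does not match the drug "
                f"MLP input width {self.config.mlp_widths[0]}"
            )
        caches = []
        for lay in self.drug_layers:
            z, cz = lay.forward(h)
            h, cm = _nn.relu_forward(z)
            caches.append((cz, cm))
        s, cp = self.proj_drug.forward(h)
        return s, (caches, cp)

    def _drug_backward(self, g: np.ndarray, cache) -> None:
        caches, cp = cache
        g = self.proj_drug.backward(g, cp)
        for lay, (cz, cm) in zip(reversed(self.drug_layers), reversed(caches)):
            g = lay.backward(_nn.relu_backward(g, cm), cz)

    def _prot_forward(self, enc: np.ndarray):
        h = self._cast(enc)
        caches = []
        for lay in self.prot_layers:
            z, cz = lay.forward(h)
            h, cm = _nn.relu_forward(z)
            caches.append((cz, cm))
        pooled, cpool = _nn.global_max_pool_forward(h)
        s, cp = self.proj_prot.forward(pooled)
        return s, (caches, cpool, cp)

    def _prot_backward(self, g: np.ndarray, cache) -> None:
        caches, cpool, cp = cache
        g = self.proj_prot.backward(g, cp)
        g = _nn.global_max_pool_backward(g, cpool)
        for lay, (cz, cm) in zip(reversed(self.prot_layers), reversed(caches)):
            g = lay.backward(_nn.relu_backward(g, cm), cz)

    def _head_forward(self, x: np.ndarray, train: bool, rng):
        h = x
        caches = []
        n_drop = len(self.config.dropout_rates)
        for i, lay in enumerate(self.head_layers[:-1]):
            z, cz = lay.forward(h)
            h, cm = _nn.relu_forward(z)
            rate = self.config.dropout_rates[i] if (train and i < n_drop) else 0.0
            h, ck = _nn.dropout_forward(h, rate, rng)
            caches.append((cz, cm, ck))
        out, cz = self.head_layers[-1].forward(h)
        return out[:, 0], (caches, cz)

    def _head_backward(self, g: np.ndarray, cache) -> np.ndarray:
        caches, cz_last = cache
        g = self.head_layers[-1].backward(g[:, None], cz_last)
        for lay, (cz, cm, ck) in zip(
            reversed(self.head_layers[:-1]), reversed(caches)
        ):
            g = _nn.dropout_backward(g, ck)
            g = lay.backward(_nn.relu_backward(g, cm), cz)
        return g

    # ---- public inference ---------------------------------------------------

    def drug_representation(self, fp: np.ndarray) -> np.ndarray:
        """Drug-tunnel output before the shared projection (width 256)."""
        h = self._cast(np.atleast_2d(fp))
        if h.shape[1] != self.config.mlp_widths[0]:
            raise ValueError(
                f"fingerprint length {h.shape[1]} does not match the drug "
                f"MLP input width {self.config.mlp_widths[0]}"
            )
        for lay in self.drug_layers:
            z, _ = lay.forward(h)
            h, _ = _nn.relu_forward(z)
        return h

    def protein_representation(self, enc: np.ndarray) -> np.ndarray:
        """Protein-tunnel output before the projection (width = last filter)."""
        h = self._cast(enc if enc.ndim == 3 else enc[None])
        for lay in self.prot_layers:
            z, _ = lay.forward(h)
            h, _ = _nn.relu_forward(z)
        pooled, _ = _nn.global_max_pool_forward(h)
        return pooled

    def encode_drug(self, fp: np.ndarray) -> np.ndarray:
        """Shared-space drug embedding, shape (batch, shared_dim)."""
        out, _ = self.proj_drug.forward(self.drug_representation(fp))
        return out

    def encode_protein(self, enc: np.ndarray) -> np.ndarray:
        """Shared-space protein embedding, shape (batch, shared_dim)."""
        out, _ = self.proj_prot.forward(self.protein_representation(enc))
        return out

    def predict(self, fp: np.ndarray, enc: np.ndarray) -> np.ndarray:
        """Predicted pKd for aligned drug/protein batches (evaluation mode)."""
        d = self.encode_drug(np.atleast_2d(fp))
        p = self.encode_protein(enc if enc.ndim == 3 else enc[None])
        if d.shape[0] == 1 and p.shape[0] > 1:
            d = np.broadcast_to(d, (p.shape[0], d.shape[1]))
        if p.shape[0] == 1 and d.shape[0] > 1:
            p = np.broadcast_to(p, (d.shape[0], p.shape[1]))
        x = np.concatenate([p, d], axis=1).astype(self.dtype)
        out, _ = self._head_forward(x, train=False, rng=None)
        return out

    # ---- training objective -------------------------------------------------

    def loss_and_grads(
        self,
        fp: np.ndarray,
        enc: np.ndarray,
        y: np.ndarray,
        neg_fp: np.ndarray,
        pos_mask: np.ndarray,
        train: bool = True,
        rng: np.random.Generator | None = None,
    ) -> dict[str, float]:
        """Combined loss on one batch; gradients accumulate into the layers.

        ``fp``/``enc``/``y`` are the batch's drug fingerprints, protein
        encodings and true pKd; ``neg_fp`` holds the sampled negative
        drug's fingerprint per record and ``pos_mask`` flags positive
        records (only those contribute triplet terms). With
        ``train=False`` dropout is disabled, which makes the loss (and its
        gradient) deterministic.
        """
        if train and rng is None:
            rng = np.random.default_rng(0)
        B = len(y)
        y = np.asarray(y, dtype=self.dtype)
        pos_mask = np.asarray(pos_mask, dtype=bool)
        lam = self.config.triplet_weight

        d_shared, d_cache = self._drug_forward(fp)
        p_shared, p_cache = self._prot_forward(enc)
        x = np.concatenate([p_shared, d_shared], axis=1)
        yhat, h_cache = self._head_forward(x, train=train, rng=rng)

        resid = yhat - y
        mse = float(np.mean(resid**2))
        g_yhat = (2.0 / B) * resid.astype(self.dtype)
        g_concat = self._head_backward(g_yhat, h_cache)
        S = self.config.shared_dim
        g_p = np.ascontiguousarray(g_concat[:, :S])
        g_d = np.ascontiguousarray(g_concat[:, S:])

        trip = 0.0
        n_cache = None
        g_n = None
        n_pos = int(pos_mask.sum())
        if lam > 0 and n_pos > 0:
            n_shared, n_cache = self._drug_forward(
                np.atleast_2d(neg_fp)[pos_mask]
            )
            a = p_shared[pos_mask]
            p = d_shared[pos_mask]
            margin = self.config.margin
            per = (
                np.sum((a - p) ** 2, axis=1)
                - np.sum((a - n_shared) ** 2, axis=1)
                + margin
            )
            active = per > 0
            trip = float(np.sum(np.maximum(per, 0.0)) / n_pos)
            coef = (lam / n_pos) * active.astype(self.dtype)[:, None]
            g_p[pos_mask] += coef * 2.0 * (n_shared - p)
            g_d[pos_mask] += coef * (-2.0) * (a - p)
            g_n = coef * 2.0 * (a - n_shared)

        self._prot_backward(g_p, p_cache)
        self._drug_backward(g_d, d_cache)
        if g_n is not None:
            self._drug_backward(g_n, n_cache)

        return {"total": mse + lam * trip, "mse": mse, "triplet": trip}

    # ---- persistence --------------------------------------------------------

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.npz`` weights and a ``<prefix>.json`` sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        weights_path = prefix.with_suffix(".npz")
        meta_path = prefix.with_suffix(".json")
        np.savez(
            weights_path,
            **{f"param_{i}": p for i, p in enumerate(self.parameters())},
        )
        meta_path.write_text(
            json.dumps(
                {
                    "config": self.config.to_dict(),
                    "protein_vocab": PROTEIN_VOCAB,
                    "fingerprint": {"radius": FP_RADIUS, "n_bits": FP_BITS},
                },
                indent=2,
            )
        )
        return weights_path, meta_path

    def clone_weights(self) -> "ThreeTunnelModel":
        other = ThreeTunnelModel(copy.deepcopy(self.config))
        other.set_weights(self.get_weights())
        return other


def load_model(prefix: str | Path) -> ThreeTunnelModel:
    """Load a model saved by :meth:`ThreeTunnelModel.save`."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    if meta.get("protein_vocab") != PROTEIN_VOCAB:
        raise ValueError("checkpoint protein vocabulary differs from this build")
    model = ThreeTunnelModel(ModelConfig.from_dict(meta["config"]))
    data = np.load(prefix.with_suffix(".npz"))
    model.set_weights([data[f"param_{i}"] for i in range(len(data.files))])
    return model
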