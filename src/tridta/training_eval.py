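"""Training loop and evaluation metrics.

Training minimizes MSE on pKd plus the weighted triplet term with Adam on
minibatches; the dataset is shuffled once per epoch with a seeded
generator, so a run is reproducible bit-for-bit for a fixed seed and
config. After every epoch the model is scored on the validation split and
the checkpoint with the lowest validation MSE is returned.

Evaluation reports mean squared error and the concordance index (CI): the
fraction of record pairs with different true affinity whose predicted
ordering matches the true ordering, counting prediction ties as 1/2.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .dataset_io import AffinityRecord, ExtendedDataset, split_records
from .featurization import featurize_drugs, featurize_proteins
from .model_core import ModelConfig, ThreeTunnelModel

__all__ = [
    "TrainingHistory",
    "train",
    "evaluate",
    "concordance_index",
    "mse",
    "DatasetFeatures",
]


@dataclass
class TrainingHistory:
    """Per-epoch training diagnostics."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    seed: int = 0
    config_hash: str = ""

    def append(self, train_loss: float, val_mse: float, val_ci: float) -> None:
        self.epochs.append(
            {
                "epoch": len(self.epochs) + 1,
                "train_loss": train_loss,
                "val_mse": val_mse,
                "val_ci": val_ci,
            }
        )

    def to_rows(self) -> list[dict]:
        return list(self.epochs)


def mse(y_true, y_pred) -> float:
    """Mean squared error."""
    t = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("mse needs at least one value")
    return float(np.mean((t - p) ** 2))


def concordance_index(y_true, y_pred) -> float:
    """Concordance index over pairs with distinct true values.

    A pair (i, j) with y_true[i] < y_true[j] scores 1 if
    y_pred[i] < y_pred[j], 1/2 if the predictions tie, 0 otherwise; pairs
    tied in y_true are not compared. Returns a value in [0, 1]; raises if
    every true value is identical (no comparable pair).
    """
    t = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and equal length")
    if t.size < 2:
        raise ValueError("concordance index needs at least two values")
    dt = t[:, None] - t[None, :]
    dp = p[:, None] - p[None, :]
    comparable = dt > 0  # ordered pairs, each unordered pair counted once
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("all true values are tied; CI is undefined")
    score = np.where(dp > 0, 1.0, np.where(dp == 0, 0.5, 0.0))
    return float(score[comparable].sum() / n_pairs)


class DatasetFeatures:
    """Cached fingerprints/encodings for every drug and protein of a dataset.

    Negative-sample SMILES normally point back at library drugs; any
    out-of-library SMILES is fingerprinted on demand and cached.
    """

    def __init__(self, dataset: ExtendedDataset, prot_max_len: int = 1000):
        base = dataset.base
        self.drug_fp = featurize_drugs(base.drug_smiles).astype(np.float32)
        self.prot_enc = featurize_proteins(
            base.protein_seqs, max_len=prot_max_len
        ).astype(np.float32)
        self._smiles_fp: dict[str, np.ndarray] = {
            s: self.drug_fp[i] for i, s in enumerate(base.drug_smiles)
        }

    def fingerprint_of(self, smiles: str) -> np.ndarray:
        if smiles not in self._smiles_fp:
            self._smiles_fp[smiles] = featurize_drugs([smiles])[0].astype(
                np.float32
            )
        return self._smiles_fp[smiles]

    def tensors(self, records: list[AffinityRecord]):
        """Assemble aligned arrays (fp, enc_index, y, neg_fp, pos_mask)."""
        fp = self.drug_fp[[r.drug_index for r in records]]
        prot_idx = np.array([r.protein_index for r in records])
        y = np.array([r.pkd for r in records], dtype=np.float32)
        neg_fp = np.stack(
            [self.fingerprint_of(r.negative_smiles) for r in records]
        )
        pos = np.array([r.label for r in records], dtype=bool)
        return fp, prot_idx, y, neg_fp, pos


def _config_hash(config: ModelConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _predict_records(
    model: ThreeTunnelModel,
    feats: DatasetFeatures,
    records: list[AffinityRecord],
    batch: int = 256,
) -> np.ndarray:
    fp = feats.drug_fp[[r.drug_index for r in records]]
    prot_idx = [r.protein_index for r in records]
    out = np.empty(len(records), dtype=float)
    for s in range(0, len(records), batch):
        sl = slice(s, s + batch)
        out[sl] = model.predict(fp[sl], feats.prot_enc[prot_idx[sl]])
    return out


def train(
    dataset: ExtendedDataset,
    config: ModelConfig,
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
) -> tuple[ThreeTunnelModel, TrainingHistory]:
    """Train on the 7:1:2 split of ``dataset``; return the best checkpoint.

    The test split is held out entirely -- re-derive it with
    :func:`tridta.dataset_io.split_records` and the same seed to score it.
    """
    records = dataset.records()
    train_recs, val_recs, _ = split_records(records, ratios, seed=config.seed)
    if not train_recs:
        raise ValueError("empty training split")
    feats = DatasetFeatures(dataset, prot_max_len=config.prot_max_len)
    fp, prot_idx, y, neg_fp, pos = feats.tensors(train_recs)
    val_y = np.array([r.pkd for r in val_recs], dtype=float)

    model = ThreeTunnelModel(config)
    # start predictions at the target mean so early steps refine structure
    # instead of walking the output bias toward ~5 pKd units
    model.head_layers[-1].b[...] = float(np.mean(y))
    opt = _nn.Adam(model.parameters(), model.gradients(), lr=config.learning_rate)
    rng_shuffle = np.random.default_rng(config.seed + 1)
    rng_dropout = np.random.default_rng(config.seed + 2)

    history = TrainingHistory(seed=config.seed, config_hash=_config_hash(config))
    best_val = np.inf
    best_weights = model.get_weights()
    n = len(train_recs)
    for _epoch in range(config.epochs):
        order = rng_shuffle.permutation(n)
        epoch_loss = 0.0
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            model.zero_grads()
            losses = model.loss_and_grads(
                fp[idx],
                feats.prot_enc[prot_idx[idx]],
                y[idx],
                neg_fp[idx],
                pos[idx],
                train=True,
                rng=rng_dropout,
            )
            opt.step()
            epoch_loss += losses["total"] * len(idx)
        epoch_loss /= n

        if val_recs:
            val_pred = _predict_records(model, feats, val_recs)
            v_mse = mse(val_y, val_pred)
            try:
                v_ci = concordance_index(val_y, val_pred)
            except ValueError:
                v_ci = float("nan")
        else:  # degenerate tiny datasets: fall back to training loss
            v_mse, v_ci = epoch_loss, float("nan")
        history.append(epoch_loss, v_mse, v_ci)
        if v_mse < best_val:
            best_val = v_mse
            history.best_epoch = len(history.epochs)
            best_weights = model.get_weights()

    model.set_weights(best_weights)
    return model, history


def evaluate(
    model: ThreeTunnelModel,
    dataset: ExtendedDataset,
    records: list[AffinityRecord] | None = None,
    features: DatasetFeatures | None = None,
) -> tuple[float, float]:
    """(MSE, CI) of the model's pKd predictions on ``records``.

    ``records`` defaults to the whole dataset; pass a split from
    :func:`split_records` to score held-out data. CI is NaN when all true
    values tie.
    """
    if records is None:
        records = dataset.records()
    if features is None:
        features = DatasetFeatures(dataset, prot_max_len=model.config.prot_max_len)
    y = np.array([r.pkd for r in records], dtype=float)
    pred = _predict_records(model, features, records)
    try:
        ci = concordance_index(y, pred)
    except ValueError:
        warnings.warn("all true values tied; CI undefined", stacklevel=2)
        ci = float("nan")
    return mse(y, pred), ci
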