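"""Joint autoencoder + feedforward regressor for drug-sensitivity prediction.

The model has three blocks:

* a mutation autoencoder compressing the binary driver-gene mutation vector
  R_C into a bottleneck embedding z_C,
* a drug autoencoder compressing the binary fingerprint R_D into z_D,
* a feedforward regressor that takes [pathway activities a, z_C, z_D] and
  predicts LN IC50 with a single linear output neuron.

Encoders/decoders are dense layers with batch normalization and ReLU; each
decoder ends in a sigmoid so reconstructions live in (0, 1).  Training is
end-to-end under the unified loss

    L = MSE(S, S') + lambda_C * BCE(R_C, R_C') + lambda_D * BCE(R_D, R_D')

optimized by Adam with mini-batch shuffling, validation-based early stopping,
and the best-validation state restored at the end.  All arithmetic is float64
and fully seeded, so identical configs give identical histories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._nn import Adam, BatchNorm, Dense, ReLU, Sequential

__all__ = [
    "AutoencoderSpec",
    "PredictorSpec",
    "TrainConfig",
    "Batch",
    "FeatureSet",
    "Autoencoder",
    "Predictor",
    "DrugResponseModel",
    "build_autoencoder",
    "bce",
    "unified_loss",
    "LossBreakdown",
    "train_end_to_end",
    "pretrain_autoencoder",
    "grid_search",
    "predict_pairs",
]

_EPS = 1e-12


@dataclass(frozen=True)
class AutoencoderSpec:
    """Widths of a symmetric 3-layer encoder / decoder pair."""

    input_dim: int
    hidden1: int
    hidden2: int
    bottleneck: int
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if not (self.input_dim > self.hidden1 >= self.hidden2 >= self.bottleneck >= 1):
            raise ValueError(
                "widths must satisfy input_dim > hidden1 >= hidden2 >= bottleneck >= 1; "
                f"got {self}"
            )

    @property
    def n_parameters(self) -> int:
        dims = [self.input_dim, self.hidden1, self.hidden2, self.bottleneck]
        n = 0
        for a, b in zip(dims[:-1], dims[1:]):  # encoder
            n += a * b + b + (2 * b if self.batch_norm else 0)
        for a, b in zip(dims[::-1][:-1], dims[::-1][1:]):  # decoder
            n += a * b + b
            if self.batch_norm and b != self.input_dim:
                n += 2 * b
        return n


@dataclass(frozen=True)
class PredictorSpec:
    """Feedforward regressor: two hidden layers as wide as the input, linear output."""

    input_dim: int
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")

    @property
    def hidden(self) -> tuple[int, int]:
        return (self.input_dim, self.input_dim)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 1024
    max_epochs: int = 100
    patience: int = 10
    lambda_c: float = 1.0
    lambda_d: float = 1.0
    monitor: str = "total"  # early-stop on val "total" (unified) or "prediction" (MSE) loss
    seed: int = 0

    def __post_init__(self) -> None:
        if self.monitor not in ("prediction", "total"):
            raise ValueError("monitor must be 'prediction' or 'total'")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch statistics)")
        if self.lambda_c < 0 or self.lambda_d < 0:
            raise ValueError("loss weights must be >= 0")


def _check_binary(x: np.ndarray, name: str) -> None:
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError(f"{name} must be binary (0/1)")


@dataclass
class Batch:
    """Aligned arrays for a set of cell-drug pairs."""

    a: np.ndarray      # (n, n_pathways) activity vectors
    r_c: np.ndarray    # (n, n_driver_genes) binary mutation vectors
    r_d: np.ndarray    # (n, n_bits) binary fingerprints
    s: np.ndarray      # (n,) observed LN IC50

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.r_c = np.asarray(self.r_c, dtype=np.float64)
        self.r_d = np.asarray(self.r_d, dtype=np.float64)
        self.s = np.asarray(self.s, dtype=np.float64).ravel()
        n = {len(self.a), len(self.r_c), len(self.r_d), len(self.s)}
        if len(n) != 1:
            raise ValueError("batch blocks have unequal lengths")
        _check_binary(self.r_c, "mutation features R_C")
        _check_binary(self.r_d, "fingerprint features R_D")

    def __len__(self) -> int:
        return len(self.s)

    def subset(self, idx: np.ndarray) -> "Batch":
        return Batch(self.a[idx], self.r_c[idx], self.r_d[idx], self.s[idx])


@dataclass
class FeatureSet:
    """Per-cell and per-drug feature tables keyed by identifier columns."""

    activities: pd.DataFrame    # pathway x cell
    mutations: pd.DataFrame     # driver gene x cell
    fingerprints: pd.DataFrame  # bit x drug

    def coverage(self, pairs: pd.DataFrame) -> pd.Series:
        cells = set(self.activities.columns) & set(self.mutations.columns)
        drugs = set(self.fingerprints.columns)
        return pairs["cell_id"].isin(cells) & pairs["drug_id"].isin(drugs)

    def batch(self, pairs: pd.DataFrame, signature: Sequence[str] | None = None) -> Batch:
        acts = self.activities if signature is None else self.activities.reindex(signature)
        if acts.isna().any().any():
            raise ValueError("activity matrix is missing signature pathways")
        a = acts[pairs["cell_id"]].to_numpy(dtype=np.float64).T
        r_c = self.mutations[pairs["cell_id"]].to_numpy(dtype=np.float64).T
        r_d = self.fingerprints[pairs["drug_id"]].to_numpy(dtype=np.float64).T
        if "ln_ic50" in pairs.columns:
            s = pairs["ln_ic50"].to_numpy(dtype=np.float64)
        else:  # prediction-only table
            s = np.zeros(len(pairs))
        return Batch(a, r_c, r_d, s)


class Autoencoder:
    """Encoder/decoder pair; the decoder's sigmoid is applied outside the
    Sequential so training can use the numerically exact BCE-with-logits
    gradient."""

    def __init__(self, spec: AutoencoderSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        dims = [spec.input_dim, spec.hidden1, spec.hidden2, spec.bottleneck]
        enc: list = []
        for a, b in zip(dims[:-1], dims[1:]):
            enc.append(Dense(a, b, rng))
            if spec.batch_norm:
                enc.append(BatchNorm(b))
            enc.append(ReLU())
        dec: list = []
        rdims = dims[::-1]
        for i, (a, b) in enumerate(zip(rdims[:-1], rdims[1:])):
            dec.append(Dense(a, b, rng))
            if b != spec.input_dim:
                if spec.batch_norm:
                    dec.append(BatchNorm(b))
                dec.append(ReLU())
        self.encoder = Sequential(enc)
        self.decoder = Sequential(dec)  # emits logits; sigmoid applied in decode()

    def encode(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.encoder.forward(x, training=training)

    def decode_logits(self, z: np.ndarray, training: bool = False) -> np.ndarray:
        return self.decoder.forward(z, training=training)

    def decode(self, z: np.ndarray, training: bool = False) -> np.ndarray:
        return expit(self.decode_logits(z, training=training))

    def reconstruct(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.decode(self.encode(x, training), training)

    def parameters(self):
        return self.encoder.parameters() + self.decoder.parameters()

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"encoder.{k}": v for k, v in self.encoder.state_arrays().items()}
        out.update({f"decoder.{k}": v for k, v in self.decoder.state_arrays().items()})
        return out

    def load_state(self, arrays: Mapping[str, np.ndarray]) -> None:
        self.encoder.load_state(
            {k[len("encoder."):]: v for k, v in arrays.items() if k.startswith("encoder.")}
        )
        self.decoder.load_state(
            {k[len("decoder."):]: v for k, v in arrays.items() if k.startswith("decoder.")}
        )


def build_autoencoder(spec: AutoencoderSpec, seed: int = 0) -> Autoencoder:
    """Seeded construction; identical seeds give identical initial weights."""
    return Autoencoder(spec, np.random.default_rng(np.random.SeedSequence(seed)))


class Predictor:
    """Two hidden layers (input-width, batchnorm + ReLU) and one linear output."""

    def __init__(self, spec: PredictorSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        d = spec.input_dim
        layers: list = []
        for _ in range(2):
            layers.append(Dense(d, d, rng))
            if spec.batch_norm:
                layers.append(BatchNorm(d))
            layers.append(ReLU())
        layers.append(Dense(d, 1, rng))
        self.net = Sequential(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(x, training=training)

    def gradient(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Inference-mode outputs and per-sample input gradients dF/dx."""
        out = self.net.forward(np.asarray(x, dtype=np.float64), training=False)
        grads = self.net.backward(np.ones_like(out))
        for p in self.net.parameters():  # gradient() must not pollute training
            p.grad[...] = 0.0
        return out.ravel(), grads

    def parameters(self):
        return self.net.parameters()


def bce(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy over all elements.

    Probabilities outside [0, 1] are an error; values are clipped away from
    exact 0/1 before the logarithm.
    """
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError("probability and target shapes differ")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("reconstruction probabilities outside (0, 1)")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class LossBreakdown:
    total: float
    mse: float
    bce_c: float
    bce_d: float


def unified_loss(
    s: np.ndarray,
    s_pred: np.ndarray,
    r_c: np.ndarray,
    rc_hat: np.ndarray,
    r_d: np.ndarray,
    rd_hat: np.ndarray,
    lambda_c: float = 1.0,
    lambda_d: float = 1.0,
) -> LossBreakdown:
    """MSE(S, S') + lambda_C * BCE(R_C, R_C') + lambda_D * BCE(R_D, R_D')."""
    s = np.asarray(s, dtype=np.float64).ravel()
    s_pred = np.asarray(s_pred, dtype=np.float64).ravel()
    if s.shape != s_pred.shape:
        raise ValueError("observed and predicted sensitivity shapes differ")
    mse = float(np.mean((s - s_pred) ** 2))
    b_c = bce(rc_hat, r_c)
    b_d = bce(rd_hat, r_d)
    return LossBreakdown(mse + lambda_c * b_c + lambda_d * b_d, mse, b_c, b_d)


class DrugResponseModel:
    """Full model state: the two autoencoders, the regressor, and the signature."""

    def __init__(
        self,
        mut_ae: Autoencoder,
        drug_ae: Autoencoder,
        predictor: Predictor,
        signature: Sequence[str],
    ) -> None:
        expected = len(signature) + mut_ae.spec.bottleneck + drug_ae.spec.bottleneck
        if predictor.spec.input_dim != expected:
            raise ValueError(
                f"predictor input_dim {predictor.spec.input_dim} != "
                f"signature + bottlenecks = {expected}"
            )
        self.mut_ae = mut_ae
        self.drug_ae = drug_ae
        self.predictor = predictor
        self.signature = list(signature)
        self.history: list[dict] = []

    @classmethod
    def build(
        cls,
        signature: Sequence[str],
        mut_spec: AutoencoderSpec,
        drug_spec: AutoencoderSpec,
        seed: int = 0,
        batch_norm: bool = True,
    ) -> "DrugResponseModel":
        s_mut, s_drug, s_pred = np.random.SeedSequence(seed).spawn(3)
        mut_ae = Autoencoder(mut_spec, np.random.default_rng(s_mut))
        drug_ae = Autoencoder(drug_spec, np.random.default_rng(s_drug))
        d_in = len(signature) + mut_spec.bottleneck + drug_spec.bottleneck
        predictor = Predictor(
            PredictorSpec(d_in, batch_norm=batch_norm), np.random.default_rng(s_pred)
        )
        return cls(mut_ae, drug_ae, predictor, signature)

    # -- forward / inference ------------------------------------------------

    def _check_dims(self, a: np.ndarray, r_c: np.ndarray, r_d: np.ndarray) -> None:
        if a.shape[1] != len(self.signature):
            raise ValueError(
                f"activity block has {a.shape[1]} columns, expected {len(self.signature)}"
            )
        if r_c.shape[1] != self.mut_ae.spec.input_dim:
            raise ValueError(
                f"mutation block has {r_c.shape[1]} columns, expected "
                f"{self.mut_ae.spec.input_dim}"
            )
        if r_d.shape[1] != self.drug_ae.spec.input_dim:
            raise ValueError(
                f"fingerprint block has {r_d.shape[1]} columns, expected "
                f"{self.drug_ae.spec.input_dim}"
            )

    def forward(
        self, a: np.ndarray, r_c: np.ndarray, r_d: np.ndarray, training: bool = False
    ) -> dict[str, np.ndarray]:
        a = np.atleast_2d(np.asarray(a, dtype=np.float64))
        r_c = np.atleast_2d(np.asarray(r_c, dtype=np.float64))
        r_d = np.atleast_2d(np.asarray(r_d, dtype=np.float64))
        self._check_dims(a, r_c, r_d)
        z_c = self.mut_ae.encode(r_c, training)
        z_d = self.drug_ae.encode(r_d, training)
        logits_c = self.mut_ae.decode_logits(z_c, training)
        logits_d = self.drug_ae.decode_logits(z_d, training)
        h = np.concatenate([a, z_c, z_d], axis=1)
        s_pred = self.predictor.forward(h, training)
        return {
            "s_pred": s_pred.ravel(),
            "rc_hat": expit(logits_c),
            "rd_hat": expit(logits_d),
            "logits_c": logits_c,
            "logits_d": logits_d,
            "z_c": z_c,
            "z_d": z_d,
            "h": h,
        }

    def predict(
        self, a: np.ndarray, r_c: np.ndarray, r_d: np.ndarray, chunk: int = 8192
    ) -> np.ndarray:
        """Deterministic batched inference (order-preserving)."""
        n = len(a)
        out = np.empty(n)
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            out[sl] = self.forward(a[sl], r_c[sl], r_d[sl], training=False)["s_pred"]
        return out

    def embed_mutations(self, r_c: np.ndarray) -> np.ndarray:
        return self.mut_ae.encode(np.atleast_2d(np.asarray(r_c, dtype=np.float64)))

    def parameters(self):
        return (
            self.mut_ae.parameters()
            + self.drug_ae.parameters()
            + self.predictor.parameters()
        )

    # -- state management ---------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"mut_ae.{k}": v for k, v in self.mut_ae.state_arrays().items()}
        out.update({f"drug_ae.{k}": v for k, v in self.drug_ae.state_arrays().items()})
        out.update({f"predictor.{k}": v for k, v in self.predictor.net.state_arrays().items()})
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def set_state(self, state: Mapping[str, np.ndarray]) -> None:
        self.mut_ae.load_state(
            {k[len("mut_ae."):]: v for k, v in state.items() if k.startswith("mut_ae.")}
        )
        self.drug_ae.load_state(
            {k[len("drug_ae."):]: v for k, v in state.items() if k.startswith("drug_ae.")}
        )
        self.predictor.net.load_state(
            {k[len("predictor."):]: v for k, v in state.items() if k.startswith("predictor.")}
        )

    def save(self, path: str | Path) -> None:
        """Single-file .npz checkpoint: weights, running stats, specs, history."""
        meta = {
            "schema": 1,
            "signature": self.signature,
            "mut_spec": asdict(self.mut_ae.spec),
            "drug_spec": asdict(self.drug_ae.spec),
            "predictor_batch_norm": self.predictor.spec.batch_norm,
            "history": self.history,
        }
        arrays = {k.replace(".", "__"): v for k, v in self.state_arrays().items()}
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DrugResponseModel":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["__meta__"]).decode("utf-8"))
            arrays = {
                k.replace("__", "."): npz[k] for k in npz.files if k != "__meta__"
            }
        model = cls.build(
            meta["signature"],
            AutoencoderSpec(**meta["mut_spec"]),
            AutoencoderSpec(**meta["drug_spec"]),
            seed=0,
            batch_norm=meta["predictor_batch_norm"],
        )
        model.set_state(arrays)
        model.history = meta["history"]
        return model


# -- training ---------------------------------------------------------------


def _train_step(
    model: DrugResponseModel, batch: Batch, opt: Adam, lambda_c: float, lambda_d: float
) -> LossBreakdown:
    """One forward/backward/update pass; returns the batch loss breakdown."""
    n = len(batch)
    out = model.forward(batch.a, batch.r_c, batch.r_d, training=True)
    loss = unified_loss(
        batch.s, out["s_pred"], batch.r_c, out["rc_hat"], batch.r_d, out["rd_hat"],
        lambda_c, lambda_d,
    )
    opt.zero_grad()
    # MSE gradient into the regressor
    ds = (2.0 / n) * (out["s_pred"] - batch.s)[:, None]
    dh = model.predictor.net.backward(ds)
    n_a = len(model.signature)
    b_c = model.mut_ae.spec.bottleneck
    dz_c = dh[:, n_a : n_a + b_c]
    dz_d = dh[:, n_a + b_c :]
    # BCE-with-logits gradients through the decoders
    dlogits_c = lambda_c * (out["rc_hat"] - batch.r_c) / batch.r_c.size
    dlogits_d = lambda_d * (out["rd_hat"] - batch.r_d) / batch.r_d.size
    dz_c = dz_c + model.mut_ae.decoder.backward(dlogits_c)
    dz_d = dz_d + model.drug_ae.decoder.backward(dlogits_d)
    model.mut_ae.encoder.backward(dz_c)
    model.drug_ae.encoder.backward(dz_d)
    opt.step()
    return loss


def _eval_loss(
    model: DrugResponseModel, data: Batch, lambda_c: float, lambda_d: float,
    chunk: int = 8192,
) -> tuple[float, float]:
    """(unified loss, prediction MSE) on a dataset in inference mode."""
    total = 0.0
    mse = 0.0
    n = len(data)
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n))
        sub = data.subset(idx)
        out = model.forward(sub.a, sub.r_c, sub.r_d, training=False)
        loss = unified_loss(
            sub.s, out["s_pred"], sub.r_c, out["rc_hat"], sub.r_d, out["rd_hat"],
            lambda_c, lambda_d,
        )
        total += loss.total * len(sub)
        mse += loss.mse * len(sub)
    return total / n, mse / n


def train_end_to_end(
    model: DrugResponseModel, train: Batch, val: Batch, config: TrainConfig
) -> DrugResponseModel:
    """Mini-batch Adam training with early stopping on the validation loss.

    Stops when the monitored validation quantity (the unified loss by
    default, or the prediction MSE with ``config.monitor='prediction'``) has
    not improved for ``patience`` consecutive epochs (or at ``max_epochs``)
    and restores the parameters of the best epoch.  ``model.history`` records
    every epoch.
    """
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    best_val = np.inf
    best_state = model.get_state()
    best_epoch = 0
    bad_epochs = 0
    model.history = []
    n = len(train)
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_used = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            if len(idx) < 2:
                continue  # batch statistics need >= 2 samples
            loss = _train_step(
                model, train.subset(idx), opt, config.lambda_c, config.lambda_d
            )
            if not np.isfinite(loss.total):
                raise ValueError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            epoch_loss += loss.total * len(idx)
            n_used += len(idx)
        val_loss, val_mse = _eval_loss(model, val, config.lambda_c, config.lambda_d)
        model.history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_used, 1),
                "val_loss": val_loss,
                "val_mse": val_mse,
            }
        )
        monitored = val_mse if config.monitor == "prediction" else val_loss
        if monitored < best_val:
            best_val = monitored
            best_state = model.get_state()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    model.set_state(best_state)
    for rec in model.history:
        rec["best"] = rec["epoch"] == best_epoch
    return model


def _train_autoencoder(
    ae: Autoencoder,
    train: np.ndarray,
    epochs: int,
    lr: float,
    batch_size: int,
    rng: np.random.Generator,
) -> None:
    opt = Adam(ae.parameters(), lr=lr)
    n = len(train)
    for _ in range(epochs):
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            if len(idx) < 2:
                continue
            x = train[idx]
            z = ae.encode(x, training=True)
            logits = ae.decode_logits(z, training=True)
            probs = expit(logits)
            opt.zero_grad()
            dlogits = (probs - x) / x.size
            ae.encoder.backward(ae.decoder.backward(dlogits))
            opt.step()


DEFAULT_AE_GRID: dict[str, tuple[int, ...]] = {
    "hidden1": (300, 200, 100),
    "hidden2": (100, 50, 30),
    "bottleneck": (30, 20, 10),
}


def pretrain_autoencoder(
    features: np.ndarray | pd.DataFrame,
    grid: Mapping[str, Sequence[int]] = DEFAULT_AE_GRID,
    epochs: int = 50,
    test_fraction: float = 0.2,
    lr: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
) -> tuple[AutoencoderSpec, pd.DataFrame]:
    """Grid search over encoder widths; select by held-out reconstruction BCE.

    Each (hidden1, hidden2, bottleneck) combination is trained for ``epochs``
    epochs on a train split and scored by BCE on the held-out split; the spec
    with the lowest held-out BCE wins, ties broken by fewer parameters.
    Returns the winning spec and a results table.
    """
    x = np.asarray(
        features.to_numpy() if isinstance(features, pd.DataFrame) else features,
        dtype=np.float64,
    )
    _check_binary(x, "autoencoder features")
    combos = [
        (h1, h2, b)
        for h1, h2, b in product(grid["hidden1"], grid["hidden2"], grid["bottleneck"])
        if x.shape[1] > h1 >= h2 >= b >= 1
    ]
    if not combos:
        raise ValueError("no valid width combination for this input dimension")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(x))
    n_test = max(1, int(round(test_fraction * len(x))))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    if len(train_idx) == 0:
        raise ValueError("not enough samples to split for pretraining")

    rows = []
    for h1, h2, b in combos:
        spec = AutoencoderSpec(x.shape[1], h1, h2, b)
        ae = Autoencoder(spec, np.random.default_rng(np.random.SeedSequence([seed, h1, h2, b])))
        _train_autoencoder(
            ae, x[train_idx], epochs, lr, batch_size,
            np.random.default_rng(np.random.SeedSequence([seed, h1, h2, b, 1])),
        )
        test_bce = bce(ae.reconstruct(x[test_idx]), x[test_idx])
        rows.append(
            {"hidden1": h1, "hidden2": h2, "bottleneck": b,
             "test_bce": test_bce, "n_parameters": spec.n_parameters}
        )
    results = pd.DataFrame(rows).sort_values(
        ["test_bce", "n_parameters", "hidden1", "hidden2", "bottleneck"]
    ).reset_index(drop=True)
    best = results.iloc[0]
    best_spec = AutoencoderSpec(
        x.shape[1], int(best["hidden1"]), int(best["hidden2"]), int(best["bottleneck"])
    )
    return best_spec, results


def grid_search(
    train: Batch,
    val: Batch,
    test: Batch,
    make_model: Callable[[int], DrugResponseModel],
    lrs: Sequence[float] = (1e-2, 1e-3, 1e-4),
    batch_sizes: Sequence[int] = (256, 512, 1024),
    epochs: int = 50,
    seed: int = 0,
) -> tuple[TrainConfig, pd.DataFrame]:
    """Hyperparameter grid over learning rate and batch size.

    Each combination trains for ``epochs`` epochs (no early stop) and is scored
    on the test partition; ranking is ascending RMSE with descending-PCC
    tie-break.  Raises if every run diverges.
    """
    rows = []
    for lr in lrs:
        for bs in batch_sizes:
            config = TrainConfig(
                learning_rate=lr, batch_size=bs, max_epochs=epochs,
                patience=epochs, seed=seed,
            )
            model = make_model(seed)
            try:
                train_end_to_end(model, train, val, config)
                pred = model.predict(test.a, test.r_c, test.r_d)
                rmse = float(np.sqrt(np.mean((pred - test.s) ** 2)))
                pcc = float(np.corrcoef(pred, test.s)[0, 1])
            except ValueError:
                rmse, pcc = np.inf, np.nan
            rows.append({"learning_rate": lr, "batch_size": bs, "rmse": rmse, "pcc": pcc})
    results = pd.DataFrame(rows)
    ok = results[np.isfinite(results["rmse"])]
    if ok.empty:
        raise ValueError("all grid-search runs diverged")
    ranked = ok.sort_values(["rmse", "pcc"], ascending=[True, False], kind="stable")
    best = ranked.iloc[0]
    return (
        TrainConfig(
            learning_rate=float(best["learning_rate"]),
            batch_size=int(best["batch_size"]),
            seed=seed,
        ),
        results,
    )


def predict_pairs(
    model: DrugResponseModel, features: FeatureSet, pairs: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Batch inference over a pair table, in input order.

    Pairs whose cell or drug lacks features are returned in a rejects table
    (with a reason column) rather than silently dropped.  Raises if no pair is
    predictable.
    """
    ok = features.coverage(pairs)
    rejects = pairs.loc[~ok].copy()
    if not rejects.empty:
        cells = set(features.activities.columns) & set(features.mutations.columns)
        rejects["reason"] = np.where(
            ~rejects["cell_id"].isin(cells), "missing cell features", "missing drug features"
        )
    usable = pairs.loc[ok]
    if usable.empty:
        raise ValueError("no pair has complete features")
    batch = features.batch(usable, signature=model.signature)
    preds = usable.copy()
    preds["s_pred"] = model.predict(batch.a, batch.r_c, batch.r_d)
    return preds, rejects
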