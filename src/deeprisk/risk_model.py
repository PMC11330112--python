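"""The deep polygenic risk model and its training loop.

Architecture: a sparse partial-connection layer aggregates each gene's encoded
SNPs into a single scalar gene feature (a masked linear map whose nonzero
pattern is the SNP-to-gene connectivity), a bidirectional LSTM per chromosome
(4 hidden units per direction) reads the genes in genomic order, and a sigmoid
head maps the concatenation of every chromosome's hidden states (plus
standardized covariates) to a risk score in (0, 1).

Training minimizes class-weighted binary cross-entropy with weights
w0 = n / (2 (n - n_pos)) and w1 = n / (2 n_pos), plus an L2 penalty on the
BiLSTM weight matrices, with dropout on the BiLSTM outputs, Adam updates and
early stopping on an internal stratified validation split.  Everything is
deterministic under the configured seed.

Model variants:
  full              two-dim ref/alt encoding + partial layer (the default)
  additive_encoding additive alt-count encoding (input dim 1) + partial layer
  no_partial_layer  two-dim encoding fed directly to the BiLSTMs, one SNP per step
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._network import Adam, DeepRiskNetwork
from .feature_encoding import ConnectivityMap, EncodedGenotypes
from .snp_selection import stratified_split

EPS = 1e-7

VARIANTS = ("full", "no_partial_layer", "additive_encoding")


@dataclass
class ModelConfig:
    lstm_hidden_per_direction: int = 4
    dropout_rate: float = 0.2
    l2_coefficient: float = 1e-4
    learning_rate: float = 1e-3
    max_epochs: int = 50
    batch_size: int = 128
    early_stop_patience: int = 5
    seed: int = 0
    variant: str = "full"
    covariate_dim: int = 0
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0,1)")
        if self.l2_coefficient < 0:
            raise ValueError("l2_coefficient must be >= 0")
        if self.lstm_hidden_per_direction != 4:
            raise ValueError("the architecture fixes 4 hidden units per direction")
        if self.covariate_dim < 0:
            raise ValueError("covariate_dim must be >= 0")

    @property
    def encoding_mode(self) -> str:
        return "additive" if self.variant == "additive_encoding" else "two_dim"


@dataclass
class TrainReport:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    chosen_epoch: int = -1
    class_weights: tuple[float, float] = (1.0, 1.0)
    seed: int = 0


@dataclass
class RiskModel:
    connectivity: ConnectivityMap
    config: ModelConfig
    network: DeepRiskNetwork
    cov_mean: np.ndarray | None = None
    cov_std: np.ndarray | None = None
    report: TrainReport | None = None


def class_weights(n_samples: int, n_positive: int) -> tuple[float, float]:
    """Balanced class weights (w0 for controls, w1 for cases)."""
    if n_positive <= 0 or n_positive >= n_samples:
        raise ValueError(
            f"degenerate cohort: {n_positive} positives of {n_samples} samples"
        )
    w0 = n_samples / (2.0 * (n_samples - n_positive))
    w1 = n_samples / (2.0 * n_positive)
    return w0, w1


def weighted_bce(
    p: np.ndarray, y: np.ndarray, w0: float = 1.0, w1: float = 1.0
) -> float:
    """Mean class-weighted binary cross-entropy; probabilities clamped at 1e-7."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: p {p.shape} vs y {y.shape}")
    pc = np.clip(p, EPS, 1.0 - EPS)
    return float(np.mean(-w1 * y * np.log(pc) - w0 * (1.0 - y) * np.log(1.0 - pc)))


def build_model(conn: ConnectivityMap, cfg: ModelConfig) -> RiskModel:
    """Instantiate an untrained model for a connectivity map."""
    if conn.n_snps == 0:
        raise ValueError("empty connectivity map")
    input_dim = 1 if cfg.variant == "additive_encoding" else 2
    use_partial = cfg.variant != "no_partial_layer"
    net = DeepRiskNetwork(conn, input_dim, use_partial, cfg.covariate_dim, cfg.seed)
    return RiskModel(connectivity=conn, config=cfg, network=net)


def _check_input(model: RiskModel, X: EncodedGenotypes) -> np.ndarray:
    if X.mode != model.config.encoding_mode:
        raise ValueError(
            f"encoding mode {X.mode!r} does not match model variant "
            f"{model.config.variant!r} (expects {model.config.encoding_mode!r})"
        )
    if X.snp_ids != model.connectivity.snp_ids:
        raise ValueError("SNP order of the encoded input does not match the model")
    return np.asarray(X.tensor, dtype=float)


def _prep_covariates(model: RiskModel, covariates: np.ndarray | None, n: int) -> np.ndarray | None:
    cfg = model.config
    if cfg.covariate_dim == 0:
        if covariates is not None and np.size(covariates):
            raise ValueError("model was built without covariates")
        return None
    if covariates is None:
        raise ValueError(f"model expects {cfg.covariate_dim} covariates")
    cov = np.asarray(covariates, dtype=float)
    if cov.shape != (n, cfg.covariate_dim):
        raise ValueError(f"covariates shape {cov.shape} != ({n},{cfg.covariate_dim})")
    if model.cov_mean is None:
        raise ValueError("model not trained; covariate scaling unknown")
    return (cov - model.cov_mean) / model.cov_std


def train(
    model: RiskModel,
    X: EncodedGenotypes,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    cfg: ModelConfig | None = None,
) -> tuple[RiskModel, TrainReport]:
    """Fit in place; returns the model and its training report."""
    cfg = cfg or model.config
    Xt = _check_input(model, X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if Xt.shape[0] != n:
        raise ValueError("X / y length mismatch")
    n_pos = int(y.sum())
    w0, w1 = class_weights(n, n_pos)

    if cfg.covariate_dim:
        cov = np.asarray(covariates, dtype=float)
        model.cov_mean = cov.mean(axis=0)
        model.cov_std = np.where(cov.std(axis=0) == 0, 1.0, cov.std(axis=0))
        cov = (cov - model.cov_mean) / model.cov_std
    else:
        cov = None

    rng = np.random.default_rng(cfg.seed)
    tr_idx, va_idx = stratified_split(y, cfg.val_fraction, cfg.seed)
    Xtr, ytr = Xt[tr_idx], y[tr_idx]
    Xva, yva = Xt[va_idx], y[va_idx]
    ctr = cov[tr_idx] if cov is not None else None
    cva = cov[va_idx] if cov is not None else None

    net = model.network
    opt = Adam(net.params, cfg.learning_rate)
    report = TrainReport(class_weights=(w0, w1), seed=cfg.seed)
    best_val = np.inf
    best_params = net.copy_params()
    best_epoch = 0
    patience_left = cfg.early_stop_patience

    n_tr = len(ytr)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            cb = ctr[idx] if ctr is not None else None
            probs, _, cache = net.forward(xb, cb, cfg.dropout_rate, rng)
            loss = weighted_bce(probs, yb, w0, w1)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: loss={loss}, "
                    f"prob range [{probs.min()}, {probs.max()}]"
                )
            pc = np.clip(probs, EPS, 1.0 - EPS)
            dlogit = (w1 * yb * (pc - 1.0) + w0 * (1.0 - yb) * pc) / len(yb)
            grads = net.backward(cache, dlogit)
            net.l2_value_and_grads(cfg.l2_coefficient, grads)
            opt.step(net.params, grads)
            epoch_loss += loss
            n_batches += 1
        report.train_loss.append(epoch_loss / max(n_batches, 1))

        val_probs, _, _ = net.forward(Xva, cva)
        val_loss = weighted_bce(val_probs, yva, w0, w1)
        report.val_loss.append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_params = net.copy_params()
            best_epoch = epoch
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    net.set_params(best_params)
    report.chosen_epoch = best_epoch
    model.report = report
    return model, report


def predict_scores(
    model: RiskModel, X: EncodedGenotypes, covariates: np.ndarray | None = None
) -> np.ndarray:
    """Deterministic scores in (0,1); dropout disabled."""
    Xt = _check_input(model, X)
    cov = _prep_covariates(model, covariates, Xt.shape[0]) if model.config.covariate_dim else None
    probs, _, _ = model.network.forward(Xt, cov)
    return np.clip(probs, EPS, 1.0 - EPS)


def save_model(model: RiskModel, path: str) -> None:
    """Checkpoint parameters + config + a connectivity fingerprint (npz)."""
    import hashlib
    import json

    edge_blob = json.dumps(model.connectivity.edges()).encode()
    conn_hash = hashlib.sha256(edge_blob).hexdigest()
    meta = {
        "config": {k: getattr(model.config, k) for k in ModelConfig.__dataclass_fields__},
        "connectivity_hash": conn_hash,
        "snp_ids": model.connectivity.snp_ids,
    }
    arrays = {f"param_{k}": v for k, v in model.network.params.items()}
    if model.cov_mean is not None:
        arrays["cov_mean"] = model.cov_mean
        arrays["cov_std"] = model.cov_std
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str, conn: ConnectivityMap) -> RiskModel:
    """Load a checkpoint; refuses to score with a mismatched connectivity map."""
    import hashlib
    import json

    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    edge_blob = json.dumps(conn.edges()).encode()
    if hashlib.sha256(edge_blob).hexdigest() != meta["connectivity_hash"]:
        raise ValueError("connectivity map does not match the checkpoint")
    cfg = ModelConfig(**meta["config"])
    model = build_model(conn, cfg)
    for k in model.network.params:
        model.network.params[k] = data[f"param_{k}"]
    if "cov_mean" in data:
        model.cov_mean = data["cov_mean"]
        model.cov_std = data["cov_std"]
    return model
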