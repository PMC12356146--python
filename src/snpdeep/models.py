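"""The classifier zoo: declaratively configured architectures with a uniform
train/predict contract, plus autoencoder pre-training and a Bayesian
(GP-based) hyperparameter search.

Every architecture consumes a numeric samples-by-features matrix (the mean
encodings of the selected SNPs) and emits a per-sample Case probability.
Conventions shared by the whole zoo:

* binary cross-entropy loss, Adam with step size = ``learning_rate``,
  mini-batches of ``batch_size`` shuffled per epoch, dropout at
  ``dropout_rate`` in every architecture;
* recurrent architectures read the feature vector as a length-n_features
  sequence of scalars, in SNP order as listed (SNPs have no true sequence;
  this is a documented convention);
* convolutional architectures apply 1-D convolutions over the feature axis;
* (data, spec, seed) fully determine the trained parameters and hence the
  predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data import EncodedMatrix
from .errors import TrainingError, ValidationError
from .nn import Adam, Conv1D, Dense, Dropout, GRUCell, LSTMCell, Module, Tensor, bce_with_logits, concat

ARCHITECTURES = (
    "fnn",
    "ae_baseline",
    "ae_bayes",
    "ae_sparse",
    "bilstm",
    "gru",
    "cnn",
    "resnet",
    "stacked_ae_fnn",
    "stacked_ae_bilstm",
)

_DENSE = {"fnn", "stacked_ae_fnn"}
_AE_HEADS = {"ae_baseline", "ae_bayes", "ae_sparse"}
_RECURRENT = {"bilstm", "gru", "stacked_ae_bilstm"}
_CONV = {"cnn", "resnet"}

#: L1 activity-penalty weight on bottleneck activations of the sparse AE.
SPARSE_ACTIVITY_WEIGHT = 1e-4


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one classifier.

    Family-specific fields: ``neurons_1``/``neurons_2`` for fully connected
    architectures, ``units`` for recurrent ones, ``filter_size`` (kernel
    width) for convolutional ones, ``bottleneck`` for anything with an
    autoencoder stage (None means ceil(n_features / 4), the baseline AE's
    structure-adapting rule).
    """

    architecture: str = "fnn"
    epochs: int = 100
    dropout_rate: float = 0.3
    batch_size: int = 32
    learning_rate: float = 1e-3
    neurons_1: int = 64
    neurons_2: int = 32
    units: int = 32
    filter_size: int = 3
    bottleneck: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValidationError(
                f"unknown architecture {self.architecture!r}; choose from {sorted(ARCHITECTURES)}"
            )
        for name in ("epochs", "batch_size", "neurons_1", "neurons_2", "units", "filter_size"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.bottleneck is not None and self.bottleneck < 1:
            raise ValidationError("bottleneck must be a positive integer or None")
        if self.architecture in _CONV and self.filter_size % 2 == 0:
            raise ValidationError("filter_size must be odd (same-padding convolutions)")

    @property
    def family(self) -> str:
        if self.architecture in _RECURRENT:
            return "recurrent"
        if self.architecture in _CONV:
            return "convolutional"
        return "dense"


def default_bottleneck(n_features: int, spec: ModelSpec) -> int:
    if spec.bottleneck is not None:
        return min(spec.bottleneck, max(1, n_features - 1))
    return max(1, math.ceil(n_features / 4))


# ---------------------------------------------------------------------------
# network definitions
# ---------------------------------------------------------------------------


class _FNN(Module):
    def __init__(self, n_in: int, spec: ModelSpec, rng: np.random.Generator):
        self.l1 = Dense(n_in, spec.neurons_1, rng)
        self.l2 = Dense(spec.neurons_1, spec.neurons_2, rng)
        self.out = Dense(spec.neurons_2, 1, rng)
        self.drop = Dropout(spec.dropout_rate)

    def __call__(self, x: Tensor, rng, train: bool) -> Tensor:
        h = self.drop(self.l1(x).relu(), rng, train)
        h = self.drop(self.l2(h).relu(), rng, train)
        return self.out(h)


class _Logistic(Module):
    def __init__(self, n_in: int, spec: ModelSpec, rng: np.random.Generator):
        self.out = Dense(n_in, 1, rng)
        self.drop = Dropout(spec.dropout_rate)

    def __call__(self, x: Tensor, rng, train: bool) -> Tensor:
        return self.out(self.drop(x, rng, train))


class _Recurrent(Module):
    """GRU or (Bi-)LSTM over the feature axis; input dim 1 per timestep."""

    def __init__(self, n_in: int, spec: ModelSpec, rng: np.random.Generator, kind: str):
        self.kind = kind
        if kind == "gru":
            self.cell = GRUCell(1, spec.units, rng)
            head_in = spec.units
        else:  # bilstm
            self.fwd = LSTMCell(1, spec.units, rng)
            self.bwd = LSTMCell(1, spec.units, rng)
            head_in = 2 * spec.units
        self.out = Dense(head_in, 1, rng)
        self.drop = Dropout(spec.dropout_rate)
        self.units = spec.units

    def _run_lstm(self, cell: LSTMCell, x: Tensor, order) -> Tensor:
        n = x.shape[0]
        h = Tensor(np.zeros((n, cell.units)))
        c = Tensor(np.zeros((n, cell.units)))
        for t in order:
            h, c = cell.step(x[:, t : t + 1], h, c)
        return h

    def __call__(self, x: Tensor, rng, train: bool) -> Tensor:
        L = x.shape[1]
        if self.kind == "gru":
            n = x.shape[0]
            h = Tensor(np.zeros((n, self.units)))
            for t in range(L):
                h = self.cell.step(x[:, t : t + 1], h)
            final = h
        else:
            final = concat([self._run_lstm(self.fwd, x, range(L)),
                            self._run_lstm(self.bwd, x, range(L - 1, -1, -1))], axis=1)
        return self.out(self.drop(final, rng, train))


class _CNN(Module):
    """One convolutional feature extractor + global average pooling head."""

    CHANNELS = 16

    def __init__(self, n_in: int, spec: ModelSpec, rng: np.random.Generator):
        self.conv = Conv1D(1, self.CHANNELS, min(spec.filter_size, n_in), rng)
        self.out = Dense(self.CHANNELS, 1, rng)
        self.drop = Dropout(spec.dropout_rate)

    def __call__(self, x: Tensor, rng, train: bool) -> Tensor:
        h = x.reshape(x.shape[0], 1, x.shape[1])
        h = self.conv(h).relu()
        h = h.mean(axis=2)  # global average pool over feature axis
        return self.out(self.drop(h, rng, train))


class _ResNet(Module):
    """1-D convolutional blocks with identity skip connections."""

    CHANNELS = 16
    N_BLOCKS = 2

    def __init__(self, n_in: int, spec: ModelSpec, rng: np.random.Generator):
        k = min(spec.filter_size, n_in)
        if k % 2 == 0:
            k = max(1, k - 1)
        self.stem = Conv1D(1, self.CHANNELS, k, rng, same=True)
        self.blocks = [
            (Conv1D(self.CHANNELS, self.CHANNELS, k, rng, same=True),
             Conv1D(self.CHANNELS, self.CHANNELS, k, rng, same=True))
            for _ in range(self.N_BLOCKS)
        ]
        self.out = Dense(self.CHANNELS, 1, rng)
        self.drop = Dropout(spec.dropout_rate)

    def parameters(self):
        params = super().parameters()
        for c1, c2 in self.blocks:
            params.extend(c1.parameters())
            params.extend(c2.parameters())
        return params

    def __call__(self, x: Tensor, rng, train: bool) -> Tensor:
        h = x.reshape(x.shape[0], 1, x.shape[1])
        h = self.stem(h).relu()
        for c1, c2 in self.blocks:
            r = c2(c1(h).relu())
            h = (h + r).relu()  # identity skip
        h = h.mean(axis=2)
        return self.out(self.drop(h, rng, train))


# ---------------------------------------------------------------------------
# autoencoder pre-training
# ---------------------------------------------------------------------------


@dataclass
class EncoderTransform:
    """Frozen encoder produced by :func:`pretrain_autoencoder`."""

    W: np.ndarray
    b: np.ndarray
    loss_history: list[float]
    bottleneck: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.tanh(X @ self.W + self.b)


def pretrain_autoencoder(X, spec: ModelSpec, sparse: bool = False) -> EncoderTransform:
    """Train a single-hidden-layer autoencoder and return the frozen encoder.

    The encoder is tanh (saturating but free of dead units even at a
    bottleneck of one), the decoder linear, the loss mean squared
    reconstruction error; ``sparse=True`` adds an L1 activity penalty on the
    bottleneck activations.  Unless the spec pins a bottleneck width, it
    adapts to the data as ceil(n_features / 4).
    """
    Xd = _as_array(X)
    n, d = Xd.shape
    width = default_bottleneck(d, spec)
    rng = np.random.default_rng(spec.seed)
    enc = Dense(d, width, rng)
    dec = Dense(width, d, rng)
    opt = Adam(enc.parameters() + dec.parameters(), lr=spec.learning_rate)
    history: list[float] = []
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb = Tensor(Xd[idx])
            codes = enc(xb).tanh()
            recon = dec(codes)
            loss = (recon - xb).square().mean()
            if sparse:
                loss = loss + codes.abs().sum(axis=1).mean() * SPARSE_ACTIVITY_WEIGHT
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite autoencoder loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history.append(epoch_loss / n)
    return EncoderTransform(enc.W.data.copy(), enc.b.data.copy(), history, width)


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    spec: ModelSpec
    net: Module
    loss_history: list[float]
    n_features: int
    encoder: EncoderTransform | None = None  # present for AE-stacked variants


def _as_array(X) -> np.ndarray:
    if isinstance(X, EncodedMatrix):
        return X.X()
    return np.asarray(X, dtype=np.float64)


def _build_net(architecture: str, n_in: int, spec: ModelSpec, rng: np.random.Generator) -> Module:
    if architecture == "fnn":
        return _FNN(n_in, spec, rng)
    if architecture == "stacked_ae_fnn":
        return _FNN(n_in, spec, rng)
    if architecture in _AE_HEADS:
        return _Logistic(n_in, spec, rng)
    if architecture == "gru":
        return _Recurrent(n_in, spec, rng, "gru")
    if architecture in ("bilstm", "stacked_ae_bilstm"):
        return _Recurrent(n_in, spec, rng, "bilstm")
    if architecture == "cnn":
        return _CNN(n_in, spec, rng)
    if architecture == "resnet":
        return _ResNet(n_in, spec, rng)
    raise ValidationError(f"unknown architecture {architecture!r}")


def train_classifier(X, y=None, spec: ModelSpec | None = None) -> TrainedModel:
    """Train one zoo architecture on a numeric feature matrix.

    ``X`` may be an :class:`EncodedMatrix` (labels taken from it when ``y``
    is None) or a plain array.  Architectures with an autoencoder stage
    (``ae_*``, ``stacked_ae_*``) first pre-train the autoencoder on ``X``,
    freeze the encoder, and train their head on the bottleneck codes.
    """
    if spec is None:
        spec = ModelSpec()
    if y is None:
        if not isinstance(X, EncodedMatrix):
            raise ValidationError("y is required unless X is an EncodedMatrix")
        y = X.y()
    Xd = _as_array(X)
    yd = np.asarray(y, dtype=np.float64).ravel()
    if Xd.shape[0] != yd.shape[0]:
        raise ValidationError("X and y disagree on the number of samples")
    if not np.isfinite(Xd).all():
        raise ValidationError("X contains non-finite values")
    if set(np.unique(yd)) - {0.0, 1.0}:
        raise ValidationError("labels must be binary 0/1 (Control/Case)")

    encoder: EncoderTransform | None = None
    if spec.architecture in _AE_HEADS or spec.architecture.startswith("stacked_ae"):
        encoder = pretrain_autoencoder(Xd, spec, sparse=spec.architecture == "ae_sparse")
        features = encoder.transform(Xd)
    else:
        features = Xd

    rng = np.random.default_rng(spec.seed + 1)  # offset: AE pretraining used spec.seed
    net = _build_net(spec.architecture, features.shape[1], spec, rng)
    opt = Adam(net.parameters(), lr=spec.learning_rate)
    n = features.shape[0]
    history: list[float] = []
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            logits = net(Tensor(features[idx]), rng, train=True)
            loss = bce_with_logits(logits, yd[idx].reshape(-1, 1))
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch} ({spec.architecture})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history.append(epoch_loss / n)
    return TrainedModel(spec, net, history, n_features=Xd.shape[1], encoder=encoder)


def predict(model: TrainedModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample Case probability and the hard label at the 0.5 threshold.

    Probability exactly 0.5 is labeled Case (the ``>= 0.5`` rule).
    """
    Xd = _as_array(X)
    if Xd.shape[1] != model.n_features:
        raise ValidationError(
            f"feature count mismatch: model expects {model.n_features}, got {Xd.shape[1]}"
        )
    feats = model.encoder.transform(Xd) if model.encoder is not None else Xd
    logits = model.net(Tensor(feats), rng=None, train=False)
    prob = 1.0 / (1.0 + np.exp(-np.clip(logits.data.ravel(), -500, 500)))
    return prob, (prob >= 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# Bayesian hyperparameter search
# ---------------------------------------------------------------------------


@dataclass
class Trial:
    params: dict
    score: float


@dataclass
class SearchResult:
    best_spec: ModelSpec
    trials: list[Trial] = field(default_factory=list)

    @property
    def best_score(self) -> float:
        return max(t.score for t in self.trials)


#: Parameters treated as log-uniform when given as a (low, high) range.
_LOG_PARAMS = {"learning_rate"}
_INT_PARAMS = {"epochs", "batch_size", "neurons_1", "neurons_2", "units", "filter_size", "bottleneck"}


def bayesian_search(
    X,
    y,
    architecture: str,
    space: dict,
    budget: int,
    seed: int = 0,
    base_spec: ModelSpec | None = None,
    inner_folds: int = 3,
) -> SearchResult:
    """Sequential model-based hyperparameter optimization (GP + expected improvement).

    ``space`` maps ModelSpec field names to either a ``(low, high)`` range
    (log-uniform for learning_rate, rounded for integer fields) or a list of
    discrete choices.  The objective is mean ``inner_folds``-fold stratified
    CV accuracy on (X, y).  The first third of the budget (at least 3 trials,
    capped by the budget) is random exploration; subsequent trials maximize
    expected improvement under a Matern-5/2 Gaussian-process surrogate fitted
    to the normalized trial coordinates.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern
    from scipy.stats import norm

    if budget < 1:
        raise ValidationError("budget must be >= 1")
    if not space:
        raise ValidationError("empty search space")
    rng = np.random.default_rng(seed)
    names = sorted(space)
    base = base_spec or ModelSpec(architecture=architecture)

    def decode(u: np.ndarray) -> dict:
        params = {}
        for j, name in enumerate(names):
            dom = space[name]
            # a 2-tuple is a (low, high) range; a list is a set of choices
            if isinstance(dom, tuple) and len(dom) == 2:
                lo, hi = float(dom[0]), float(dom[1])
                if name in _LOG_PARAMS:
                    val = float(np.exp(np.log(lo) + u[j] * (np.log(hi) - np.log(lo))))
                else:
                    val = lo + u[j] * (hi - lo)
                params[name] = int(round(val)) if name in _INT_PARAMS else val
            else:
                choices = list(dom)
                params[name] = choices[min(int(u[j] * len(choices)), len(choices) - 1)]
        return params

    def objective(params: dict) -> float:
        from .evaluate import stratified_kfold

        spec = replace(base, architecture=architecture, **params)
        folds = stratified_kfold(np.asarray(y), k=inner_folds, seed=seed)
        accs = []
        Xd = _as_array(X)
        yd = np.asarray(y)
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(len(yd)), test_idx)
            model = train_classifier(Xd[train_idx], yd[train_idx], spec)
            _, pred = predict(model, Xd[test_idx])
            accs.append(float((pred == yd[test_idx]).mean()))
        return float(np.mean(accs))

    n_init = min(budget, max(3, budget // 3))
    us: list[np.ndarray] = []
    trials: list[Trial] = []
    for _ in range(n_init):
        u = rng.random(len(names))
        us.append(u)
        params = decode(u)
        trials.append(Trial(params, objective(params)))

    while len(trials) < budget:
        scores = np.array([t.score for t in trials])
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5, length_scale=0.3),
            alpha=1e-4,
            normalize_y=True,
            random_state=int(rng.integers(2**31)),
        )
        gp.fit(np.array(us), scores)
        cand = rng.random((256, len(names)))
        mu, sd = gp.predict(cand, return_std=True)
        best = scores.max()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best) / sd
            ei = np.where(sd > 0, (mu - best) * norm.cdf(z) + sd * norm.pdf(z), 0.0)
        u = cand[int(np.argmax(ei))]
        us.append(u)
        params = decode(u)
        trials.append(Trial(params, objective(params)))

    best_trial = max(trials, key=lambda t: t.score)
    best_spec = replace(base, architecture=architecture, **best_trial.params)
    return SearchResult(best_spec, trials)
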