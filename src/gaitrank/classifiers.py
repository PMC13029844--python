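"""Base-classifier harness: architecture templates, training, posteriors.

Five deep 1-D architectures (CNN, CNN-LSTM-FC, ResNet1D, ConvMixer1D,
InceptionTime) are provided as configurable templates whose hyperparameters
are bounded by per-architecture search spaces, plus ``nearest_centroid`` — a
deterministic reference classifier (mean training waveform per identity,
posteriors from normalised inverse distances) that exercises the ensemble
layer without long training runs.  The fusion stage is agnostic to which
backend produced a posterior matrix.

Every trained classifier records its stratified 80/20 trial-level split so
the ensemble's position-wise accuracies can later be computed on exactly
the 20% of training data the fit never optimised on.  Augmentation, when
used, is applied to training inputs only — never to validation or test
cycles.

Template defaults sit at the small end of each search space so that CPU
training stays practical; study-scale widths remain reachable through the
config.  Below-space configurations (e.g. a two-block CNN for smoke tests)
are accepted unless ``strict`` table validation is requested, which is what
the random-search driver uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nets
from .grf import GaitDataset

__all__ = [
    "ARCHITECTURES",
    "ClassifierConfig",
    "PosteriorMatrix",
    "FittedClassifier",
    "stratified_split",
    "train_classifier",
    "predict_posteriors",
    "random_search",
]

ARCHITECTURES = (
    "cnn",
    "cnn_lstm_fc",
    "resnet1d",
    "convmixer1d",
    "inception_time",
    "nearest_centroid",
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture template plus training hyperparameters.

    ``downsample`` decimates the time axis and ``channels`` restricts the
    input to a channel subset; both are preprocessing choices shared by all
    backends (and a cheap source of harness diversity for the deterministic
    backend).
    """

    architecture: str = "nearest_centroid"
    # training
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.2
    seed: int = 0
    # input preprocessing
    downsample: int = 1
    channels: tuple[int, ...] | None = None
    # cnn / cnn_lstm_fc convolutional front end
    conv_filters: tuple[int, ...] = (16, 32, 64, 128, 256)
    conv_kernels: tuple[int, ...] = (7, 5, 3, 3, 3)
    fc_units: tuple[int, ...] = (512, 256)
    dropout: float = 0.1
    # lstm head
    lstm_hidden: int = 64
    lstm_layers: int = 1
    lstm_bidirectional: bool = False
    # resnet1d
    resnet_filters: int = 16
    resnet_depth: int = 2
    resnet_kernel: int = 7
    # convmixer1d
    mixer_filters: int = 16
    mixer_depth: int = 4
    mixer_kernel: int = 9
    mixer_stem_kernel: int = 7
    # inception_time
    inception_blocks: int = 3
    inception_filters: int = 16
    inception_kernel: int = 7
    inception_bottleneck: int = 16

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 1e-5 <= self.learning_rate <= 1e-3:
            raise ValueError("learning rate must lie in [1e-5, 1e-3]")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")

    def validate_in_space(self) -> None:
        """Raise unless every hyperparameter lies inside the architecture's
        search space (see :data:`SEARCH_SPACES`)."""
        space = SEARCH_SPACES[self.architecture]
        for name, allowed in space.items():
            value = getattr(self, name)
            if isinstance(allowed, tuple) and len(allowed) == 2 and all(
                isinstance(v, float) for v in allowed
            ):
                lo, hi = allowed
                values = value if isinstance(value, tuple) else (value,)
                if not all(lo <= v <= hi for v in values):
                    raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
            else:
                values = value if isinstance(value, tuple) else (value,)
                for i, v in enumerate(values):
                    opts = allowed[i] if isinstance(allowed[0], (tuple, list)) else allowed
                    if v not in opts:
                        raise ValueError(f"{name}[{i}]={v} not in {opts}")


#: per-architecture hyperparameter search spaces: per-block filter counts and
#: kernel sizes, head widths, regularisation and training ranges.
SEARCH_SPACES: dict[str, dict] = {
    "cnn": {
        "conv_filters": [
            (16, 32, 64), (32, 64, 128), (64, 128, 256),
            (128, 256, 512), (256, 512, 1024), (256, 512),
        ],
        "conv_kernels": [(3, 5, 7), (3, 5), (3, 5), (3,), (3,), (3,)],
        "fc_units": [(512, 1024), (256, 512, 700)],
        "dropout": (0.1, 0.6),
        "batch_size": (16, 32, 64),
        "learning_rate": (1e-5, 1e-3),
    },
    "cnn_lstm_fc": {
        "conv_filters": [
            (16, 32, 64), (32, 64, 128), (64, 128, 256),
            (128, 256, 512), (256, 512, 1024), (256, 512),
        ],
        "conv_kernels": [(3, 5, 7), (3, 5), (3, 5), (3,), (3,), (3,)],
        "lstm_hidden": (64, 128, 192, 256, 320, 384, 448, 512),
        "lstm_layers": (1, 2),
        "lstm_bidirectional": (False, True),
        "fc_units": [(128, 256, 512, 1024)],
        "dropout": (0.1, 0.5),
        "batch_size": (16, 32, 64, 128),
        "learning_rate": (1e-5, 1e-3),
    },
    "resnet1d": {
        "resnet_filters": (16, 32, 64),
        "resnet_kernel": (7,),
        "resnet_depth": (2, 3, 4, 5, 6),
        "batch_size": (16, 32, 64),
        "learning_rate": (1e-5, 1e-3),
    },
    "convmixer1d": {
        "mixer_filters": (16, 32, 64, 128),
        "mixer_stem_kernel": (7,),
        "mixer_depth": (4, 5, 6, 7, 8),
        "mixer_kernel": (3, 5, 7, 9),
        "dropout": (0.0, 0.4),
        "batch_size": (16, 32, 64, 128),
        "learning_rate": (1e-5, 1e-3),
    },
    "inception_time": {
        "inception_blocks": (3, 4, 5, 6, 7, 8, 9),
        "inception_filters": (16, 32, 64, 96),
        "inception_kernel": (7, 9, 11),
        "inception_bottleneck": (16, 32),
        "dropout": (0.0, 0.5),
        "batch_size": (32, 64, 128),
        "learning_rate": (1e-5, 1e-3),
    },
    "nearest_centroid": {},
}


@dataclass
class PosteriorMatrix:
    """Row-stochastic class-probability matrix of one classifier."""

    classifier_id: str
    sample_ids: list
    class_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.class_ids)):
            raise ValueError("posterior matrix shape mismatch")
        if self.values.size:
            if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
                raise ValueError("posteriors outside [0, 1]")
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("posterior rows must sum to 1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]


# ------------------------------------------------------------------
# architecture builders
# ------------------------------------------------------------------

def _conv_blocks(cfg: ClassifierConfig, c_in, rng):
    layers = []
    c = c_in
    for f, k in zip(cfg.conv_filters, cfg.conv_kernels):
        layers += [
            nets.Conv1D(c, f, k, rng),
            nets.BatchNorm1D(f),
            nets.ReLU(),
            nets.MaxPool1D(2),
        ]
        c = f
    return layers, c


def _build_cnn(cfg, c_in, n_classes, rng):
    layers, c = _conv_blocks(cfg, c_in, rng)
    layers.append(nets.GlobalAvgPool1D())
    d = c
    for units in cfg.fc_units:
        layers += [nets.Dense(d, units, rng), nets.ReLU(), nets.Dropout(cfg.dropout, rng)]
        d = units
    layers.append(nets.Dense(d, n_classes, rng))
    return nets.Sequential(layers)


def _build_cnn_lstm_fc(cfg, c_in, n_classes, rng):
    layers, c = _conv_blocks(cfg, c_in, rng)
    layers.append(
        nets.LSTM(
            c,
            cfg.lstm_hidden,
            rng,
            num_layers=cfg.lstm_layers,
            bidirectional=cfg.lstm_bidirectional,
        )
    )
    d = cfg.lstm_hidden * (2 if cfg.lstm_bidirectional else 1)
    for units in cfg.fc_units[:1]:
        layers += [nets.Dense(d, units, rng), nets.ReLU(), nets.Dropout(cfg.dropout, rng)]
        d = units
    layers.append(nets.Dense(d, n_classes, rng))
    return nets.Sequential(layers)


def _build_resnet1d(cfg, c_in, n_classes, rng):
    f = cfg.resnet_filters
    layers = [nets.Conv1D(c_in, f, cfg.resnet_kernel, rng), nets.BatchNorm1D(f), nets.ReLU()]
    for _ in range(cfg.resnet_depth):
        main = nets.Sequential(
            [
                nets.Conv1D(f, f, 3, rng),
                nets.BatchNorm1D(f),
                nets.ReLU(),
                nets.Conv1D(f, f, 3, rng),
                nets.BatchNorm1D(f),
            ]
        )
        layers.append(nets.Residual(main, activation=nets.ReLU()))
    layers += [nets.GlobalAvgPool1D(), nets.Dense(f, n_classes, rng)]
    return nets.Sequential(layers)


def _build_convmixer1d(cfg, c_in, n_classes, rng):
    f = cfg.mixer_filters
    layers = [nets.Conv1D(c_in, f, cfg.mixer_stem_kernel, rng), nets.BatchNorm1D(f), nets.GELU()]
    for _ in range(cfg.mixer_depth):
        spatial = nets.Sequential(
            [nets.DepthwiseConv1D(f, cfg.mixer_kernel, rng), nets.GELU(), nets.BatchNorm1D(f)]
        )
        layers.append(nets.Residual(spatial))
        layers += [
            nets.Conv1D(f, f, 1, rng),
            nets.GELU(),
            nets.BatchNorm1D(f),
            nets.Dropout(cfg.dropout, rng),
        ]
    layers += [nets.GlobalAvgPool1D(), nets.Dense(f, n_classes, rng)]
    return nets.Sequential(layers)


def _odd(k: int) -> int:
    return max(3, k if k % 2 else k - 1)


def _build_inception_time(cfg, c_in, n_classes, rng):
    f, k = cfg.inception_filters, cfg.inception_kernel
    kernels = (_odd(k), _odd(k // 2), 3)
    layers = []
    c = c_in
    for _ in range(cfg.inception_blocks):
        bottleneck = nets.Conv1D(c, cfg.inception_bottleneck, 1, rng)
        branches = [
            nets.Sequential([bottleneck if i == 0 else _Share(bottleneck),
                             nets.Conv1D(cfg.inception_bottleneck, f, ks, rng)])
            for i, ks in enumerate(kernels)
        ]
        branches.append(nets.Sequential([nets.Conv1D(c, f, 1, rng)]))
        main = nets.Sequential([nets.Concat(branches), nets.BatchNorm1D(4 * f)])
        shortcut = nets.Sequential([nets.Conv1D(c, 4 * f, 1, rng)])
        layers.append(nets.Residual(main, shortcut=shortcut, activation=nets.ReLU()))
        layers.append(nets.Dropout(cfg.dropout, rng))
        c = 4 * f
    layers += [nets.GlobalAvgPool1D(), nets.Dense(c, n_classes, rng)]
    return nets.Sequential(layers)


class _Share(nets.Layer):
    """Reuse a layer's forward pass without double-counting its parameters.

    The inception bottleneck feeds several branches; only the first branch
    owns the parameters, the others recompute forward/backward through this
    proxy (gradients accumulate into the owner's arrays).
    """

    def __init__(self, owner: nets.Conv1D):
        super().__init__()
        self.owner = owner

    def forward(self, x, training=False):
        self._cols = nets._im2col(x, self.owner.kernel)
        self._shape = x.shape
        return (self._cols @ self.owner.w.T + self.owner.b).transpose(0, 2, 1)

    def backward(self, grad):
        g = grad.transpose(0, 2, 1)
        flat_g = g.reshape(-1, g.shape[-1])
        self.owner.grads[0] += flat_g.T @ self._cols.reshape(-1, self._cols.shape[-1])
        self.owner.grads[1] += flat_g.sum(axis=0)
        b, c, l = self._shape
        return nets._col2im(g @ self.owner.w, b, c, l, self.owner.kernel)


_BUILDERS = {
    "cnn": _build_cnn,
    "cnn_lstm_fc": _build_cnn_lstm_fc,
    "resnet1d": _build_resnet1d,
    "convmixer1d": _build_convmixer1d,
    "inception_time": _build_inception_time,
}


# ------------------------------------------------------------------
# fitting
# ------------------------------------------------------------------

class _CentroidBackend:
    """Mean training waveform per identity; posteriors are normalised
    inverse Euclidean distances.  Fully deterministic."""

    eps = 1e-9

    def fit(self, x: np.ndarray, y: np.ndarray, n_classes: int) -> "_CentroidBackend":
        d = x.reshape(x.shape[0], -1)
        self.centroids = np.zeros((n_classes, d.shape[1]))
        for c in range(n_classes):
            mask = y == c
            if not mask.any():
                raise ValueError(f"class {c} missing from training data")
            self.centroids[c] = d[mask].mean(axis=0)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if x.shape[0] == 0:
            return np.zeros((0, self.centroids.shape[0]))
        d = x.reshape(x.shape[0], -1)
        dist = np.sqrt(
            np.maximum(
                (d**2).sum(1)[:, None]
                - 2 * d @ self.centroids.T
                + (self.centroids**2).sum(1)[None, :],
                0.0,
            )
        )
        inv = 1.0 / (dist + self.eps)
        return inv / inv.sum(axis=1, keepdims=True)


@dataclass
class FittedClassifier:
    classifier_id: str
    config: ClassifierConfig
    backend: object
    class_ids: list
    input_length: int
    train_indices: np.ndarray
    val_indices: np.ndarray
    history: dict = field(default_factory=dict)

    def preprocess(self, x: np.ndarray) -> np.ndarray:
        if self.config.channels is not None:
            x = x[:, list(self.config.channels), :]
        if self.config.downsample > 1:
            x = x[:, :, :: self.config.downsample]
        return x


def stratified_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-level split keeping every class in the training part.

    Within each class the trials are shuffled and ``val_fraction`` of them
    (at least one, when the class has two or more) go to validation.
    """
    train_idx, val_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * idx.size)) if idx.size >= 2 else 0
        n_val = min(max(n_val, 1 if idx.size >= 2 else 0), idx.size - 1)
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx, dtype=np.intp)), np.sort(
        np.array(val_idx, dtype=np.intp)
    )


def train_classifier(
    config: ClassifierConfig,
    train: GaitDataset,
    classifier_id: str | None = None,
    fit_dataset: GaitDataset | None = None,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> FittedClassifier:
    """Fit one base classifier on a gait dataset.

    ``train`` provides the stratified 80/20 trial-level split; the fit uses
    the 80% part and early-stops on the 20% part, whose indices are kept on
    the result for the ensemble's accuracy table.  An ensemble harness can
    impose a shared ``split`` so that every member is validated on the same
    cycles.  When ``fit_dataset`` is given (Scenario C), the model is
    fitted on *it* instead of the 80% part — the caller is responsible for
    augmenting only training cycles — while validation still uses the
    untouched 20% split of ``train``.
    """
    class_ids = train.class_ids()
    if len(class_ids) < 2:
        raise ValueError("training requires at least two identity classes")
    labels = train.labels()
    if split is not None:
        train_idx, val_idx = (np.asarray(s, dtype=np.intp) for s in split)
    else:
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 17)))
        train_idx, val_idx = stratified_split(labels, config.val_fraction, rng)
    missing = set(range(len(class_ids))) - set(labels[train_idx])
    if missing:
        raise ValueError(f"classes {sorted(missing)} missing from the 80% split")

    fitted = FittedClassifier(
        classifier_id=classifier_id or config.architecture,
        config=config,
        backend=None,
        class_ids=class_ids,
        input_length=train.unified_length,
        train_indices=train_idx,
        val_indices=val_idx,
    )

    signals = train.signals()
    x_val = fitted.preprocess(signals[val_idx])
    y_val = labels[val_idx]
    if fit_dataset is not None:
        if fit_dataset.class_ids() != class_ids:
            raise ValueError("fit_dataset must share the training roster")
        x_fit = fitted.preprocess(fit_dataset.signals())
        y_fit = fit_dataset.labels()
    else:
        x_fit = fitted.preprocess(signals[train_idx])
        y_fit = labels[train_idx]

    if config.architecture == "nearest_centroid":
        fitted.backend = _CentroidBackend().fit(x_fit, y_fit, len(class_ids))
    else:
        net_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 23)))
        net = _BUILDERS[config.architecture](
            config, x_fit.shape[1], len(class_ids), net_rng
        )
        model = nets.NetworkClassifier(net, net_rng)
        model.fit(
            x_fit,
            y_fit,
            x_val,
            y_val,
            epochs=config.max_epochs,
            batch_size=config.batch_size,
            lr=config.learning_rate,
            patience=config.patience,
        )
        fitted.backend = model
        fitted.history = model.history
    return fitted


def predict_posteriors(fitted: FittedClassifier, data) -> PosteriorMatrix:
    """Class posteriors for a dataset or a stacked ``(M, 6, N)`` array."""
    if isinstance(data, GaitDataset):
        if len(data) and data.unified_length != fitted.input_length:
            raise ValueError(
                f"cycle length {data.unified_length} != trained length "
                f"{fitted.input_length}"
            )
        x = data.signals()
        sample_ids = [c.key for c in data.cycles]
    else:
        x = np.asarray(data)
        if x.size and x.shape[2] != fitted.input_length:
            raise ValueError("cycle length differs from the trained length")
        sample_ids = list(range(x.shape[0]))
    if x.shape[0] == 0:
        values = np.zeros((0, len(fitted.class_ids)))
    else:
        values = fitted.backend.predict_proba(fitted.preprocess(x))
    return PosteriorMatrix(
        classifier_id=fitted.classifier_id,
        sample_ids=sample_ids,
        class_ids=list(fitted.class_ids),
        values=values,
    )


# ------------------------------------------------------------------
# bounded random hyperparameter search
# ------------------------------------------------------------------

def _sample_config(architecture: str, rng: np.random.Generator, base: ClassifierConfig):
    space = SEARCH_SPACES[architecture]
    kwargs: dict = {"architecture": architecture}
    for name, allowed in space.items():
        if isinstance(allowed, list):  # per-block choice lists
            kwargs[name] = tuple(int(rng.choice(opts)) for opts in allowed)
        elif name == "learning_rate":
            lo, hi = allowed
            kwargs[name] = float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))
        elif isinstance(allowed, tuple) and len(allowed) == 2 and all(
            isinstance(v, float) for v in allowed
        ):
            kwargs[name] = float(rng.uniform(*allowed))
        else:
            value = allowed[int(rng.integers(len(allowed)))]
            kwargs[name] = bool(value) if isinstance(value, bool) else value
    if architecture == "cnn":
        # the sixth convolutional block is optional
        n_blocks = int(rng.integers(5, 7))
        kwargs["conv_filters"] = kwargs["conv_filters"][:n_blocks]
        kwargs["conv_kernels"] = kwargs["conv_kernels"][:n_blocks]
    return replace(base, **kwargs)


def random_search(
    architecture: str,
    train: GaitDataset,
    budget: int,
    seed: int = 0,
    base: ClassifierConfig | None = None,
    full_output: bool = False,
):
    """Best-of-``budget`` random search inside the architecture's space.

    Draws configurations sequentially from one seeded stream (so a larger
    budget extends, never replaces, a smaller one), trains each and scores
    validation Top-1.  Returns the best configuration (and the trial list
    when ``full_output``).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if architecture not in SEARCH_SPACES or not SEARCH_SPACES[architecture]:
        raise ValueError(f"no search space for {architecture!r}")
    base = base or ClassifierConfig(architecture=architecture)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 29)))
    trials = []
    labels = train.labels()
    for i in range(budget):
        cfg = replace(_sample_config(architecture, rng, base), seed=seed + i)
        cfg.validate_in_space()
        fitted = train_classifier(cfg, train)
        post = predict_posteriors(fitted, train.signals()[fitted.val_indices])
        top1 = float(
            np.mean(post.values.argmax(axis=1) == labels[fitted.val_indices])
        )
        trials.append((cfg, top1))
    best = max(trials, key=lambda t: t[1])[0]
    return (best, trials) if full_output else best
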