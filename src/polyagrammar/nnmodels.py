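"""PolyaID and PolyaStrength model definitions and training.

PolyaID couples polyA-site classification to nucleotide-resolution cleavage
profiling: a convolutional layer (window 8) reads local sequence composition,
a bidirectional LSTM integrates the 240-nt context, and two output branches
emit (i) the probability that the window centre is a cleavage/polyadenylation
site and (ii) a 50-long cleavage probability vector over offsets −25..+24.
PolyaStrength shares the trunk design but regresses the site strength — the
log2-odds of relative usage — through a single linear output.

Training uses Adam with Nesterov momentum (Nadam), batch size 100 and
learning rate 0.001; the classification (binary cross-entropy) and cleavage
(KL divergence) losses are equally weighted, and the weights from the epoch
with minimum validation loss are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field, replace

import numpy as np

from .nn.layers import BiLSTM, Conv1D, Dense, Dropout, Flatten, MaxPool1D, ReLU
from .nn.network import DualHeadNet, RegressionNet, Sequential
from .nn.optim import Nadam
from .nn.losses import binary_cross_entropy, kl_divergence, mean_squared_error

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 240
CLEAVAGE_LENGTH = 50


@dataclass
class ModelConfig:
    """Architecture and optimisation settings.

    Defaults correspond to the full-size models; tests and desk-scale runs
    use a reduced configuration (16 filters / 16 recurrent units).
    """

    conv_window: int = 8
    conv_filters: int = 64
    rnn_units: int = 32
    dense_units: int = 64
    dropout: float = 0.3
    pool_size: int = 3
    learning_rate: float = 0.001
    batch_size: int = 100
    max_epochs: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.conv_window < 1:
            raise ValueError("conv_window must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _build_trunk(config: ModelConfig, rng: np.random.Generator) -> tuple[Sequential, int]:
    conv_out = WINDOW_LENGTH - config.conv_window + 1
    pooled = conv_out // config.pool_size if config.pool_size > 1 else conv_out
    flat_dim = pooled * 2 * config.rnn_units
    trunk = Sequential([
        Conv1D(4, config.conv_filters, config.conv_window, rng),
        ReLU(),
        MaxPool1D(config.pool_size),
        BiLSTM(config.conv_filters, config.rnn_units, rng),
        Flatten(),
        Dense(flat_dim, config.dense_units, rng),
        ReLU(),
        Dropout(config.dropout, rng),
    ])
    return trunk, config.dense_units


def build_polyaid(config: ModelConfig) -> DualHeadNet:
    """Dual-head classifier + cleavage-vector model over 4x240 one-hot input."""
    rng = np.random.default_rng(config.seed)
    trunk, feat_dim = _build_trunk(config, rng)
    head_class = Dense(feat_dim, 1, rng)
    head_cleavage = Dense(feat_dim, CLEAVAGE_LENGTH, rng)
    return DualHeadNet(trunk, head_class, head_cleavage,
                       config={"kind": "polyaid", **asdict(config)})


def build_polyastrength(config: ModelConfig) -> RegressionNet:
    """Single-output regression model for the log2-odds usage score."""
    rng = np.random.default_rng(config.seed)
    trunk, feat_dim = _build_trunk(config, rng)
    head = Dense(feat_dim, 1, rng)
    return RegressionNet(trunk, head,
                         config={"kind": "polyastrength", **asdict(config)})


# re-exported loss functions with the operation names used throughout
def loss_classification(y, p) -> float:
    return binary_cross_entropy(y, p)


def loss_cleavage(observed, predicted) -> float:
    return kl_divergence(observed, predicted)


def loss_usage(u, v) -> float:
    return mean_squared_error(u, v)


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = -1


def train(model, datasets: dict, config: ModelConfig) -> TrainHistory:
    """Fit `model` on ``datasets`` and restore the best-validation weights.

    ``datasets`` maps split name to a tuple: for PolyaID
    ``(X, y, cleavage)`` with X of shape (N, 4, 240); for PolyaStrength
    ``(X, target)``.  Required keys: ``"train"`` and ``"val"``.
    """
    rng = np.random.default_rng(config.seed)
    x_train = datasets["train"][0]
    extras_train = datasets["train"][1:]
    val = datasets["val"]
    n = len(x_train)
    optimizer = Nadam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best_loss = np.inf
    best_params = model.get_parameters()
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = (x_train[idx], *(e[idx] for e in extras_train))
            loss = model.train_batch(*batch, optimizer)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}")
            losses.append(loss)
        val_loss = model.evaluate(*val)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(float(val_loss))
        if val_loss < best_loss:
            best_loss = val_loss
            best_epoch = epoch
            best_params = model.get_parameters()
            history.best_epoch = best_epoch
    model.set_parameters(best_params)
    return history


def train_with_restarts(build_fn, datasets: dict, config: ModelConfig,
                        max_restarts: int = 3,
                        min_val_spread: float = 0.05):
    """Train, reinitialising deterministically when optimisation stalls.

    Reduced-capacity models occasionally settle into a "predict the prior"
    saddle where the validation loss never moves from its initial value.
    The collapse is detected from the validation trace (spread below
    ``min_val_spread`` or no improvement over epoch 0); each restart rebuilds
    the model with the next seed (``config.seed + attempt``).  Returns
    (model, history) from the first successful attempt, or the last attempt
    if all stall.
    """
    model, history = None, None
    for attempt in range(max_restarts + 1):
        cfg = replace(config, seed=config.seed + attempt)
        model = build_fn(cfg)
        history = train(model, datasets, cfg)
        collapsed = (np.ptp(history.val_loss) <= min_val_spread
                     or min(history.val_loss) >= history.val_loss[0])
        if not collapsed:
            return model, history
        logger.warning("training stalled at the prior (seed %d); restarting",
                       cfg.seed)
    return model, history
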