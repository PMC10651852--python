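"""Training losses: binary cross-entropy, KL divergence, mean squared error.

The cleavage loss is the divergence of the predicted vector from the observed
one, KL(observed ‖ predicted) = Σ_j obs_j · log(obs_j / pred_j), summed over
the 50 cleavage positions and averaged over the batch.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7


def binary_cross_entropy(y_true: np.ndarray, p: np.ndarray) -> float:
    """Mean over the batch of −[y·log p + (1−y)·log(1−p)]; p clipped to (ε, 1−ε)."""
    y = np.asarray(y_true, dtype=np.float64).ravel()
    p = np.clip(np.asarray(p, dtype=np.float64).ravel(), EPS, 1.0 - EPS)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log1p(-p))))


def kl_divergence(observed: np.ndarray, predicted: np.ndarray) -> float:
    """KL(observed ‖ predicted), per-sample sum then batch mean.

    Both arguments live on the probability simplex along the last axis.
    0·log(0/·) is taken as 0; the predicted vector is clipped away from 0.
    """
    o = np.atleast_2d(np.asarray(observed, dtype=np.float64))
    c = np.clip(np.atleast_2d(np.asarray(predicted, dtype=np.float64)), EPS, None)
    terms = np.where(o > 0, o * (np.log(np.where(o > 0, o, 1.0)) - np.log(c)), 0.0)
    return float(terms.sum(axis=1).mean())


def mean_squared_error(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    return float(np.mean((u - v) ** 2))
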