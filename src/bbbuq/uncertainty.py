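"""Per-prediction uncertainty scorers and their weighted combination.

Six scorers, one value per prediction, larger = less trustworthy:

* **entropy** — Shannon entropy of the predicted class distribution,
  µ = −Σ_c p_c log₂ p_c; base 2 so binary uncertainty spans [0, 1].
* **mc_dropout** — variance of the positive-class probability across
  stochastic dropout passes at inference.
* **multi_initial** — variance of the positive-class probability across
  independently initialized retrainings.
* **fps_dist** — Tanimoto distance to the nearest training molecule in
  ECFP4 space (1 − max similarity): an applicability-domain score.
* **latent_dist** — Euclidean distance to the nearest training molecule in
  the network's last-hidden-layer representation.
* **random** — uniform noise in [0, 1]; the baseline any useful scorer must
  beat.

Variances are population variances (divide by N) of p(positive). The
combination ("modZ" weighted average) anchors on entropy: every scorer is
min–max rescaled to [0, 1], entropy gets weight 1, and every other scorer is
weighted by its Spearman rank correlation with entropy, clipped at 0 so an
anti-correlated scorer cannot invert the ranking. The weighted mean is the
ensemble uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .exceptions import (
    DimensionMismatch,
    DropoutUnsupported,
    EmptyReference,
    EntropyMissing,
    LengthMismatch,
    TooFewReplicates,
)
from .featurization import max_similarity_profile
from .models import PredictionSet, TrainedModel, predict_probabilities

METHODS = ("entropy", "mc_dropout", "multi_initial", "fps_dist", "latent_dist", "random")


@dataclass
class UncertaintyVector:
    """Named per-prediction uncertainty scores (nonnegative)."""

    method: str
    values: np.ndarray
    scale: str = "native"  # "native" | "unit"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class EnsembleWeights:
    """modZ combination weights and the rank correlations behind them."""

    weights: dict = field(default_factory=dict)
    spearman: dict = field(default_factory=dict)


def entropy_uncertainty(preds: PredictionSet) -> UncertaintyVector:
    """Shannon entropy (base 2) of each prediction's class distribution."""
    p = np.asarray(preds.probabilities, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0.0, -p * np.log2(np.where(p > 0.0, p, 1.0)), 0.0)
    return UncertaintyVector(method="entropy", values=terms.sum(axis=1))


def population_variance(samples: np.ndarray) -> np.ndarray:
    """Column-wise population variance (ddof=0) of a (passes, n) array."""
    return np.var(np.asarray(samples, dtype=np.float64), axis=0, ddof=0)


def mc_dropout_uncertainty(
    model: TrainedModel, features, n_passes: int = 50, seed: int | None = None
) -> UncertaintyVector:
    """Variance of p(positive) across seeded dropout passes at inference."""
    if not model.supports_dropout_inference:
        raise DropoutUnsupported("MC-dropout requires an MLP")
    if n_passes < 2:
        raise ValueError("n_passes must be >= 2")
    rng = np.random.default_rng(seed)
    pass_seeds = rng.integers(0, 2**31 - 1, size=n_passes)
    p_pos = np.vstack(
        [
            predict_probabilities(model, features, dropout_active=True, pass_seed=int(s)).p_positive
            for s in pass_seeds
        ]
    )
    return UncertaintyVector(method="mc_dropout", values=population_variance(p_pos))


def multi_initial_uncertainty(replicates, features) -> UncertaintyVector:
    """Variance of p(positive) across independently initialized replicates."""
    replicates = list(replicates)
    if len(replicates) < 2:
        raise TooFewReplicates("need >= 2 replicate models")
    kinds = {(m.spec.family, m.spec.feature_kind) for m in replicates}
    if len(kinds) != 1:
        raise DimensionMismatch(f"mixed replicate specs: {kinds}")
    p_pos = np.vstack([predict_probabilities(m, features).p_positive for m in replicates])
    return UncertaintyVector(method="multi_initial", values=population_variance(p_pos))


def fps_dist_uncertainty(query_fps, train_fps) -> UncertaintyVector:
    """Tanimoto distance to the nearest training fingerprint, in [0, 1]."""
    max_sim = max_similarity_profile(query_fps, train_fps, exclude_self=False)
    return UncertaintyVector(method="fps_dist", values=1.0 - max_sim)


def latent_dist_uncertainty(query_latent, train_latent) -> UncertaintyVector:
    """Euclidean distance to the nearest training row in latent space."""
    q = np.atleast_2d(np.asarray(query_latent, dtype=np.float64))
    t = np.atleast_2d(np.asarray(train_latent, dtype=np.float64))
    if t.shape[0] == 0:
        raise EmptyReference("empty training latent matrix")
    if q.shape[1] != t.shape[1]:
        raise DimensionMismatch(f"latent dims {q.shape[1]} vs {t.shape[1]}")
    return UncertaintyVector(method="latent_dist", values=cdist(q, t).min(axis=1))


def random_uncertainty(n: int, seed: int | None = None) -> UncertaintyVector:
    """Uniform [0, 1] noise: the baseline scorer."""
    rng = np.random.default_rng(seed)
    return UncertaintyVector(method="random", values=rng.random(n))


def rescale_unit(u: UncertaintyVector) -> UncertaintyVector:
    """Min–max rescale to [0, 1]; a constant vector maps to all zeros."""
    v = u.values
    if v.size == 0:
        raise ValueError("empty uncertainty vector")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        scaled = np.zeros_like(v)
    else:
        scaled = (v - lo) / (hi - lo)
    return UncertaintyVector(method=u.method, values=scaled, scale="unit")


def modz_combine(
    methods: dict[str, UncertaintyVector],
) -> tuple[UncertaintyVector, EnsembleWeights]:
    """Spearman-weighted average of uncertainty scorers anchored on entropy.

    Each vector is unit-rescaled first (native scales are incommensurate:
    variances live near 0, distances near 1). Entropy's weight is fixed at 1;
    every other scorer is weighted by max(ρ_Spearman(scorer, entropy), 0).
    A scorer that is constant (undefined correlation) gets weight 0.
    """
    if "entropy" not in methods:
        raise EntropyMissing("modZ combination requires the entropy scorer")
    n = len(methods["entropy"])
    for name, u in methods.items():
        if len(u) != n:
            raise LengthMismatch(f"{name}: {len(u)} vs {n}")
    entropy_native = methods["entropy"].values
    weights: dict[str, float] = {}
    spearman: dict[str, float] = {}
    scaled: dict[str, np.ndarray] = {}
    for name, u in methods.items():
        scaled[name] = rescale_unit(u).values
        if name == "entropy":
            weights[name] = 1.0
            spearman[name] = 1.0
            continue
        rho = spearmanr(u.values, entropy_native).statistic
        if not np.isfinite(rho):
            rho = 0.0
        spearman[name] = float(rho)
        weights[name] = max(float(rho), 0.0)
    total = sum(weights.values())
    combined = sum(w * scaled[name] for name, w in weights.items()) / total
    vec = UncertaintyVector(method="ensemble", values=combined, scale="unit")
    return vec, EnsembleWeights(weights=weights, spearman=spearman)
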