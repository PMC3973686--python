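"""Linear baselines: log-odds-ratio scores and regularized linear classifiers.

The odds-ratio family assigns each individual the average over SNPs of
``g_j * log(OR_j)`` where ``g_j`` counts minor alleles and ``OR_j`` is
the allelic odds ratio — either estimated directly from the 2x2 allele
table (``fit_or``) or as the slope of a per-SNP univariate logistic
regression (``fit_or_beta``).

The classifier family minimizes ``(1/n) sum loss(y_i, w.x_i + b) +
lambda * penalty(w)`` with hinge or logistic loss and an L1 or L2
penalty, via a plain stochastic subgradient procedure with the Pegasos
step size ``eta_t = 1 / (lambda * t)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .genotype_data import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ORModel",
    "LinearModel",
    "fit_or",
    "fit_or_beta",
    "score_or",
    "fit_linear_classifier",
    "score_linear",
    "trend_pvalues",
]

_BETA_CAP = 10.0


@dataclass
class ORModel:
    """Per-SNP log allelic odds ratios."""

    log_or: np.ndarray
    source: str  # "empirical_counts" or "per_snp_logistic"


@dataclass
class LinearModel:
    weights: np.ndarray
    intercept: float
    loss: str
    penalty: str
    lam: float


def _allele_tables(data: GenotypeDataset):
    """Per-SNP 2x2 allele counts (minor/major x case/control), missing
    genotypes excluded."""
    G = data.genotypes
    case = data.phenotype == 1
    obs = G != MISSING
    Gz = np.where(obs, G, 0).astype(np.int64)
    minor_case = Gz[case].sum(axis=0).astype(float)
    minor_ctrl = Gz[~case].sum(axis=0).astype(float)
    alleles_case = 2.0 * obs[case].sum(axis=0)
    alleles_ctrl = 2.0 * obs[~case].sum(axis=0)
    return minor_case, alleles_case - minor_case, minor_ctrl, alleles_ctrl - minor_ctrl


def fit_or(data: GenotypeDataset, p_threshold: Optional[float] = None) -> ORModel:
    """Empirical allelic odds ratios with Haldane-Anscombe correction.

    ``OR_j = (minor/major odds in cases) / (minor/major odds in
    controls)``; whenever a table has a zero cell, 0.5 is added to all
    four cells, keeping every log OR finite.  With ``p_threshold`` set,
    SNPs whose Cochran-Armitage trend p-value exceeds the threshold get
    a zero weight (the optional p-value pre-filtering variant).
    """
    if not data.has_both_classes():
        raise ValueError("both classes required to fit odds ratios")
    a, b, c, d = _allele_tables(data)
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    corr = np.where(zero, 0.5, 0.0)
    log_or = np.log(((a + corr) * (d + corr)) / ((b + corr) * (c + corr)))
    if p_threshold is not None:
        log_or = np.where(trend_pvalues(data) <= p_threshold, log_or, 0.0)
    return ORModel(log_or=log_or, source="empirical_counts")


def score_or(model: ORModel, data: GenotypeDataset) -> np.ndarray:
    """Average risk over non-missing SNPs: ``(1/p_i) sum_j g_ij log OR_j``."""
    G = data.genotypes
    obs = G != MISSING
    Gz = np.where(obs, G, 0).astype(float)
    p_i = obs.sum(axis=1).astype(float)
    return (Gz @ model.log_or) / np.maximum(p_i, 1)


def fit_or_beta(data: GenotypeDataset, tol: float = 1e-8,
                max_iter: int = 50) -> ORModel:
    """Per-SNP univariate logistic regression slopes (additive coding).

    All SNPs are fitted in parallel with Newton/IRLS; complete
    separation is handled by capping ``|beta|`` at 10 with a logged
    warning.
    """
    if not data.has_both_classes():
        raise ValueError("both classes required to fit odds ratios")
    G = data.genotypes
    obs = G != MISSING
    g = np.where(obs, G, 0).astype(float)
    w_obs = obs.astype(float)
    y = data.phenotype.astype(float)[:, None]
    p = G.shape[1]
    alpha = np.zeros(p)
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = alpha[None, :] + beta[None, :] * g
        mu = expit(eta)
        r = (y - mu) * w_obs
        w = mu * (1 - mu) * w_obs
        s0 = w.sum(axis=0)
        s1 = (w * g).sum(axis=0)
        s2 = (w * g * g).sum(axis=0)
        g0 = r.sum(axis=0)
        g1 = (r * g).sum(axis=0)
        det = s0 * s2 - s1 * s1
        det = np.where(np.abs(det) < 1e-12, np.inf, det)
        da = (s2 * g0 - s1 * g1) / det
        db = (s0 * g1 - s1 * g0) / det
        alpha += da
        beta += db
        beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
        if max(np.abs(da).max(initial=0), np.abs(db).max(initial=0)) < tol:
            break
    n_capped = int((np.abs(beta) >= _BETA_CAP).sum())
    if n_capped:
        logger.warning(
            "capped %d per-SNP logistic slopes at |beta|=%g (separation)",
            n_capped, _BETA_CAP,
        )
    return ORModel(log_or=beta, source="per_snp_logistic")


def trend_pvalues(data: GenotypeDataset) -> np.ndarray:
    """Cochran-Armitage trend test p-values per SNP (additive scores)."""
    G = data.genotypes
    obs = G != MISSING
    y = data.phenotype.astype(float)
    p = G.shape[1]
    pvals = np.ones(p)
    g = np.where(obs, G, 0).astype(float)
    n = obs.sum(axis=0).astype(float)
    n_case = (obs * y[:, None]).sum(axis=0)
    sum_g = g.sum(axis=0)
    sum_g2 = (g * g).sum(axis=0)
    sum_gy = (g * y[:, None]).sum(axis=0)
    phi = n_case / np.maximum(n, 1)
    num = sum_gy - phi * sum_g
    var = phi * (1 - phi) * (sum_g2 - sum_g**2 / np.maximum(n, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = num / np.sqrt(var)
    z = np.where(np.isfinite(z), z, 0.0)
    return 2.0 * norm.sf(np.abs(z))


def fit_linear_classifier(
    data, loss: str = "hinge", penalty: str = "L2", lam: float = 1e-4,
    seed: int = 0, epochs: int = 50, standardize: bool = False, y=None,
) -> LinearModel:
    """Stochastic subgradient descent for regularized linear scoring.

    Minimizes ``(1/n) sum loss + lam * penalty(w)`` with ``eta_t =
    1/(lam t)``, a fixed epoch count and seeded per-epoch shuffling.
    Genotypes enter as raw 0/1/2 unless ``standardize`` is set.
    """
    if loss not in ("hinge", "logistic"):
        raise ValueError(f"unknown loss {loss!r}")
    if penalty not in ("L1", "L2"):
        raise ValueError(f"unknown penalty {penalty!r}")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if isinstance(data, GenotypeDataset):
        X = data.genotypes.astype(np.float64)
        X[data.genotypes == MISSING] = 0.0
        yv = data.phenotype
    else:
        X = np.asarray(data, dtype=np.float64)
        yv = np.asarray(y)
    ypm = np.where(yv == 1, 1.0, -1.0)
    n, p = X.shape
    mean = np.zeros(p)
    scale = np.ones(p)
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = (X - mean) / scale
    rng = np.random.default_rng(seed)
    w = np.zeros(p)
    b = 0.0
    # Pegasos-style decaying step; the offset keeps the first L1 steps
    # bounded (L2 is self-stabilizing through its multiplicative shrink).
    t0 = n if penalty == "L1" else 0
    t = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            t += 1
            eta = 1.0 / (lam * (t + t0))
            margin = ypm[i] * (X[i] @ w + b)
            if loss == "hinge":
                dmargin = -1.0 if margin < 1.0 else 0.0
            else:
                dmargin = -expit(-margin)
            if penalty == "L2":
                w -= eta * (dmargin * ypm[i] * X[i] + lam * w)
            else:  # truncated gradient: loss step then soft-threshold
                w -= eta * dmargin * ypm[i] * X[i]
                w = np.sign(w) * np.maximum(np.abs(w) - eta * lam, 0.0)
            b -= eta * dmargin * ypm[i]
    if standardize:  # fold standardization back into the weights
        w = w / scale
        b = b - float(mean @ w)
    return LinearModel(weights=w, intercept=b, loss=loss, penalty=penalty, lam=lam)


def score_linear(model: LinearModel, data) -> np.ndarray:
    if isinstance(data, GenotypeDataset):
        X = data.genotypes.astype(np.float64)
        X[data.genotypes == MISSING] = 0.0
    else:
        X = np.asarray(data, dtype=np.float64)
    return X @ model.weights + model.intercept
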