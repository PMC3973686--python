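"""Cross-validation with shared folds, AUC, and experiment grids.

Every method is evaluated on the exact same stratified k-fold plan so
that differences in mean AUC reflect the methods, not fold noise.  AUC
uses the Mann-Whitney formulation ``P(score_case > score_control) +
0.5 P(tie)`` computed exactly from ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import linear_baselines as lb
from . import tree_core, ttree
from .genotype_data import BlockMap, GenotypeDataset, impute_missing, make_block_map

__all__ = [
    "FoldPlan",
    "CVResult",
    "Method",
    "make_folds",
    "auc",
    "cross_validate",
    "run_grid",
    "make_method",
]


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of individuals to k cross-validation folds."""

    k: int
    assignment: np.ndarray
    seed: int

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=np.int64)
        object.__setattr__(self, "assignment", a)
        if not ((a >= 0) & (a < self.k)).all():
            raise ValueError("fold ids must lie in 0..k-1")

    def train_test(self, fold: int):
        test = np.nonzero(self.assignment == fold)[0]
        train = np.nonzero(self.assignment != fold)[0]
        return train, test

    def to_tsv(self, individual_ids, path) -> None:
        with open(path, "w") as fh:
            fh.write("individual\tfold\n")
            for i, f in zip(individual_ids, self.assignment):
                fh.write(f"{i}\t{f}\n")


def make_folds(phenotype, k: int, seed: int, stratified: bool = True) -> FoldPlan:
    """Seeded (by default stratified) k-fold assignment.

    Stratification shuffles each class separately and deals fold ids
    round-robin, so per-fold case fractions match the global fraction as
    closely as integer counts allow.
    """
    y = np.asarray(phenotype)
    n = y.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of individuals ({n})")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=np.int64)
    if stratified:
        for cls in np.unique(y):
            idx = np.nonzero(y == cls)[0]
            idx = rng.permutation(idx)
            assignment[idx] = np.arange(idx.size) % k
    else:
        assignment[:] = rng.permutation(np.arange(n) % k)
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: probability a random case outscores a random
    control, counting ties as one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)  # average ranks handle ties
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class Method:
    """A fit/score pair evaluated under cross-validation."""

    name: str
    fit: Callable[[GenotypeDataset, int], object]  # (train_data, seed) -> model
    score: Callable[[object, GenotypeDataset], np.ndarray]
    params: dict = field(default_factory=dict)


@dataclass
class CVResult:
    method: str
    fold_aucs: np.ndarray
    params: dict

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def cross_validate(
    method: Method,
    data: GenotypeDataset,
    folds: FoldPlan,
    seed: int = 0,
    impute_per_fold: bool = False,
) -> CVResult:
    """Fit on k-1 folds, score the held-out fold, average fold AUCs.

    By default missing genotypes are expected to have been imputed once
    on the full matrix before CV; ``impute_per_fold`` instead re-imputes
    the training and test matrices inside each fold.
    """
    fold_aucs = []
    for f in range(folds.k):
        train_idx, test_idx = folds.train_test(f)
        train = data.subset(train_idx)
        test = data.subset(test_idx)
        fold_seed = int(np.random.SeedSequence((seed, f)).generate_state(1)[0] % 2**31)
        if impute_per_fold:
            train = impute_missing(train, seed=fold_seed)
            test = impute_missing(test, seed=fold_seed + 1)
        model = method.fit(train, fold_seed)
        scores = method.score(model, test)
        fold_aucs.append(auc(scores, test.phenotype))
    return CVResult(method.name, np.asarray(fold_aucs), dict(method.params))


def make_method(name: str, block_map: Optional[BlockMap] = None, **hyper) -> Method:
    """Build a named method: rf, et, ttrees, or, or_beta, sgd_l1,
    sgd_l2 or logit.  Hyper-parameters are passed through to the
    underlying fit function; ``ttrees`` takes a ``block_map`` (or builds
    a contiguous one of size ``B`` at fit time)."""
    name = name.lower()
    if name in ("rf", "et"):
        mode = "exhaustive_cutpoint" if name == "rf" else "random_cutpoint"
        base = dict(split_mode=mode, bootstrap=(name == "rf"))
        base.update(hyper)

        def fit(train, seed, base=base):
            params = tree_core.ForestParams(**{**base, "seed": seed})
            return tree_core.fit_forest(train, params=params)

        return Method(name, fit, lambda m, d: m.predict_proba(d), dict(base))
    if name in ("ttrees", "tt"):
        def fit(train, seed, hyper=hyper, block_map=block_map):
            params = ttree.TTreeParams(**{**hyper, "seed": seed})
            bm = block_map or make_block_map(train.n_snps, params.B)
            return ttree.fit_ttrees(train, bm, params)

        return Method("ttrees", fit, lambda m, d: m.predict_proba(d), dict(hyper))
    if name == "or":
        return Method(
            "or",
            lambda train, seed: lb.fit_or(train, **hyper),
            lambda m, d: lb.score_or(m, d),
            dict(hyper),
        )
    if name == "or_beta":
        return Method(
            "or_beta",
            lambda train, seed: lb.fit_or_beta(train, **hyper),
            lambda m, d: lb.score_or(m, d),
            dict(hyper),
        )
    if name in ("sgd_l1", "sgd_l2", "logit"):
        loss = "logistic" if name == "logit" else "hinge"
        penalty = "L1" if name == "sgd_l1" else "L2"
        base = dict(loss=loss, penalty=penalty)
        base.update(hyper)

        def fit(train, seed, base=base):
            return lb.fit_linear_classifier(train, seed=seed, **base)

        return Method(name, fit, lambda m, d: lb.score_linear(m, d), dict(base))
    raise ValueError(f"unknown method {name!r}")


def run_grid(
    grid: Sequence[dict],
    data: GenotypeDataset,
    folds: FoldPlan,
    seed: int = 0,
    block_map: Optional[BlockMap] = None,
) -> pd.DataFrame:
    """Evaluate a list of method configurations on shared folds.

    Each grid entry is ``{"method": name, **hyperparams}``; the result
    table has one row per configuration with per-fold and mean AUCs.
    """
    rows = []
    for i, spec in enumerate(grid):
        spec = dict(spec)
        name = spec.pop("method")
        method = make_method(name, block_map=block_map, **spec)
        res = cross_validate(method, data, folds, seed=int(
            np.random.SeedSequence((seed, i)).generate_state(1)[0] % 2**31
        ))
        row = {"method": name, **spec, "mean_auc": res.mean_auc}
        for f, a in enumerate(res.fold_aucs):
            row[f"fold{f}_auc"] = a
        rows.append(row)
    return pd.DataFrame(rows)
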