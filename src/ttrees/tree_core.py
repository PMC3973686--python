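"""Binary classification trees and forests for additively coded genotypes.

Implements CART-style induction with the two classic randomization
schemes — Random-Forest splits (random variable subset, exhaustive
cut-point search) and Extra-Trees splits (random variable subset, one
random cut-point per variable) — plus soft-voting ensembles and
mean-decrease-impurity (MDI) variable importance.

Features must be integer-coded ordinal values (genotypes 0/1/2); a
univariate split is a threshold test ``x[j] <= c``.  Impurity is the
Gini index ``2 q (1 - q)`` throughout — the usual basis of MDI.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .genotype_data import MISSING, GenotypeDataset

__all__ = [
    "SplitSpec",
    "ForestParams",
    "Tree",
    "Forest",
    "gini_impurity",
    "best_split_exhaustive",
    "random_cutpoint_split",
    "grow_tree",
    "fit_forest",
    "save_forest",
    "load_forest",
]


def gini_impurity(class_counts) -> float:
    """Gini impurity ``2 q (1-q)`` of a (n_control, n_case) leaf."""
    n0, n1 = class_counts
    n = n0 + n1
    if n <= 0:
        raise ValueError("empty node has no impurity")
    q = n1 / n
    return 2.0 * q * (1.0 - q)


@dataclass(frozen=True)
class SplitSpec:
    """A univariate threshold split and its quality."""

    variable_index: int
    cut_point: float
    impurity_decrease: float
    n_node_samples: int


def _split_delta(labels: np.ndarray, mask_left: np.ndarray) -> float:
    n = labels.size
    n1 = int(labels.sum())
    nl = int(mask_left.sum())
    cl = int(labels[mask_left].sum())
    i0 = gini_impurity((n - n1, n1))
    il = gini_impurity((nl - cl, cl))
    ir = gini_impurity((n - nl - (n1 - cl), n1 - cl))
    return i0 - (nl / n) * il - ((n - nl) / n) * ir


def best_split_exhaustive(
    values, labels, variable_index: int = 0
) -> Optional[SplitSpec]:
    """Best threshold over midpoints of consecutive distinct sorted values.

    Returns ``None`` when the values are constant.  Ties in impurity
    decrease are broken toward the lowest cut-point.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size < 2:
        return None
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    y = labels[order].astype(np.int64)
    if v[0] == v[-1]:
        return None
    n = v.size
    n1 = int(y.sum())
    cum_n1 = np.cumsum(y)
    boundaries = np.nonzero(np.diff(v) > 0)[0]  # split after position b
    best = None
    i0 = gini_impurity((n - n1, n1))
    for b in boundaries:
        nl = b + 1
        cl = int(cum_n1[b])
        il = gini_impurity((nl - cl, cl))
        ir = gini_impurity(((n - nl) - (n1 - cl), n1 - cl))
        d = i0 - (nl / n) * il - ((n - nl) / n) * ir
        cut = 0.5 * (v[b] + v[b + 1])
        if best is None or d > best[0] or (d == best[0] and cut < best[1]):
            best = (d, cut)
    if best is None:
        return None
    return SplitSpec(
        variable_index=variable_index,
        cut_point=float(best[1]),
        impurity_decrease=float(best[0]),
        n_node_samples=n,
    )


def random_cutpoint_split(
    values, labels, seed=None, variable_index: int = 0
) -> Optional[SplitSpec]:
    """Extra-Trees split: one cut-point drawn uniformly in (min, max)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size < 2:
        return None
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        return None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = rng.random()
    while r <= 0.0:  # keep the cut strictly inside the range
        r = rng.random()
    cut = vmin + r * (vmax - vmin)
    d = _split_delta(labels.astype(np.int64), values <= cut)
    return SplitSpec(
        variable_index=variable_index,
        cut_point=cut,
        impurity_decrease=float(d),
        n_node_samples=values.size,
    )


@dataclass
class ForestParams:
    """Hyper-parameters for RF / Extra-Trees ensembles.

    ``m_try=None`` resolves to ``ceil(sqrt(p))`` at fit time.  ``N_min``
    is the minimum number of samples required to split a node (2 = fully
    grown).  ``split_mode`` selects RF-style exhaustive cut-points or
    ET-style random cut-points.
    """

    T: int = 100
    m_try: Optional[int] = None
    N_min: int = 2
    bootstrap: bool = True
    split_mode: str = "exhaustive_cutpoint"
    seed: int = 0

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.N_min < 2:
            raise ValueError("N_min must be >= 2")
        if self.split_mode not in ("exhaustive_cutpoint", "random_cutpoint"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")


class Tree:
    """A grown tree over flat node arrays (see :mod:`ttrees._kernels`)."""

    def __init__(self, feat, thr, left, right, n_node, n_case, delta, n_in_bag):
        self.feat = feat
        self.thr = thr
        self.left = left
        self.right = right
        self.n_node = n_node
        self.n_case = n_case
        self.delta = delta
        self.n_in_bag = int(n_in_bag)

    @property
    def n_nodes(self) -> int:
        return self.feat.size

    @property
    def n_internal(self) -> int:
        return int((self.feat >= 0).sum())

    def leaf_proba(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.n_case / np.maximum(self.n_node, 1)

    def predict_proba(self, X) -> np.ndarray:
        X = _as_genotype_matrix(X)
        return _kernels.predict_tree(
            self.feat, self.thr, self.left, self.right, self.leaf_proba(), X
        )

    def mdi_importance(self, p: int) -> np.ndarray:
        """Per-variable weighted impurity decrease of this tree."""
        imp = np.zeros(p)
        internal = self.feat >= 0
        np.add.at(
            imp,
            self.feat[internal],
            (self.n_node[internal] / self.n_in_bag) * self.delta[internal],
        )
        return imp

    def total_weighted_decrease(self) -> float:
        internal = self.feat >= 0
        return float(
            ((self.n_node[internal] / self.n_in_bag) * self.delta[internal]).sum()
        )

    def to_record(self) -> dict:
        return {
            "feat": self.feat.tolist(),
            "thr": self.thr.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "n_node": self.n_node.tolist(),
            "n_case": self.n_case.tolist(),
            "delta": self.delta.tolist(),
            "n_in_bag": self.n_in_bag,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Tree":
        return cls(
            np.asarray(rec["feat"], np.int64),
            np.asarray(rec["thr"], float),
            np.asarray(rec["left"], np.int64),
            np.asarray(rec["right"], np.int64),
            np.asarray(rec["n_node"], np.int64),
            np.asarray(rec["n_case"], np.int64),
            np.asarray(rec["delta"], float),
            rec["n_in_bag"],
        )


def _as_genotype_matrix(X) -> np.ndarray:
    if isinstance(X, GenotypeDataset):
        X = X.genotypes
    X = np.ascontiguousarray(X, dtype=np.int8)
    if (X == MISSING).any():
        raise ValueError("matrix contains missing genotypes; impute first")
    if X.size and (X.min() < 0 or X.max() > 63):
        raise ValueError("features must be small non-negative integer codes")
    return X


def _resolve_xy(data, y):
    if isinstance(data, GenotypeDataset):
        return _as_genotype_matrix(data.genotypes), data.phenotype.astype(np.uint8)
    if y is None:
        raise ValueError("y required when data is a plain matrix")
    return _as_genotype_matrix(data), np.asarray(y, dtype=np.uint8)


def _tree_seeds(seed: int, T: int) -> np.ndarray:
    # independent per-tree streams; kept below 2^31 for the numba RNG
    return (
        np.random.SeedSequence(seed).generate_state(T, dtype=np.uint64) % (2**31)
    ).astype(np.int64)


def grow_tree(X, y, params: ForestParams, seed: Optional[int] = None) -> Tree:
    """Grow a single tree (no bootstrap) with the given randomization."""
    X, y = _resolve_xy(X, y)
    n, p = X.shape
    if n < 1:
        raise ValueError("need at least one sample")
    m_try = params.m_try or max(1, math.ceil(math.sqrt(p)))
    m_try = min(m_try, p)
    arrays = _kernels.grow_snp_tree(
        X,
        y,
        np.arange(n, dtype=np.int64),
        m_try,
        params.N_min,
        1 if params.split_mode == "random_cutpoint" else 0,
        int(X.max()) if X.size else 1,
        int(params.seed if seed is None else seed),
    )
    return Tree(*arrays, n_in_bag=n)


class Forest:
    """Soft-voting ensemble of randomized trees."""

    def __init__(self, trees: Sequence[Tree], params: ForestParams, n_features: int,
                 oob_indices=None):
        self.trees = list(trees)
        self.params = params
        self.n_features = n_features
        self.oob_indices = oob_indices

    def predict_proba(self, X) -> np.ndarray:
        X = _as_genotype_matrix(X)
        out = np.zeros(X.shape[0])
        for t in self.trees:
            out += _kernels.predict_tree(
                t.feat, t.thr, t.left, t.right, t.leaf_proba(), X
            )
        return out / len(self.trees)

    def predict(self, X) -> np.ndarray:
        """Hard majority vote (1 = case)."""
        return (self.predict_proba(X) > 0.5).astype(np.uint8)

    def mdi_importance(self) -> np.ndarray:
        imp = np.zeros(self.n_features)
        for t in self.trees:
            imp += t.mdi_importance(self.n_features)
        return imp / len(self.trees)


def fit_forest(data, y=None, params: Optional[ForestParams] = None) -> Forest:
    """Fit an RF or ET ensemble of ``params.T`` trees.

    With ``bootstrap=True`` each tree sees an n-sample bootstrap copy;
    out-of-bag indices are recorded on the model.  Per-tree seeds derive
    from the master seed, so serial and parallel runs agree.
    """
    params = params or ForestParams()
    X, y = _resolve_xy(data, y)
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must contain both classes for fitting")
    m_try = params.m_try or max(1, math.ceil(math.sqrt(p)))
    m_try = min(m_try, p)
    seeds = _tree_seeds(params.seed, params.T)
    vmax = int(X.max()) if X.size else 1
    mode = 1 if params.split_mode == "random_cutpoint" else 0
    trees = []
    oob = []
    for t in range(params.T):
        rng = np.random.default_rng(seeds[t])
        if params.bootstrap:
            samp = rng.integers(0, n, size=n).astype(np.int64)
            oob.append(np.setdiff1d(np.arange(n), samp))
        else:
            samp = np.arange(n, dtype=np.int64)
            oob.append(np.empty(0, dtype=np.int64))
        arrays = _kernels.grow_snp_tree(
            X, y, samp, m_try, params.N_min, mode, vmax, int(seeds[t])
        )
        trees.append(Tree(*arrays, n_in_bag=n))
    return Forest(trees, params, n_features=p, oob_indices=oob)


def mdi_importance(model: Forest) -> np.ndarray:
    """MDI importance: per-variable mean (over trees) of the weighted
    impurity decreases of the nodes testing it."""
    return model.mdi_importance()


def predict_proba(model: Forest, X) -> np.ndarray:
    return model.predict_proba(X)


def save_forest(model: Forest, path) -> None:
    """JSON-lines model file: one params header then one tree per line."""
    with open(path, "w") as fh:
        header = {
            "model": "forest",
            "params": asdict(model.params),
            "n_features": model.n_features,
        }
        fh.write(json.dumps(header) + "\n")
        for t in model.trees:
            fh.write(json.dumps(t.to_record()) + "\n")


def load_forest(path) -> Forest:
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("model") != "forest":
            raise ValueError("not a forest model file")
        trees = [Tree.from_record(json.loads(line)) for line in fh if line.strip()]
    return Forest(trees, ForestParams(**header["params"]), header["n_features"])
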