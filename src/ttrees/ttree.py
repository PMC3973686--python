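"""Trees-inside-trees (T-Trees) ensembles for block-structured GWAS data.

A T-Tree is a decision tree whose internal ("outer") nodes do not test a
single SNP but a *block* of contiguous SNPs: at each outer node a small
node-count-limited Extra-Tree (the "inner tree") is grown on the block's
SNPs using the samples present at the node, every sample is scored with
the inner tree's case-probability, and an exhaustive cut-point is fitted
on that numeric score to partition the node.  The number of test nodes
in an inner tree is capped by the internal-complexity parameter ``IC``,
and inner leaves are expanded in uniform-random order to avoid the
degenerate chains a depth-first expansion would produce under the cap.

An ensemble of ``T`` such trees is grown on bootstrap copies; two nested
MDI-style importance measures fall out of the structure:

* **SNP importance** — weighted impurity decreases of all *inner* nodes
  testing the SNP, regardless of originating block;
* **block importance** — weighted impurity decreases of all *outer*
  nodes testing the block.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .genotype_data import BlockMap, GenotypeDataset
from .tree_core import SplitSpec, _as_genotype_matrix, _resolve_xy, _tree_seeds, best_split_exhaustive

__all__ = [
    "TTreeParams",
    "InnerTree",
    "TTree",
    "TTreeEnsemble",
    "ImportanceReport",
    "grow_inner_tree",
    "inner_tree_scores",
    "split_outer_node",
    "fit_ttrees",
    "predict_ttrees",
    "snp_importance",
    "block_importance",
    "importance_report",
    "merge_important_snps",
    "save_ttrees",
    "load_ttrees",
]


@dataclass
class TTreeParams:
    """T-Trees hyper-parameters.

    ``B`` is the nominal block size (used when the caller asks the model
    to build its own contiguous map), ``IC`` the maximum number of test
    nodes per inner tree, ``k_internal`` the number of candidate SNPs
    probed per inner node (default ``ceil(sqrt(B))``), ``m_try_blocks``
    the number of candidate blocks per outer node (default
    ``ceil(sqrt(n_blocks))``).  ``N_min=None`` resolves at fit time to
    ``max(2, n // 8)`` — T-Trees work best strongly pruned.
    ``laplace`` optionally smooths inner-leaf probabilities
    ``(c + a) / (n + 2a)``; the default is the raw case fraction.
    """

    T: int = 1000
    B: int = 20
    IC: int = 5
    m_try_blocks: Optional[int] = None
    N_min: Optional[int] = None
    k_internal: Optional[int] = None
    bootstrap: bool = True
    laplace: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.IC < 1:
            raise ValueError("IC must be >= 1")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.laplace < 0:
            raise ValueError("laplace must be >= 0")


class InnerTree:
    """A node-count-limited Extra-Tree over one block's SNPs.

    ``var`` holds global SNP column indices (-1 for leaves); leaf
    case-probabilities are ``(n_case + a) / (n_node + 2a)``.
    """

    def __init__(self, block_index, var, cut, left, right, n_node, n_case,
                 delta, n_test_nodes, laplace=0.0):
        self.block_index = int(block_index)
        self.var = var
        self.cut = cut
        self.left = left
        self.right = right
        self.n_node = n_node
        self.n_case = n_case
        self.delta = delta
        self.n_test_nodes = int(n_test_nodes)
        self.laplace = float(laplace)

    @property
    def n_nodes(self) -> int:
        return self.var.size

    def leaf_proba(self) -> np.ndarray:
        a = self.laplace
        return (self.n_case + a) / (self.n_node + 2.0 * a)

    def scores(self, X) -> np.ndarray:
        """Case-probability of each row of X under this inner tree."""
        X = _as_genotype_matrix(X)
        return _kernels.predict_tree(
            self.var, self.cut, self.left, self.right, self.leaf_proba(), X
        )

    def total_weighted_decrease(self, n_total: int) -> float:
        internal = self.var >= 0
        return float(
            ((self.n_node[internal] / n_total) * self.delta[internal]).sum()
        )


def grow_inner_tree(
    X_block, y_node, IC: int, k_internal: Optional[int] = None,
    seed: int = 0, block_index: int = 0, column_indices=None,
    laplace: float = 0.0,
) -> InnerTree:
    """Grow one inner Extra-Tree on a block submatrix.

    ``X_block`` is ``n_node x B`` (the block's SNPs only, unless
    ``column_indices`` names the block columns inside a wider matrix).
    Degenerate input (pure labels, constant SNPs, n < 2) yields a
    0-test-node stump carrying the root case probability.
    """
    X = _as_genotype_matrix(X_block)
    y = np.asarray(y_node, dtype=np.uint8)
    if column_indices is None:
        bcols = np.arange(X.shape[1], dtype=np.int64)
    else:
        bcols = np.asarray(column_indices, dtype=np.int64)
    k_internal = k_internal or max(1, math.ceil(math.sqrt(bcols.size)))
    out = _kernels.grow_inner_tree_seeded(
        X, y, bcols, int(IC), int(k_internal), int(seed)
    )
    ivar, icut, ileft, iright, inn, inc, idelta, node_of, n_test = out
    return InnerTree(
        block_index, ivar, icut, ileft, iright, inn, inc, idelta, n_test,
        laplace=laplace,
    )


def inner_tree_scores(tree: InnerTree, X_block) -> np.ndarray:
    return tree.scores(X_block)


@dataclass
class OuterSplit:
    """The (block, inner tree, cut-point) triple selected at an outer node."""

    block_index: int
    inner_tree: InnerTree
    cut_point: float
    impurity_decrease: float
    n_node_samples: int

    def left_mask(self, X) -> np.ndarray:
        return self.inner_tree.scores(X) <= self.cut_point


def split_outer_node(
    node_samples, data, block_map: BlockMap, params: TTreeParams, seed: int
) -> Optional[OuterSplit]:
    """Reference (non-fused) outer-node split used for analysis and tests.

    Draws ``m_try_blocks`` candidate blocks without replacement, grows an
    inner tree per candidate on the node's samples, fits the best
    exhaustive cut-point on each candidate's score vector, and keeps the
    triple with the largest impurity decrease (ties: lowest block
    index).  Returns ``None`` when no candidate achieves a positive
    decrease with two non-empty children.
    """
    if isinstance(data, GenotypeDataset):
        X, y = _resolve_xy(data, None)
    else:
        X, y = _resolve_xy(*data)
    idx = np.asarray(node_samples, dtype=np.int64)
    Xn, yn = X[idx], y[idx]
    if len(np.unique(yn)) < 2 or idx.size < 2:
        return None
    rng = np.random.default_rng(seed)
    nb = block_map.n_blocks
    m = params.m_try_blocks or max(1, math.ceil(math.sqrt(nb)))
    cand = rng.permutation(nb)[: min(m, nb)]
    k_int_default = params.k_internal
    best: Optional[OuterSplit] = None
    for b in cand:
        bcols = block_map.blocks[b]
        k_int = k_int_default or max(1, math.ceil(math.sqrt(len(bcols))))
        it = grow_inner_tree(
            Xn[:, bcols], yn, params.IC, k_int,
            seed=int(rng.integers(2**31)), block_index=int(b),
            laplace=params.laplace,
        )
        # store global column indices so the tree can score full matrices
        it.var = np.where(it.var >= 0, bcols[np.maximum(it.var, 0)], -1)
        scores = it.scores(Xn)
        spec = best_split_exhaustive(scores, yn, variable_index=int(b))
        if spec is None or spec.impurity_decrease <= 0:
            continue
        cand_split = OuterSplit(
            block_index=int(b),
            inner_tree=it,
            cut_point=spec.cut_point,
            impurity_decrease=spec.impurity_decrease,
            n_node_samples=idx.size,
        )
        if (
            best is None
            or cand_split.impurity_decrease > best.impurity_decrease
            or (
                cand_split.impurity_decrease == best.impurity_decrease
                and cand_split.block_index < best.block_index
            )
        ):
            best = cand_split
    return best


class TTree:
    """One grown T-Tree over flat outer-node and pooled inner-node arrays."""

    def __init__(self, oblk, ocut, oleft, oright, onn, onc, odelta,
                 oioff, oin, pvar, pcut, pleft, pright, pnn, pnc, pdelta,
                 n_in_bag, laplace=0.0):
        self.oblk = oblk
        self.ocut = ocut
        self.oleft = oleft
        self.oright = oright
        self.onn = onn
        self.onc = onc
        self.odelta = odelta
        self.oioff = oioff
        self.oin = oin
        self.pvar = pvar
        self.pcut = pcut
        self.pleft = pleft
        self.pright = pright
        self.pnn = pnn
        self.pnc = pnc
        self.pdelta = pdelta
        self.n_in_bag = int(n_in_bag)
        self.laplace = float(laplace)

    @property
    def n_outer_internal(self) -> int:
        return int((self.oblk >= 0).sum())

    def inner_trees(self) -> list[InnerTree]:
        out = []
        for node in np.nonzero(self.oblk >= 0)[0]:
            off, cnt = self.oioff[node], self.oin[node]
            sl = slice(off, off + cnt)
            out.append(
                InnerTree(
                    self.oblk[node],
                    self.pvar[sl], self.pcut[sl], self.pleft[sl],
                    self.pright[sl], self.pnn[sl], self.pnc[sl],
                    self.pdelta[sl],
                    n_test_nodes=int((self.pvar[sl] >= 0).sum()),
                    laplace=self.laplace,
                )
            )
        return out

    def predict_proba(self, X) -> np.ndarray:
        X = _as_genotype_matrix(X)
        return _kernels.predict_ttree(
            self.oblk, self.ocut, self.oleft, self.oright, self.onn, self.onc,
            self.oioff, self.pvar, self.pcut, self.pleft, self.pright,
            self.pnn, self.pnc, self.laplace, X,
        )

    def snp_importance(self, p: int) -> np.ndarray:
        imp = np.zeros(p)
        inner = self.pvar >= 0
        np.add.at(
            imp,
            self.pvar[inner],
            (self.pnn[inner] / self.n_in_bag) * self.pdelta[inner],
        )
        return imp

    def block_importance(self, n_blocks: int) -> np.ndarray:
        imp = np.zeros(n_blocks)
        outer = self.oblk >= 0
        np.add.at(
            imp,
            self.oblk[outer],
            (self.onn[outer] / self.n_in_bag) * self.odelta[outer],
        )
        return imp

    def to_record(self) -> dict:
        rec = {}
        for name in ("oblk", "ocut", "oleft", "oright", "onn", "onc",
                     "odelta", "oioff", "oin", "pvar", "pcut", "pleft",
                     "pright", "pnn", "pnc", "pdelta"):
            rec[name] = getattr(self, name).tolist()
        rec["n_in_bag"] = self.n_in_bag
        rec["laplace"] = self.laplace
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "TTree":
        kwargs = {}
        for name in ("oblk", "oleft", "oright", "onn", "onc", "oioff",
                     "oin", "pvar", "pleft", "pright", "pnn", "pnc"):
            kwargs[name] = np.asarray(rec[name], np.int64)
        for name in ("ocut", "odelta", "pcut", "pdelta"):
            kwargs[name] = np.asarray(rec[name], float)
        return cls(n_in_bag=rec["n_in_bag"], laplace=rec.get("laplace", 0.0),
                   **kwargs)


class TTreeEnsemble:
    """Ensemble of T outer trees plus the block map they were grown on."""

    def __init__(self, trees: Sequence[TTree], block_map: BlockMap,
                 params: TTreeParams, n_features: int):
        self.trees = list(trees)
        self.block_map = block_map
        self.params = params
        self.n_features = n_features

    def predict_proba(self, X) -> np.ndarray:
        X = _as_genotype_matrix(X)
        out = np.zeros(X.shape[0])
        for t in self.trees:
            out += t.predict_proba(X)
        return out / len(self.trees)

    def snp_importance(self) -> np.ndarray:
        imp = np.zeros(self.n_features)
        for t in self.trees:
            imp += t.snp_importance(self.n_features)
        return imp / len(self.trees)

    def block_importance(self) -> np.ndarray:
        imp = np.zeros(self.block_map.n_blocks)
        for t in self.trees:
            imp += t.block_importance(self.block_map.n_blocks)
        return imp / len(self.trees)


def fit_ttrees(data, block_map: BlockMap, params: Optional[TTreeParams] = None,
               y=None) -> TTreeEnsemble:
    """Fit an ensemble of ``params.T`` T-Trees on bootstrap copies."""
    params = params or TTreeParams()
    X, y = _resolve_xy(data, y)
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype must contain both classes for fitting")
    if block_map.n_snps != p:
        raise ValueError("block map does not cover the SNP matrix")
    nb = block_map.n_blocks
    m_try = params.m_try_blocks or max(1, math.ceil(math.sqrt(nb)))
    m_try = min(m_try, nb)
    n_min = params.N_min if params.N_min is not None else max(2, n // 8)
    sizes = block_map.sizes()
    k_int = params.k_internal or max(1, math.ceil(math.sqrt(max(sizes))))
    bsnps = np.concatenate(block_map.blocks).astype(np.int64)
    boff = np.zeros(nb + 1, dtype=np.int64)
    np.cumsum(sizes, out=boff[1:])
    seeds = _tree_seeds(params.seed, params.T)
    trees = []
    for t in range(params.T):
        rng = np.random.default_rng(seeds[t])
        if params.bootstrap:
            samp = rng.integers(0, n, size=n).astype(np.int64)
        else:
            samp = np.arange(n, dtype=np.int64)
        arrays = _kernels.grow_ttree(
            X, y, samp, bsnps, boff, m_try, n_min, params.IC, k_int,
            params.laplace, int(seeds[t]),
        )
        trees.append(TTree(*arrays, n_in_bag=n, laplace=params.laplace))
    return TTreeEnsemble(trees, block_map, params, n_features=p)


def predict_ttrees(model: TTreeEnsemble, data) -> np.ndarray:
    X = data.genotypes if isinstance(data, GenotypeDataset) else data
    return model.predict_proba(X)


def snp_importance(model: TTreeEnsemble) -> np.ndarray:
    return model.snp_importance()


def block_importance(model: TTreeEnsemble) -> np.ndarray:
    return model.block_importance()


def _ranks(scores: np.ndarray) -> np.ndarray:
    """Rank 1 = largest score; ties broken by lowest index."""
    order = np.lexsort((np.arange(scores.size), -scores))
    ranks = np.empty(scores.size, dtype=np.int64)
    ranks[order] = np.arange(1, scores.size + 1)
    return ranks


@dataclass
class ImportanceReport:
    snp_importance: np.ndarray
    block_importance: np.ndarray
    snp_ranks: np.ndarray
    block_ranks: np.ndarray


def importance_report(model: TTreeEnsemble) -> ImportanceReport:
    si = model.snp_importance()
    bi = model.block_importance()
    return ImportanceReport(si, bi, _ranks(si), _ranks(bi))


def merge_important_snps(
    snp_imp: np.ndarray, top_n: int = 200, gap: int = 20
) -> list[dict]:
    """Group top-ranked SNPs into regions.

    Takes the ``top_n`` SNPs by importance and merges those whose matrix
    indices are separated by at most ``gap`` SNPs; each region reports
    its span, size, best SNP and that SNP's importance and overall rank.
    ``gap=0`` yields one region per selected SNP.
    """
    ranks = _ranks(snp_imp)
    top = np.sort(np.argsort(-snp_imp, kind="stable")[:top_n])
    regions = []
    start = prev = None
    members: list[int] = []
    for j in [int(x) for x in top] + [None]:
        if prev is not None and (j is None or j - prev > gap):
            best = max(members, key=lambda s: (snp_imp[s], -s))
            regions.append(
                {
                    "start": start,
                    "end": prev,
                    "n_snps": len(members),
                    "top_snp": best,
                    "importance": float(snp_imp[best]),
                    "rank": int(ranks[best]),
                }
            )
            members = []
            start = None
        if j is None:
            break
        if start is None:
            start = j
        members.append(j)
        prev = j
    return regions


def write_importance_tsv(report: ImportanceReport, snp_ids, path,
                         snp_positions=None) -> None:
    """TSV of per-SNP importances: rank, snp_id, chrom, position, score."""
    order = np.argsort(report.snp_ranks)
    with open(path, "w") as fh:
        fh.write("rank\tsnp_id\tchrom\tposition\timportance\n")
        for j in order:
            chrom, pos = ("NA", "NA")
            if snp_positions is not None:
                chrom, pos = snp_positions[j]
            fh.write(
                f"{report.snp_ranks[j]}\t{snp_ids[j]}\t{chrom}\t{pos}\t"
                f"{report.snp_importance[j]:.6g}\n"
            )


def save_ttrees(model: TTreeEnsemble, path) -> None:
    """JSON-lines model file: params + block map header, one tree/line."""
    with open(path, "w") as fh:
        header = {
            "model": "ttrees",
            "params": asdict(model.params),
            "n_features": model.n_features,
            "blocks": [b.tolist() for b in model.block_map.blocks],
            "block_size_B": model.block_map.block_size_B,
        }
        fh.write(json.dumps(header) + "\n")
        for t in model.trees:
            fh.write(json.dumps(t.to_record()) + "\n")


def load_ttrees(path) -> TTreeEnsemble:
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("model") != "ttrees":
            raise ValueError("not a ttrees model file")
        trees = [TTree.from_record(json.loads(line)) for line in fh if line.strip()]
    bm = BlockMap(
        blocks=tuple(np.asarray(b) for b in header["blocks"]),
        block_size_B=header["block_size_B"],
    )
    return TTreeEnsemble(trees, bm, TTreeParams(**header["params"]),
                         header["n_features"])
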