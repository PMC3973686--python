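"""Reference experiments: seeded multi-run studies on the bundled scenarios.

These drivers reproduce, at desk scale on synthetic LD-block data, the
qualitative comparisons the method was designed around: block-aware
T-Trees versus SNP-wise forests under within-block combination effects,
contiguous versus randomized block maps, causal-locus recovery through
the nested importances, null calibration, and the linear-baseline
ordering on additive signal.  Every study takes an explicit master seed
and derives per-replicate seeds from it, so results are exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest, chisquare

from . import synthetic as syn
from . import tree_core, ttree
from .evaluation import auc, cross_validate, make_folds, make_method
from .genotype_data import impute_missing, make_block_map, shuffle_block_map

__all__ = [
    "study_seeds",
    "interaction_study",
    "null_study",
    "additive_study",
    "inner_tree_invariants",
    "oracle_equivalences",
    "imputation_fidelity",
]

LINEAR_METHODS = ("or", "or_beta", "sgd_l1", "sgd_l2", "logit")


def study_seeds(master_seed: int, n_seeds: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n_seeds,
                                                               dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _tt_method(block_map=None, T=200, B=10, IC=5):
    return make_method("ttrees", block_map=block_map, T=T, B=B, IC=IC)


def interaction_study(
    master_seed: int = 1,
    n_seeds: int = 10,
    n: int = 2000,
    T: int = 200,
    k_folds: int = 5,
    with_linear: bool = True,
) -> dict:
    """Super-allele scenario: TT vs RF vs linear, contiguous vs shuffled
    blocks, and causal-locus recovery, over ``n_seeds`` replicates.

    RF is evaluated at both m = sqrt(p) and m = p/10 and the better mean
    AUC is kept per replicate (tuned in RF's favor).
    """
    rows = []
    for seed in study_seeds(master_seed, n_seeds):
        sd = syn.simulate(syn.interaction_scenario(n=n, seed=seed))
        data, bm = sd.data, sd.block_map
        p = data.n_snps
        folds = make_folds(data.phenotype, k_folds, seed=seed)
        row = {
            "seed": seed,
            "bayes_auc": auc(sd.true_risk, data.phenotype),
            "tt_auc": cross_validate(_tt_method(T=T), data, folds).mean_auc,
            "tt_shuffled_auc": cross_validate(
                _tt_method(block_map=shuffle_block_map(bm, seed=seed + 1), T=T),
                data, folds).mean_auc,
            "rf_auc": max(
                cross_validate(make_method("rf", T=T, m_try=m), data,
                               folds).mean_auc
                for m in (int(np.ceil(np.sqrt(p))), p // 10)
            ),
        }
        if with_linear:
            for name in LINEAR_METHODS:
                hyper = {"lam": 1e-3} if name not in ("or", "or_beta") else {}
                row[f"{name}_auc"] = cross_validate(
                    make_method(name, **hyper), data, folds).mean_auc
        # recovery: importances from a fit on the full replicate
        model = ttree.fit_ttrees(
            data, bm, ttree.TTreeParams(T=T, B=10, IC=5, seed=seed)
        )
        bi, si = model.block_importance(), model.snp_importance()
        causal = set(sd.info["causal_blocks"])
        top5 = set(np.argsort(-bi, kind="stable")[:5].tolist())
        top20_blocks = {
            int(j) // sd.block_map.block_size_B
            for j in np.argsort(-si, kind="stable")[:20]
        }
        row["blocks_in_top5"] = causal <= top5
        row["snps_in_top20"] = causal <= top20_blocks
        rows.append(row)

    out = {"replicates": rows, "n_seeds": n_seeds}
    tt = np.array([r["tt_auc"] for r in rows])
    rf = np.array([r["rf_auc"] for r in rows])
    sh = np.array([r["tt_shuffled_auc"] for r in rows])
    out["mean_tt_auc"] = float(tt.mean())
    out["mean_rf_auc"] = float(rf.mean())
    out["mean_tt_shuffled_auc"] = float(sh.mean())
    out["mean_bayes_auc"] = float(np.mean([r["bayes_auc"] for r in rows]))
    out["tt_minus_rf"] = float((tt - rf).mean())
    out["tt_minus_shuffled"] = float((tt - sh).mean())
    out["tt_beats_rf_count"] = int((tt > rf).sum())
    out["sign_test_p"] = float(
        binomtest(int((tt > rf).sum()), n_seeds, alternative="greater").pvalue
    )
    if with_linear:
        best_lin = np.array([
            max(r[f"{m}_auc"] for m in LINEAR_METHODS) for r in rows
        ])
        out["mean_best_linear_auc"] = float(best_lin.mean())
        out["tt_minus_best_linear"] = float((tt - best_lin).mean())
    out["block_recovery_rate"] = float(
        np.mean([r["blocks_in_top5"] for r in rows])
    )
    out["snp_recovery_rate"] = float(
        np.mean([r["snps_in_top20"] for r in rows])
    )
    return out


def null_study(
    master_seed: int = 1,
    n_seeds: int = 10,
    n: int = 2000,
    T: int = 200,
    k_folds: int = 5,
) -> dict:
    """All methods on phenotypes independent of genotype: every mean CV
    AUC should sit near one half."""
    methods = ("ttrees", "rf") + LINEAR_METHODS
    per_method = {m: [] for m in methods}
    for seed in study_seeds(master_seed, n_seeds):
        sd = syn.simulate(syn.null_scenario(n=n, seed=seed))
        folds = make_folds(sd.data.phenotype, k_folds, seed=seed)
        for name in methods:
            if name == "ttrees":
                method = _tt_method(T=T)
            elif name == "rf":
                method = make_method("rf", T=T)
            elif name in ("or", "or_beta"):
                method = make_method(name)
            else:
                method = make_method(name, lam=1e-3)
            per_method[name].append(
                cross_validate(method, sd.data, folds).mean_auc
            )
    return {
        "mean_auc": {m: float(np.mean(v)) for m, v in per_method.items()},
        "per_seed": per_method,
        "max_abs_deviation": float(
            max(abs(np.mean(v) - 0.5) for v in per_method.values())
        ),
    }


def additive_study(
    master_seed: int = 1,
    n_seeds: int = 10,
    T: int = 200,
    k_folds: int = 5,
) -> dict:
    """Additive-only panel: OR and OR-beta should approach the Bayes AUC
    and agree with each other; T-Trees should keep pace."""
    rows = []
    for seed in study_seeds(master_seed, n_seeds):
        sd = syn.simulate(syn.additive_scenario(seed=seed))
        folds = make_folds(sd.data.phenotype, k_folds, seed=seed)
        rows.append({
            "seed": seed,
            "bayes_auc": auc(sd.true_risk, sd.data.phenotype),
            "or_auc": cross_validate(make_method("or"), sd.data,
                                     folds).mean_auc,
            "or_beta_auc": cross_validate(make_method("or_beta"), sd.data,
                                          folds).mean_auc,
            "tt_auc": cross_validate(
                _tt_method(block_map=sd.block_map, T=T), sd.data,
                folds).mean_auc,
        })
    res = {k: float(np.mean([r[k] for r in rows]))
           for k in ("bayes_auc", "or_auc", "or_beta_auc", "tt_auc")}
    res["replicates"] = rows
    res["or_vs_or_beta"] = abs(res["or_auc"] - res["or_beta_auc"])
    res["bayes_minus_or"] = res["bayes_auc"] - max(res["or_auc"],
                                                   res["or_beta_auc"])
    res["tt_minus_best_linear"] = res["tt_auc"] - max(res["or_auc"],
                                                      res["or_beta_auc"])
    return res


def inner_tree_invariants(
    master_seed: int = 1, n_builds: int = 10_000
) -> dict:
    """Randomized sweep of inner-tree builds: the IC node-count cap, block
    containment of split variables and MDI conservation must never fail."""
    rng = np.random.default_rng(master_seed)
    violations = {"node_cap": 0, "containment": 0, "conservation": 0}
    worst_conservation = 0.0
    for i in range(n_builds):
        n = int(rng.integers(10, 120))
        B = int(rng.integers(2, 12))
        ic = int(rng.integers(1, 8))
        X = rng.integers(0, 3, size=(n, B)).astype(np.int8)
        y = rng.integers(0, 2, n).astype(np.uint8)
        t = ttree.grow_inner_tree(
            X, y, IC=ic, k_internal=int(rng.integers(1, B + 1)),
            seed=int(rng.integers(2**31)),
        )
        if t.n_test_nodes > ic:
            violations["node_cap"] += 1
        used = t.var[t.var >= 0]
        if used.size and (used.min() < 0 or used.max() >= B):
            violations["containment"] += 1
        internal = t.var >= 0
        contrib = ((t.n_node[internal] / n) * t.delta[internal]).sum()
        err = abs(contrib - t.total_weighted_decrease(n))
        worst_conservation = max(worst_conservation, err)
        if err > 1e-10:
            violations["conservation"] += 1
    return {
        "n_builds": n_builds,
        "violations": violations,
        "worst_conservation_error": worst_conservation,
    }


def oracle_equivalences(master_seed: int = 1) -> dict:
    """Dual-route agreement counts: exhaustive split vs brute-force scan,
    rank AUC vs trapezoidal ROC area, and B=1/IC=1 outer splits vs
    univariate threshold partitions."""
    from .tree_core import best_split_exhaustive, gini_impurity
    from .genotype_data import GenotypeDataset

    rng = np.random.default_rng(master_seed)

    split_agree = 0
    n_split = 1000
    for _ in range(n_split):
        k = int(rng.integers(2, 51))
        values = rng.choice(np.linspace(0, 3, 7), size=k)
        labels = rng.integers(0, 2, k)
        spec = best_split_exhaustive(values, labels)
        # brute force over midpoints
        uniq = np.unique(values)
        if uniq.size < 2:
            split_agree += spec is None
            continue
        n1 = labels.sum()
        i0 = gini_impurity((k - n1, n1))
        best = -1.0
        for a, b in zip(uniq[:-1], uniq[1:]):
            left = values <= (a + b) / 2
            nl, cl = int(left.sum()), int(labels[left].sum())
            d = (i0 - (nl / k) * gini_impurity((nl - cl, cl))
                 - ((k - nl) / k) * gini_impurity((k - nl - (n1 - cl),
                                                   n1 - cl)))
            best = max(best, d)
        split_agree += abs(spec.impurity_decrease - best) < 1e-12

    auc_agree = 0
    n_auc = 1000
    for _ in range(n_auc):
        m = int(rng.integers(4, 80))
        scores = rng.choice(np.linspace(0, 1, 9), size=m)
        labels = rng.integers(0, 2, m)
        labels[:2] = [0, 1]
        a1 = auc(scores, labels)
        # trapezoidal ROC area
        thr = np.r_[np.inf, np.unique(scores)[::-1]]
        P, N = (labels == 1).sum(), (labels == 0).sum()
        tpr = [0.0]
        fpr = [0.0]
        for t in thr:
            tpr.append(((scores >= t) & (labels == 1)).sum() / P)
            fpr.append(((scores >= t) & (labels == 0)).sum() / N)
        auc_agree += abs(a1 - np.trapezoid(tpr, fpr)) < 1e-12

    reduction_agree = 0
    n_red = 500
    for i in range(n_red):
        n = int(rng.integers(20, 80))
        X = rng.integers(0, 3, size=(n, 6)).astype(np.int8)
        y = rng.integers(0, 2, n).astype(np.uint8)
        data = GenotypeDataset(X, y, [f"s{j}" for j in range(6)])
        bm = make_block_map(6, 1)
        s = ttree.split_outer_node(
            np.arange(n), data, bm,
            ttree.TTreeParams(T=1, IC=1, k_internal=1, m_try_blocks=2),
            seed=int(rng.integers(2**31)),
        )
        if s is None:
            reduction_agree += 1  # no split either way
            continue
        mask = s.left_mask(X)
        g = X[:, s.block_index]
        ok = any(
            np.array_equal(mask, c) or np.array_equal(mask, ~c)
            for c in (g <= 0.5, g <= 1.5)
        )
        reduction_agree += ok

    return {
        "split_oracle_agree": split_agree, "split_oracle_total": n_split,
        "auc_oracle_agree": auc_agree, "auc_oracle_total": n_auc,
        "reduction_agree": reduction_agree, "reduction_total": n_red,
    }


def imputation_fidelity(master_seed: int = 1, n: int = 4000) -> dict:
    """Chi-square goodness of fit of imputed fills against the observed
    genotype distribution, pooled over SNPs (>= 10^4 imputed cells)."""
    sd = syn.simulate(syn.null_scenario(n=n, seed=master_seed,
                                        missing_rate=0.05))
    data = sd.data
    filled = impute_missing(data, seed=master_seed + 1)
    miss = data.genotypes == -1
    n_cells = int(miss.sum())
    # pool per-SNP observed frequencies into expected counts per genotype
    obs_fill = np.zeros(3)
    exp_fill = np.zeros(3)
    for j in range(data.n_snps):
        mj = miss[:, j]
        if not mj.any():
            continue
        observed_col = data.genotypes[~mj, j]
        freq = np.bincount(observed_col, minlength=3) / observed_col.size
        exp_fill += freq * mj.sum()
        obs_fill += np.bincount(filled.genotypes[mj, j], minlength=3)
    keep = exp_fill > 0
    stat, p = chisquare(obs_fill[keep], exp_fill[keep] *
                        obs_fill.sum() / exp_fill[keep].sum())
    return {"n_imputed_cells": n_cells, "chi2_stat": float(stat),
            "chi2_p": float(p)}
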