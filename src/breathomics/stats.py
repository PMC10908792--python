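"""Three-method significance machinery and the Venn consensus.

A group contrast is interrogated three ways — univariate volcano analysis
(Welch t-test with Benjamini-Hochberg FDR and a fold-change gate),
multivariate PLS-DA with VIP scoring, and random-forest classification
with out-of-bag permutation importance — and the three significant sets
are partitioned in a Venn diagram.  Features significant under all three
criteria form the robust consensus list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from .preprocess import FeatureTable, log_pareto


# ---------------------------------------------------------------- grouping

def group_vector(
    table: FeatureTable, groups: Mapping[str, str]
) -> pd.Series:
    """Align a sample_id -> group-label mapping with the table columns."""
    missing = [c for c in table.values.columns if c not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing[:5]}")
    g = pd.Series({c: groups[c] for c in table.values.columns})
    sizes = g.value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    return g


# ------------------------------------------------------------- fold change

def fold_change(
    table: FeatureTable,
    groups: Mapping[str, str],
    numerator: str,
    denominator: str,
) -> pd.Series:
    """Per-feature ratio of group means of raw (unlogged) intensities.

    The orientation (numerator/denominator) is carried in the Series name
    so downstream output is unambiguous.
    """
    g = group_vector(table, groups)
    num_cols = list(g.index[g == numerator])
    den_cols = list(g.index[g == denominator])
    if not num_cols or not den_cols:
        raise ValueError("numerator/denominator groups not found")
    num = table.values[num_cols].mean(axis=1)
    den = table.values[den_cols].mean(axis=1)
    if (den == 0).any():
        raise ValueError("zero denominator group mean (impute first)")
    fc = num / den
    fc.name = f"{numerator}/{denominator}"
    return fc


# ----------------------------------------------------------------- volcano

@dataclass
class VolcanoResult:
    """Per-feature fold change, Welch-t p, BH-adjusted p and the flag."""

    table: pd.DataFrame  # columns: log2_fc, p, p_adj, significant
    numerator: str
    denominator: str
    log2fc_min: float
    alpha: float

    @property
    def significant(self) -> Set[str]:
        return set(self.table.index[self.table["significant"]])


def volcano(
    table: FeatureTable,
    groups: Mapping[str, str],
    log2fc_min: float = 1.0,
    alpha: float = 0.1,
    two_sided_fc: bool = True,
    log_base: float = 10.0,
) -> VolcanoResult:
    """Two-group volcano analysis on a raw-intensity table.

    The test is a Welch t-test on log-transformed intensities (invariant
    to the Pareto scaling applied for the multivariate methods), adjusted
    by Benjamini-Hochberg; the fold change is the ratio of raw group
    means, second-listed group over first.  A feature is significant when
    the adjusted p-value is below ``alpha`` and |log2 FC| (or signed
    log2 FC when ``two_sided_fc=False``) is at least ``log2fc_min``.
    """
    g = group_vector(table, groups)
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError("volcano requires exactly two groups")
    denominator, numerator = labels[0], labels[1]
    fc = fold_change(table, groups, numerator, denominator)
    log2_fc = np.log2(fc)

    a = np.log(table.values[list(g.index[g == numerator])].to_numpy()) / np.log(log_base)
    b = np.log(table.values[list(g.index[g == denominator])].to_numpy()) / np.log(log_base)
    t, p = sstats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    p_adj = benjamini_hochberg(p)
    if two_sided_fc:
        fc_pass = np.abs(log2_fc) >= log2fc_min
    else:
        fc_pass = log2_fc >= log2fc_min
    sig = (p_adj < alpha) & fc_pass
    out = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": sig,
        },
        index=table.values.index,
    )
    return VolcanoResult(out, numerator, denominator, log2fc_min, alpha)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (via statsmodels)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------- ANOVA/Tukey

def anova_tukey(
    table: FeatureTable,
    groups: Mapping[str, str],
    alpha: float = 0.1,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """One-way ANOVA with Tukey HSD pairwise comparisons per feature.

    Works on log-transformed intensities.  The ANOVA p-values are
    BH-adjusted across features; a feature is significant when the
    adjusted ANOVA p and the smallest Tukey-adjusted pairwise p are both
    below ``alpha``.  The frame also reports which pair drove the effect.
    """
    g = group_vector(table, groups)
    labels = sorted(g.unique())
    cols_per = {lab: list(g.index[g == lab]) for lab in labels}
    for lab, cols in cols_per.items():
        if len(cols) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    logged = np.log(table.values.to_numpy()) / np.log(log_base)
    col_idx = {c: i for i, c in enumerate(table.values.columns)}
    blocks = {lab: [col_idx[c] for c in cols] for lab, cols in cols_per.items()}

    rows = []
    for i, fid in enumerate(table.values.index):
        arrs = [logged[i, blocks[lab]] for lab in labels]
        if all(np.allclose(a, arrs[0][0]) for a in arrs):
            rows.append((1.0, 1.0, ""))
            continue
        f, p_anova = sstats.f_oneway(*arrs)
        res = sstats.tukey_hsd(*arrs)
        pvals = res.pvalue
        best_p, best_pair = 1.0, ""
        for ai in range(len(labels)):
            for bi in range(ai + 1, len(labels)):
                if pvals[ai, bi] < best_p:
                    best_p = float(pvals[ai, bi])
                    best_pair = f"{labels[ai]} vs {labels[bi]}"
        rows.append((float(p_anova), best_p, best_pair))
    out = pd.DataFrame(
        rows, index=table.values.index, columns=["p_anova", "p_tukey_min", "best_pair"]
    )
    out["p_anova_adj"] = benjamini_hochberg(out["p_anova"].to_numpy())
    out["significant"] = (out["p_anova_adj"] < alpha) & (out["p_tukey_min"] < alpha)
    return out


# ------------------------------------------------------------------ PLS-DA

@dataclass
class PlsdaModel:
    """A fitted PLS-DA model with its quality metrics and VIP scores."""

    n_components: int
    r2y: float
    r2y_per_component: np.ndarray  # cumulative
    q2y: float
    vip: pd.Series
    scores: pd.DataFrame  # samples x components
    class_labels: Tuple[str, str]


def plsda_fit(
    X: pd.DataFrame,
    y: Sequence[str],
    n_components: int = 5,
    cv_folds: int = 10,
    seed: int = 0,
) -> PlsdaModel:
    """PLS-DA on a samples x features matrix against a binary class vector.

    Fits PLS regression (NIPALS deflation) of the centred 0/1 class
    indicator on X.  R2Y is the cumulative fraction of class variance
    explained; Q2Y is 1 - PRESS/TSS from seeded stratified cross-
    validation; VIP_j = sqrt(p * sum_a SSY_a w_aj^2 / sum_a SSY_a), so the
    mean of VIP^2 over features is exactly 1.
    """
    X = pd.DataFrame(X)
    labels = sorted(set(y))
    if len(labels) != 2:
        raise ValueError("plsda_fit requires exactly two classes")
    yv = np.array([1.0 if lab == labels[1] else 0.0 for lab in y])
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError("n_components exceeds the rank of X")

    model = PLSRegression(n_components=n_components, scale=False)
    model.fit(X.to_numpy(), yv.reshape(-1, 1))
    T = model.x_scores_  # orthogonal columns
    W = model.x_weights_  # unit columns
    Q = model.y_loadings_
    yc = yv - yv.mean()
    ssy_total = float(np.sum(yc**2))

    # per-component explained class variance (NIPALS components are orthogonal)
    ssy_a = (Q[0] ** 2) * np.sum(T**2, axis=0)
    r2y_cum = np.cumsum(ssy_a) / ssy_total

    vip = np.sqrt(p * (W**2 @ ssy_a) / ssy_a.sum())

    # cross-validated Q2Y
    press, tss = 0.0, 0.0
    cv_folds = max(2, min(cv_folds, int(np.bincount(yv.astype(int)).min())))
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, yv):
        ncomp = min(n_components, len(train) - 1, p)
        m = PLSRegression(n_components=ncomp, scale=False)
        m.fit(X.iloc[train].to_numpy(), yv[train].reshape(-1, 1))
        pred = m.predict(X.iloc[test].to_numpy()).ravel()
        press += float(np.sum((yv[test] - pred) ** 2))
        tss += float(np.sum((yv[test] - yv[train].mean()) ** 2))
    q2y = 1.0 - press / tss

    return PlsdaModel(
        n_components=n_components,
        r2y=float(r2y_cum[-1]),
        r2y_per_component=r2y_cum,
        q2y=float(q2y),
        vip=pd.Series(vip, index=X.columns, name="VIP"),
        scores=pd.DataFrame(
            T, index=X.index, columns=[f"comp{a + 1}" for a in range(n_components)]
        ),
        class_labels=(labels[0], labels[1]),
    )


# ------------------------------------------------------------ random forest

def mtry_rule(n_features: int) -> int:
    """Number of candidate predictors per split: nearest integer to the
    square root of the feature count."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return max(1, int(math.floor(math.sqrt(n_features) + 0.5)))


@dataclass
class RandomForestResult:
    """OOB-evaluated bootstrap tree ensemble."""

    n_trees: int
    n_predictors: int
    oob_error: float
    per_class_error: Dict[str, float]
    confusion: pd.DataFrame
    importance: pd.Series  # mean decrease in OOB accuracy
    class_labels: List[str]


def rf_classify(
    X: pd.DataFrame,
    y: Sequence[str],
    n_trees: int = 500,
    n_predictors: Optional[int] = None,
    seed: int = 0,
    max_trees: int = 1000,
) -> RandomForestResult:
    """Random-forest classification with OOB error and permutation MDA.

    The bagging loop is explicit (CART trees from scikit-learn, bootstrap
    the size of the sample set, ``n_predictors`` candidate features per
    split) so that out-of-bag votes are available per tree: the OOB error
    is the misclassification rate of the majority OOB vote, and the mean
    decrease in accuracy of feature j is the average over trees of the
    drop in that tree's OOB accuracy when column j is permuted.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    labels = sorted(set(y.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    n_trees = min(n_trees, max_trees)
    n, p = X.shape
    if n_predictors is None:
        n_predictors = mtry_rule(p)
    rng = np.random.default_rng(seed)
    Xa = X.to_numpy()
    y_codes = np.searchsorted(labels, y)

    votes = np.zeros((n, len(labels)))
    mda = np.zeros(p)
    oob_counts = np.zeros(p)  # trees contributing to feature j's MDA
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeClassifier(
            max_features=n_predictors,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(Xa[boot], y_codes[boot])
        if oob.size == 0:
            continue
        pred = tree.predict(Xa[oob])
        np.add.at(votes, (oob, pred), 1.0)
        acc = float(np.mean(pred == y_codes[oob]))
        Xoob = Xa[oob]
        perm = rng.permutation(oob.size)
        for j in range(p):
            saved = Xoob[:, j].copy()
            Xoob[:, j] = saved[perm]
            acc_perm = float(np.mean(tree.predict(Xoob) == y_codes[oob]))
            Xoob[:, j] = saved
            mda[j] += acc - acc_perm
            oob_counts[j] += 1

    voted = votes.sum(axis=1) > 0
    oob_pred = votes.argmax(axis=1)
    oob_error = float(np.mean(oob_pred[voted] != y_codes[voted]))
    confusion = pd.DataFrame(
        0, index=labels, columns=labels, dtype=int
    )
    for true_c, pred_c in zip(y_codes[voted], oob_pred[voted]):
        confusion.iloc[true_c, pred_c] += 1
    per_class_error = {}
    for ci, lab in enumerate(labels):
        row = confusion.iloc[ci]
        total = int(row.sum())
        per_class_error[lab] = (
            float((total - row.iloc[ci]) / total) if total else float("nan")
        )
    mda = np.divide(mda, oob_counts, out=np.zeros(p), where=oob_counts > 0)
    return RandomForestResult(
        n_trees=n_trees,
        n_predictors=n_predictors,
        oob_error=oob_error,
        per_class_error=per_class_error,
        confusion=confusion,
        importance=pd.Series(mda, index=X.columns, name="mean_decrease_accuracy"),
        class_labels=labels,
    )


# ------------------------------------------------------------ Venn/consensus

def venn_partition(
    set_a: Set[str], set_b: Set[str], set_c: Set[str]
) -> Dict[str, int]:
    """Counts of the 7 regions of a three-set Venn diagram."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    return {
        "A_only": len(a - b - c),
        "B_only": len(b - a - c),
        "C_only": len(c - a - b),
        "AB_only": len((a & b) - c),
        "AC_only": len((a & c) - b),
        "BC_only": len((b & c) - a),
        "ABC": len(a & b & c),
    }


@dataclass
class ConsensusThresholds:
    """Selection criteria for the three significant sets."""

    vip: float = 1.5
    mda: float = 0.00016
    alpha: float = 0.1
    log2fc_min: float = 1.0


@dataclass
class ConsensusResult:
    """The three significant sets, their Venn partition, and the ranked
    intersection (the robust consensus metabolites)."""

    volcano: VolcanoResult
    plsda: PlsdaModel
    rf: RandomForestResult
    sets: Dict[str, Set[str]]
    venn: Dict[str, int]
    consensus: pd.DataFrame  # ABC features ranked by adjusted p


def consensus(
    table: FeatureTable,
    groups: Mapping[str, str],
    thresholds: Optional[ConsensusThresholds] = None,
    n_components: int = 5,
    n_trees: int = 500,
    n_predictors: Optional[int] = None,
    seed: int = 0,
) -> ConsensusResult:
    """Run volcano, PLS-DA+VIP and random forest on one binary contrast.

    ``table`` must be the analysis-ready raw-intensity table (imputed and
    median-normalized); the multivariate methods work on its log/Pareto
    transform internally.  Venn sets: A = volcano, B = PLS-DA VIP,
    C = random forest MDA.
    """
    th = thresholds or ConsensusThresholds()
    volc = volcano(
        table, groups, log2fc_min=th.log2fc_min, alpha=th.alpha
    )
    scaled = log_pareto(table)
    Xs = scaled.values.T  # samples x features
    g = group_vector(table, groups)
    yv = [g[c] for c in Xs.index]
    ncomp = min(n_components, Xs.shape[0] - 2, Xs.shape[1])
    pls = plsda_fit(Xs, yv, n_components=ncomp, seed=seed)
    rf = rf_classify(
        Xs, yv, n_trees=n_trees, n_predictors=n_predictors, seed=seed
    )
    sets = {
        "volcano": volc.significant,
        "vip": set(pls.vip.index[pls.vip > th.vip]),
        "rf": set(rf.importance.index[rf.importance > th.mda]),
    }
    venn = venn_partition(sets["volcano"], sets["vip"], sets["rf"])
    abc = sorted(sets["volcano"] & sets["vip"] & sets["rf"])
    cons = volc.table.loc[abc, ["log2_fc", "p", "p_adj"]].copy()
    cons["vip"] = pls.vip.loc[abc]
    cons["mda"] = rf.importance.loc[abc]
    cons = cons.sort_values("p_adj")
    return ConsensusResult(
        volcano=volc, plsda=pls, rf=rf, sets=sets, venn=venn, consensus=cons
    )
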