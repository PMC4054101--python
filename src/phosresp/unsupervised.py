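"""Unsupervised sample classification and differential phosphorylation.

Samples are classified two ways: principal component analysis of the
log-transformed, peptide-mean-centered relative intensities, and
agglomerative hierarchical clustering with complete linkage on a
rank-correlation distance, d(i, j) = 1 - tau_b(sample_i, sample_j).
The tie-corrected tau_b variant is used because relative-intensity data
contain ties after imputation. Note 1 - tau is not a metric; only symmetry
and d(i, i) = 0 are guaranteed, with d in [0, 2].

Differentially phosphorylated peptides are flagged per disease group either
by one-way ANOVA with Bonferroni correction across peptides plus Tukey HSD
pairwise tests (the stringent default: corrected ANOVA and Tukey p below the
threshold and group fold over the mean of the remaining samples above the
fold threshold), or by a group-vs-rest Welch t-test with Benjamini-Hochberg
correction. Tests run on log2 relative intensities; folds are computed on
the linear relative scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

from .io import SampleMeta
from .preprocess import NormalizedMatrix

__all__ = [
    "PcaResult",
    "ClusterTree",
    "DifferentialResult",
    "pca_scores",
    "kendall_distance_matrix",
    "complete_linkage_cluster",
    "differential_filter",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # peptides x components
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_scores(logm: NormalizedMatrix, n_components: int = 2) -> PcaResult:
    """PCA of the peptide-mean-centered matrix via singular value decomposition.

    Each peptide is mean-centered across samples before decomposition.
    The sign convention scales each component so that its largest-magnitude
    loading entry is positive, making results deterministic.
    """
    df = logm.data
    n_samples, n_peptides = df.shape[1], df.shape[0]
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    max_rank = min(n_samples, n_peptides)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds min(dims)={max_rank}")
    x = df.to_numpy(dtype=float).T  # samples x peptides
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic orientation: largest-|loading| entry positive per component
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    total = float((s**2).sum())
    evf = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    cols = [f"PC{k + 1}" for k in range(n_components)]
    scores = pd.DataFrame((u[:, :n_components] * s[:n_components]), index=df.columns, columns=cols)
    loadings = pd.DataFrame(vt[:n_components].T, index=df.index, columns=cols)
    return PcaResult(scores=scores, loadings=loadings, explained_variance_fraction=evf)


# ---------------------------------------------------------------------------
# Rank-correlation distances and complete-linkage clustering
# ---------------------------------------------------------------------------


def kendall_distance_matrix(logm: NormalizedMatrix) -> pd.DataFrame:
    """Pairwise sample distances d(i, j) = 1 - tau_b over all peptides."""
    df = logm.data
    values = df.to_numpy(dtype=float)
    n = values.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    for j in range(n):
        if np.all(values[:, j] == values[0, j]):
            raise ValueError(
                f"sample {df.columns[j]!r} is constant across peptides; tau is undefined"
            )
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tau = stats.kendalltau(values[:, i], values[:, j], variant="b").statistic
            d[i, j] = d[j, i] = 1.0 - tau
    return pd.DataFrame(d, index=df.columns, columns=df.columns)


@dataclass(frozen=True)
class ClusterTree:
    """Binary merge tree over samples with complete-linkage merge heights.

    ``linkage`` follows the scipy convention: row k merges cluster ids
    Z[k,0] and Z[k,1] at height Z[k,2] into new cluster ``n_leaves + k``.
    """

    labels: tuple[str, ...]
    linkage: np.ndarray

    def leaf_sets(self) -> list[frozenset[str]]:
        """Leaf-label set of every internal node, in merge order."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for k, (a, b, _, _) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            out.append(merged)
        return out

    def is_pure_subtree(self, samples: set[str] | frozenset[str]) -> bool:
        """True iff ``samples`` is exactly the leaf set of some node."""
        target = frozenset(samples)
        if len(target) == 1:
            return target <= set(self.labels)
        return target in set(self.leaf_sets())

    def to_newick(self) -> str:
        n = len(self.labels)

        def render(node: int) -> tuple[str, float]:
            if node < n:
                return self.labels[node], 0.0
            a, b, height, _ = self.linkage[node - n]
            sa, ha = render(int(a))
            sb, hb = render(int(b))
            # branch lengths from node height to child heights
            return f"({sa}:{height - ha:.6g},{sb}:{height - hb:.6g})", float(height)

        body, _ = render(2 * n - 2)
        return body + ";"


def complete_linkage_cluster(d: pd.DataFrame) -> ClusterTree:
    """Complete-linkage agglomeration of a sample distance matrix.

    Ties on the minimum inter-cluster distance are broken by merging the
    pair whose (lexicographically smallest member label, then the other
    cluster's smallest label) sorts first, so the tree is deterministic.
    """
    values = d.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("distance matrix contains NaN")
    if values.shape[0] != values.shape[1] or list(d.index) != list(d.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(values, values.T):
        raise ValueError("distance matrix must be symmetric")
    labels = tuple(str(c) for c in d.columns)
    n = len(labels)
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    rep: dict[int, str] = {i: labels[i] for i in range(n)}  # smallest member label
    dist: dict[tuple[int, int], float] = {
        (i, j): float(values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    linkage = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], *sorted((rep[kv[0][0]], rep[kv[0][1]]))),
        )
        (a, b), height = best
        new_id = n + step
        size = active[a] + active[b]
        linkage[step] = [a, b, height, size]
        for c in list(active):
            if c in (a, b):
                continue
            da = dist.pop((min(a, c), max(a, c)))
            db = dist.pop((min(b, c), max(b, c)))
            dist[(min(new_id, c), max(new_id, c))] = max(da, db)
        del dist[(a, b)]
        del active[a], active[b]
        active[new_id] = size
        rep[new_id] = min(rep[a], rep[b])
    return ClusterTree(labels=labels, linkage=linkage)


# ---------------------------------------------------------------------------
# Differential phosphorylation
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _sr_critical(k: int, df: int, alpha: float) -> float:
    """Exact studentized-range critical value q such that sf(q; k, df) = alpha."""
    return float(studentized_range.ppf(1.0 - alpha, k, df))


@lru_cache(maxsize=32)
def _sr_sf_table(k: int, df: int) -> tuple[np.ndarray, np.ndarray]:
    q = np.linspace(0.0, 25.0, 251)
    return q, studentized_range.sf(q, k, df)


def _sr_sf(q: np.ndarray, k: int, df: int) -> np.ndarray:
    """Studentized-range survival function, interpolated from a cached grid.

    Reported Tukey p-values come from this table (absolute accuracy ~1e-4);
    pass/fail decisions never use it — they compare the q statistic against
    the exact critical value from :func:`_sr_critical`.
    """
    qs, sf = _sr_sf_table(k, df)
    return np.interp(q, qs, sf)


@dataclass(frozen=True)
class DifferentialResult:
    """Per (peptide, disease group) differential statistics.

    ``table`` columns: peptide_id, group, group_mean, rest_mean, fold
    (group mean over mean of all other samples, reciprocal for decreased),
    direction, anova_p, anova_p_bonf, tukey_p_max (largest pairwise Tukey p
    involving the group; NaN in t-test mode), ttest_p / ttest_p_bh (NaN in
    ANOVA mode), passed.
    """

    table: pd.DataFrame
    mode: str
    p_threshold: float
    fold_threshold: float

    def passing(self, group: str | None = None) -> pd.DataFrame:
        sub = self.table[self.table["passed"]]
        if group is not None:
            sub = sub[sub["group"] == group]
        return sub

    def pass_counts(self) -> pd.Series:
        return self.table[self.table["passed"]].groupby("group").size()


def differential_filter(
    normm: NormalizedMatrix,
    meta: SampleMeta,
    mode: str = "anova_tukey",
    p_threshold: float | None = None,
    fold_threshold: float = 2.0,
) -> DifferentialResult:
    """Flag peptides differentially phosphorylated between disease groups.

    ``anova_tukey`` (default): pass requires Bonferroni-corrected ANOVA p and
    every pairwise Tukey p involving the group below ``p_threshold``
    (default 0.01) and fold above ``fold_threshold``. ``ttest_fdr``: pass
    requires Benjamini-Hochberg-corrected group-vs-rest Welch t-test p below
    ``p_threshold`` (default 0.05) and fold above ``fold_threshold``.
    """
    if mode not in ("anova_tukey", "ttest_fdr"):
        raise ValueError(f"unknown mode {mode!r}")
    if p_threshold is None:
        p_threshold = 0.01 if mode == "anova_tukey" else 0.05
    if normm.is_log:
        raise ValueError("differential_filter expects linear relative intensities")
    groups = meta.disease_groups()
    groups = {g: [s for s in samples if s in normm.data.columns] for g, samples in groups.items()}
    groups = {g: s for g, s in groups.items() if s}
    if len(groups) < 2:
        raise ValueError("need at least 2 disease groups")
    for g, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    group_names = sorted(groups)
    values = normm.data  # linear relative intensities
    log_values = np.log2(values.to_numpy(dtype=float, copy=True).clip(min=np.finfo(float).tiny))
    col_idx = {s: k for k, s in enumerate(values.columns)}
    group_cols = {g: [col_idx[s] for s in samples] for g, samples in groups.items()}
    n_pep = values.shape[0]

    log_groups = [log_values[:, group_cols[g]] for g in group_names]
    with np.errstate(invalid="ignore", divide="ignore"):
        anova = stats.f_oneway(*log_groups, axis=1)
    anova_p = np.where(np.isfinite(anova.pvalue), anova.pvalue, 1.0)
    anova_p_bonf = np.minimum(anova_p * n_pep, 1.0)

    rows: list[dict] = []
    kg = len(group_names)
    if mode == "anova_tukey":
        # Tukey-Kramer pairwise tests, vectorized over peptides
        ns = np.array([len(group_cols[g]) for g in group_names])
        df_err = int(ns.sum() - kg)
        if df_err < 1:
            raise ValueError("not enough samples for Tukey HSD")
        gmeans_log = np.column_stack([lg.mean(axis=1) for lg in log_groups])
        ss_within = sum(
            ((lg - lg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for lg in log_groups
        )
        mse = ss_within / df_err
        q_crit = _sr_critical(kg, df_err, p_threshold)
        tukey_p = np.zeros((n_pep, kg))  # max pairwise p involving the group
        tukey_ok = np.ones((n_pep, kg), dtype=bool)  # all pairs beyond the critical value
        for gi in range(kg):
            for gj in range(gi + 1, kg):
                denom = np.sqrt(mse / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
                gap = np.abs(gmeans_log[:, gi] - gmeans_log[:, gj])
                with np.errstate(divide="ignore", invalid="ignore"):
                    q = np.where(denom > 0, gap / denom, np.where(gap > 0, np.inf, 0.0))
                p = _sr_sf(np.minimum(q, 25.0), kg, df_err)
                p[np.isinf(q)] = 0.0
                p[q == 0] = 1.0
                for g in (gi, gj):
                    tukey_p[:, g] = np.maximum(tukey_p[:, g], p)
                    tukey_ok[:, g] &= q > q_crit
    else:
        ttest_p = np.ones((n_pep, len(group_names)))
        for gi, g in enumerate(group_names):
            cols = group_cols[g]
            rest = [c for c in range(values.shape[1]) if c not in cols]
            with np.errstate(invalid="ignore", divide="ignore"):
                t = stats.ttest_ind(
                    log_values[:, cols], log_values[:, rest], axis=1, equal_var=False
                )
            ttest_p[:, gi] = np.where(np.isfinite(t.pvalue), t.pvalue, 1.0)
        ttest_p_bh = np.column_stack(
            [stats.false_discovery_control(ttest_p[:, gi]) for gi in range(len(group_names))]
        )

    all_cols = np.arange(values.shape[1])
    vals = values.to_numpy(dtype=float)
    for gi, g in enumerate(group_names):
        cols = group_cols[g]
        rest = np.setdiff1d(all_cols, cols)
        gmean = vals[:, cols].mean(axis=1)
        rmean = vals[:, rest].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw_fold = gmean / rmean
        increased = raw_fold >= 1.0
        fold_stat = np.where(increased, raw_fold, 1.0 / raw_fold)
        for i in range(n_pep):
            row = {
                "peptide_id": values.index[i],
                "group": g,
                "group_mean": float(gmean[i]),
                "rest_mean": float(rmean[i]),
                "fold": float(fold_stat[i]),
                "direction": "increased" if increased[i] else "decreased",
                "anova_p": float(anova_p[i]),
                "anova_p_bonf": float(anova_p_bonf[i]),
                "tukey_p_max": np.nan,
                "ttest_p": np.nan,
                "ttest_p_bh": np.nan,
            }
            if mode == "anova_tukey":
                row["tukey_p_max"] = float(tukey_p[i, gi])
                row["passed"] = bool(
                    anova_p_bonf[i] < p_threshold
                    and tukey_ok[i, gi]
                    and fold_stat[i] > fold_threshold
                )
            else:
                row["ttest_p"] = float(ttest_p[i, gi])
                row["ttest_p_bh"] = float(ttest_p_bh[i, gi])
                row["passed"] = bool(
                    ttest_p_bh[i, gi] < p_threshold and fold_stat[i] > fold_threshold
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    return DifferentialResult(
        table=table, mode=mode, p_threshold=p_threshold, fold_threshold=fold_threshold
    )
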