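"""Compositional statistics for microbiome count tables.

Sequencing counts carry no information about absolute scale, so all
inference here is on log-ratios: reference-frame log-ratios (e.g. gene of
interest over the rpoA housekeeping gene), the centred log-ratio (CLR)
transform and the Aitchison distance built on it, a robust-CLR ordination
that treats zeros as missing, and permutation PERMANOVA on distance
matrices. Feature-length normalisation (reads per kilobase, RPK) and
reaction/pathway aggregation operate upstream of the log-ratio machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, tukey_hsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureTable",
    "LogRatioSeries",
    "PermanovaResult",
    "OrdinationResult",
    "rpk_normalize",
    "log_ratio",
    "wilcoxon_rank_sum",
    "group_test",
    "clr",
    "aitchison_distance",
    "rclr",
    "ordinate",
    "permanova",
    "pathway_aggregate",
]


@dataclass(frozen=True)
class FeatureTable:
    """Samples x features counts with annotations and sample metadata.

    ``counts`` rows are samples, columns are features. ``feature_meta`` is
    indexed by feature (taxonomy columns, gene symbol, pathway, length_bp);
    ``sample_meta`` by sample (group labels).
    """

    counts: pd.DataFrame
    feature_meta: pd.DataFrame | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.feature_meta is not None and not self.counts.columns.equals(
            self.feature_meta.index
        ):
            raise ValueError("feature_meta index must match count columns")
        if self.sample_meta is not None and not self.counts.index.equals(
            self.sample_meta.index
        ):
            raise ValueError("sample_meta index must match count rows")

    def features_where(self, column: str, value) -> list[str]:
        """Feature ids whose annotation ``column`` equals ``value``."""
        if self.feature_meta is None:
            raise ValueError("table has no feature annotations")
        mask = self.feature_meta[column] == value
        return list(self.feature_meta.index[mask])


@dataclass(frozen=True)
class LogRatioSeries:
    """Per-sample ln(numerator aggregate / denominator aggregate)."""

    values: pd.Series
    numerator_set: tuple[str, ...]
    denominator_set: tuple[str, ...]
    excluded_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("log-ratio values must be finite")


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pseudo_F < 0:
            raise ValueError("pseudo-F must be >= 0")
        if not 1.0 / (self.n_permutations + 1) - 1e-12 <= self.p_value <= 1.0:
            raise ValueError("p-value outside attainable range")


@dataclass(frozen=True)
class OrdinationResult:
    samples: pd.DataFrame  # sample scores, one column per axis
    features: pd.DataFrame  # feature loadings
    proportion_explained: pd.Series

    def __post_init__(self) -> None:
        p = self.proportion_explained.to_numpy(dtype=float)
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("proportions explained must lie in [0, 1]")
        if np.any(np.diff(p) > 1e-12):
            raise ValueError("proportions explained must be non-increasing")


def rpk_normalize(table: FeatureTable, length_column: str = "length_bp") -> FeatureTable:
    """Reads per kilobase: divide each count by feature length / 1000."""
    if table.feature_meta is None or length_column not in table.feature_meta:
        raise ValueError(f"feature_meta must provide {length_column!r}")
    lengths = table.feature_meta[length_column].astype(float)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    return replace(table, counts=table.counts / (lengths / 1000.0))


def log_ratio(
    table: FeatureTable,
    numerator_set,
    denominator_set,
    pseudocount: float = 0.0,
    allow_overlap: bool = False,
) -> LogRatioSeries:
    """Per-sample ln(sum of numerator features / sum of denominator features).

    ``pseudocount`` is added to each count before aggregation. With
    pseudocount 0, samples with a zero aggregate on either side are excluded
    and reported in ``excluded_samples`` rather than dropped silently. The
    statistic is invariant to per-sample depth (exactly so at pseudocount 0).
    """
    num = list(numerator_set)
    den = list(denominator_set)
    if not num or not den:
        raise ValueError("numerator and denominator sets must be non-empty")
    if not allow_overlap and set(num) & set(den) and set(num) != set(den):
        raise ValueError("numerator and denominator sets overlap")
    counts = table.counts + pseudocount
    num_agg = counts[num].sum(axis=1)
    den_agg = counts[den].sum(axis=1)
    ok = (num_agg > 0) & (den_agg > 0)
    values = np.log(num_agg[ok] / den_agg[ok])
    return LogRatioSeries(
        values=values,
        numerator_set=tuple(num),
        denominator_set=tuple(den),
        excluded_samples=tuple(table.counts.index[~ok]),
    )


def wilcoxon_rank_sum(x, y, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact null distribution when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie correction. Two degenerate identical samples
    (all values tied) return p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_max_n and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_test(
    values,
    groups,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests across groups.

    ``values`` is a :class:`LogRatioSeries` or a numeric series aligned with
    ``groups``. Multiplicity adjustment across group pairs defaults to
    Benjamini-Hochberg; ``adjust="tukey-hsd"`` substitutes scipy's
    parametric Tukey HSD p-values (offered because the published pairing of
    a rank-sum test with an HSD post hoc is ambiguous), ``adjust=None``
    reports raw p-values.
    """
    if isinstance(values, LogRatioSeries):
        values = values.values
    values = pd.Series(values)
    groups = pd.Series(groups)
    groups = groups.loc[values.index] if groups.index.equals(values.index) else groups
    labels = sorted(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    by_label = {lab: values[np.asarray(groups) == lab].to_numpy() for lab in labels}
    for lab, vals in by_label.items():
        if vals.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
    rows = []
    for a, b in itertools.combinations(labels, 2):
        stat, p = wilcoxon_rank_sum(by_label[a], by_label[b])
        rows.append({"group1": a, "group2": b, "statistic": stat, "p_value": p})
    out = pd.DataFrame(rows)
    if adjust is None:
        out["p_adjusted"] = out["p_value"]
    elif adjust == "tukey-hsd":
        res = tukey_hsd(*[by_label[lab] for lab in labels])
        out["p_adjusted"] = [
            float(res.pvalue[labels.index(a), labels.index(b)])
            for a, b in itertools.combinations(labels, 2)
        ]
    else:
        out["p_adjusted"] = multipletests(out["p_value"], method=adjust)[1]
    return out


def clr(compositions: np.ndarray) -> np.ndarray:
    """Centred log-ratio transform of strictly positive rows."""
    comp = np.asarray(compositions, dtype=float)
    if np.any(comp <= 0):
        raise ValueError("CLR requires strictly positive entries")
    logc = np.log(comp)
    return logc - logc.mean(axis=1, keepdims=True)


def aitchison_distance(table: FeatureTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Euclidean distance between CLR-transformed samples.

    ``pseudocount`` (default 1) is added to every count first; pass 0 only
    for all-positive tables. Scale- and perturbation-invariant in the
    Aitchison geometry.
    """
    counts = table.counts.to_numpy(dtype=float) + pseudocount
    if np.any(counts <= 0):
        raise ValueError("zeros present: use a positive pseudocount")
    mat = squareform(pdist(clr(counts), metric="euclidean"))
    return pd.DataFrame(mat, index=table.counts.index, columns=table.counts.index)


def rclr(counts: np.ndarray) -> np.ndarray:
    """Robust CLR: log of nonzero entries centred per sample over observed
    features; zeros become NaN (treated as missing, not as small values)."""
    counts = np.asarray(counts, dtype=float)
    logc = np.full(counts.shape, np.nan)
    np.log(counts, out=logc, where=counts > 0)
    row_mean = np.nanmean(logc, axis=1, keepdims=True)
    return logc - row_mean


def ordinate(
    table: FeatureTable,
    rank: int = 2,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> OrdinationResult:
    """Compositional ordination: rclr transform, iterative low-rank
    completion of the missing (zero) cells, truncated SVD.

    With a zero-free table the completion is a no-op and the result is
    ordinary CLR-PCA. Deterministic; axis signs are fixed by making the
    largest-magnitude feature loading on each axis positive.
    """
    n, p = table.counts.shape
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank >= min(n, p):
        raise ValueError(f"rank must be < min(n_samples, n_features) = {min(n, p)}")
    X = rclr(table.counts.to_numpy())
    # centre per observed feature as well, so dense tables reduce to
    # double-centred CLR
    X = X - np.nanmean(X, axis=0, keepdims=True)
    missing = np.isnan(X)
    filled = np.where(missing, 0.0, X)
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(filled, full_matrices=False)
        approx = (U[:, :rank] * s[:rank]) @ Vt[:rank]
        new = np.where(missing, approx, X)
        if np.max(np.abs(new - filled)) < tol:
            filled = new
            break
        filled = new
    U, s, Vt = np.linalg.svd(filled, full_matrices=False)
    signs = np.sign(Vt[np.arange(rank), np.argmax(np.abs(Vt[:rank]), axis=1)])
    signs[signs == 0] = 1.0
    axes = [f"PC{i + 1}" for i in range(rank)]
    scores = pd.DataFrame(
        U[:, :rank] * s[:rank] * signs, index=table.counts.index, columns=axes
    )
    loadings = pd.DataFrame(
        Vt[:rank].T * signs, index=table.counts.columns, columns=axes
    )
    var = s**2
    prop = pd.Series(var[:rank] / var.sum() if var.sum() > 0 else 0.0, index=axes)
    return OrdinationResult(samples=scores, features=loadings, proportion_explained=prop)


def _pseudo_f(d2: np.ndarray, masks: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Vectorised PERMANOVA pseudo-F for one or many group labellings.

    ``d2`` is the squared distance matrix; ``masks`` is (B, k, n) boolean
    group membership; ``sizes`` is (k,) group sizes.
    """
    n = d2.shape[0]
    k = sizes.size
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    m = masks.astype(float)
    # within-group sum of squared distances: 0.5 * m G m^T per group
    within = np.einsum("bgi,ij,bgj->bg", m, d2, m) / 2.0
    ss_within = (within / sizes).sum(axis=1)
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    dist_matrix: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F compares among-group to within-group sums of squared
    distances; the p-value is the one-sided exceedance probability of the
    observed F under label permutation, with the +1 correction
    ``p = (1 + #{F_perm >= F_obs}) / (n_permutations + 1)``. With
    ``exhaustive=True`` all distinct label arrangements are enumerated and
    the p-value is the exact fraction (the observed labelling included).
    """
    d = np.asarray(
        dist_matrix.to_numpy() if isinstance(dist_matrix, pd.DataFrame) else dist_matrix,
        dtype=float,
    )
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    groups = np.asarray(groups)
    if groups.size != n:
        raise ValueError("groups length must match distance matrix")
    labels, inverse = np.unique(groups, return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(inverse).astype(float)
    d2 = d**2

    def masks_for(assignments: np.ndarray) -> np.ndarray:
        # assignments: (B, n) integer labels -> (B, k, n) boolean
        return np.stack([assignments == g for g in range(labels.size)], axis=1)

    f_obs = float(_pseudo_f(d2, masks_for(inverse[None, :]), sizes)[0])

    if exhaustive:
        perms = np.array(sorted(set(itertools.permutations(inverse))), dtype=int)
        f_all = _pseudo_f(d2, masks_for(perms), sizes)
        p = float(np.mean(f_all >= f_obs - 1e-12))
        n_perm = perms.shape[0] - 1
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(inverse) for _ in range(n_permutations)])
        f_perm = _pseudo_f(d2, masks_for(perms), sizes)
        p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (n_permutations + 1.0)
        n_perm = n_permutations
    return PermanovaResult(
        pseudo_F=f_obs, p_value=float(p), n_permutations=n_perm, seed=seed
    )


def pathway_aggregate(
    expression: FeatureTable | pd.DataFrame,
    pathway_map: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate gene-level values to pathway x sample.

    ``pathway_map`` has columns ``feature``, ``reaction``, ``pathway``.
    Multi-copy genes mapping to one reaction are resolved by taking the
    maximum (the most abundant/most highly expressed copy); a pathway's
    value is the mean over its reactions.
    """
    values = expression.counts if isinstance(expression, FeatureTable) else expression
    required = {"feature", "reaction", "pathway"}
    if not required <= set(pathway_map.columns):
        raise ValueError(f"pathway_map needs columns {sorted(required)}")
    missing = set(pathway_map["feature"]) - set(values.columns)
    if missing:
        raise ValueError(f"pathway_map features absent from table: {sorted(missing)}")
    long = values[pathway_map["feature"]].T
    long.index = pd.MultiIndex.from_frame(pathway_map[["pathway", "reaction"]])
    per_reaction = long.groupby(level=["pathway", "reaction"]).max()
    per_pathway = per_reaction.groupby(level="pathway").mean()
    per_pathway.index.name = "pathway"
    return per_pathway
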