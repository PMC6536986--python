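"""Technical-reproducibility battery for the replicate design.

Given 6 technical replicates per biological case (2 labs x 3 days), this
module provides: distribution-based outlier flagging, pairwise Pearson
correlation, pooled between-lab correlation, intra-/inter-assay precision
(%CV), PCA, correlation-distance hierarchical clustering, and a per-gene
balanced two-way ANOVA comparing case mean squares against residual mean
squares (the "is biology above system noise" diagnostic: for each gene one
point MS_case vs MS_residual; under the no-biology null the F ratio is
central, so about P(F > 1) of genes land above the diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .panel_io import ExpressionMatrix, SampleTable, Scale

__all__ = [
    "flag_distribution_outliers",
    "pairwise_pearson",
    "between_group_scatter_r",
    "PrecisionReport",
    "precision_report",
    "pca_scores",
    "hierarchical_cluster",
    "AnovaResult",
    "anova_ms",
]


def flag_distribution_outliers(m: ExpressionMatrix, k: float = 3.0) -> list[str]:
    """Samples whose median expression falls outside the k*IQR fence.

    The fence is [Q1 - k*IQR, Q3 + k*IQR] of the per-sample medians — an
    operational version of "notably different boxplot distribution".
    """
    if m.values.shape[1] < 4:
        raise ValueError("need >= 4 samples to define an IQR fence")
    medians = m.values.median(axis=0)
    q1, q3 = medians.quantile(0.25), medians.quantile(0.75)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return medians.index[(medians < lo) | (medians > hi)].tolist()


def pairwise_pearson(
    m: ExpressionMatrix, sample_subset: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix of per-sample gene vectors."""
    values = m.values if sample_subset is None else m.subset_samples(sample_subset).values
    if values.shape[1] < 2 or values.shape[0] < 3:
        raise ValueError("need >= 2 samples and >= 3 genes")
    arr = values.to_numpy()
    if (arr.std(axis=0) == 0).any():
        bad = values.columns[arr.std(axis=0) == 0].tolist()
        raise ValueError(f"zero-variance sample vector(s): {bad}")
    corr = np.corrcoef(arr, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=values.columns, columns=values.columns)


def between_group_scatter_r(
    m_group_a: ExpressionMatrix,
    m_group_b: ExpressionMatrix,
    pairing: dict[str, str],
) -> float:
    """Pooled Pearson r over all (gene, pair) values of paired samples.

    ``pairing`` maps a sample in group A to its counterpart in group B (same
    case and day, other lab).  All pairs are pooled into two long vectors.
    """
    if not pairing:
        raise ValueError("empty pairing")
    missing_a = [s for s in pairing if s not in m_group_a.values.columns]
    missing_b = [s for s in pairing.values() if s not in m_group_b.values.columns]
    if missing_a or missing_b:
        raise ValueError(f"unpaired sample(s): {missing_a + missing_b}")
    xs = np.concatenate([m_group_a.values[a].to_numpy() for a in pairing])
    ys = np.concatenate([m_group_b.values[b].to_numpy() for b in pairing.values()])
    return float(np.corrcoef(xs, ys)[0, 1])


# ---------------------------------------------------------------------------
# Precision
# ---------------------------------------------------------------------------

@dataclass
class PrecisionReport:
    """Intra-/inter-assay %CV summaries against the acceptance thresholds."""

    intra_cv: pd.DataFrame          # genes x (case, lab) groups, %CV over days
    inter_cv: pd.DataFrame          # genes x cases, %CV over all replicates
    median_intra_cv: float
    median_inter_cv: float
    pass_intra: bool
    pass_inter: bool
    replicate_r2_min: float
    n_undefined: int                # gene/group cells with zero mean, excluded

    def summary(self) -> dict:
        return {
            "median_intra_cv_pct": self.median_intra_cv,
            "median_inter_cv_pct": self.median_inter_cv,
            "pass_intra": self.pass_intra,
            "pass_inter": self.pass_inter,
            "replicate_r2_min": self.replicate_r2_min,
            "n_undefined": self.n_undefined,
        }


def _group_cv(values: pd.DataFrame, groups: dict) -> tuple[pd.DataFrame, int]:
    """%CV per gene per group; groups map label -> sample id list."""
    out = {}
    n_undefined = 0
    for label, samples in groups.items():
        block = values[samples].to_numpy()
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        cv = np.full(len(mean), np.nan)
        ok = mean != 0
        n_undefined += int((~ok).sum())
        cv[ok] = 100.0 * sd[ok] / mean[ok]
        out[label] = cv
    frame = pd.DataFrame(out, index=values.index)
    return frame, n_undefined


def precision_report(
    m: ExpressionMatrix,
    meta: SampleTable,
    intra_threshold: float = 10.0,
    inter_threshold: float = 15.0,
) -> PrecisionReport:
    """Per-gene %CV within (case, lab) over days and within case over all
    replicates, on the normalized (linear) scale."""
    if m.scale != Scale.NORMALIZED:
        raise ValueError("precision is computed on the normalized (linear) scale")
    table = meta.table[meta.table["sample_id"].isin(m.values.columns)]
    intra_groups = {}
    for (case, lab), grp in table.groupby(["case_id", "lab"]):
        if len(grp) >= 2:
            intra_groups[f"{case}|{lab}"] = grp["sample_id"].tolist()
    inter_groups = {}
    for case, grp in table.groupby("case_id"):
        if len(grp) >= 2:
            inter_groups[case] = grp["sample_id"].tolist()
    if not intra_groups or not inter_groups:
        raise ValueError("need >= 2 replicates per grouping")

    intra, n_undef_a = _group_cv(m.values, intra_groups)
    inter, n_undef_b = _group_cv(m.values, inter_groups)
    median_intra = float(np.nanmedian(intra.to_numpy()))
    median_inter = float(np.nanmedian(inter.to_numpy()))

    # minimum pairwise replicate r^2 (log2 scale) over within-case pairs;
    # undefined (kept at 1) when fewer than 2 genes are present
    log_values = np.log2(m.values + 1.0)
    r2_min = 1.0
    if len(log_values) >= 2:
        for samples in inter_groups.values():
            arr = log_values[samples].to_numpy()
            corr = np.corrcoef(arr, rowvar=False)
            off = corr[np.triu_indices_from(corr, k=1)]
            if len(off):
                r2_min = min(r2_min, float(np.min(off ** 2)))

    return PrecisionReport(
        intra_cv=intra, inter_cv=inter,
        median_intra_cv=median_intra, median_inter_cv=median_inter,
        pass_intra=median_intra < intra_threshold,
        pass_inter=median_inter < inter_threshold,
        replicate_r2_min=r2_min,
        n_undefined=n_undef_a + n_undef_b)


# ---------------------------------------------------------------------------
# Multivariate structure
# ---------------------------------------------------------------------------

def pca_scores(
    m: ExpressionMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores from gene-mean-centered PCA (no gene scaling).

    Component signs are fixed so each component's largest-magnitude gene
    loading is positive, making scores reproducible across runs.
    Returns (scores: samples x components, explained-variance fractions).
    """
    X = m.values.to_numpy().T                     # samples x genes
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return (pd.DataFrame(scores, index=m.values.columns, columns=cols),
            pca.explained_variance_ratio_)


def hierarchical_cluster(
    m: ExpressionMatrix, k: int, method: str = "average"
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering on 1 - Pearson distance between samples.

    Samples are processed in lexicographic sample_id order so ties break
    deterministically.  Returns (labels: sample -> 1..k, linkage matrix).
    """
    if m.values.shape[1] < k:
        raise ValueError("fewer samples than clusters")
    order = sorted(m.values.columns)
    corr = pairwise_pearson(m.subset_samples(order))
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)  # enforce exact symmetry
    Z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=order, name="cluster"), Z


# ---------------------------------------------------------------------------
# Per-gene two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-gene mean squares for a balanced two-way layout."""

    table: pd.DataFrame             # per gene: ss/ms for case, batch, residual; F
    fraction_above_diagonal: float  # genes with MS_case > MS_residual
    df_case: int
    df_batch: int
    df_residual: int


def anova_ms(
    m: ExpressionMatrix,
    meta: SampleTable,
    case_col: str = "case_id",
    batch_cols: tuple[str, ...] = ("lab", "day"),
) -> AnovaResult:
    """Balanced two-way decomposition per gene: case x batch (lab x day).

    SS_residual = SS_total - SS_case - SS_batch (interaction pooled with
    noise, the standard diagnostic layout for technical-replicate designs).
    Requires a fully balanced design; missing cells are refused.
    """
    table = meta.table[meta.table["sample_id"].isin(m.values.columns)].copy()
    table["_batch"] = table[list(batch_cols)].astype(str).agg("|".join, axis=1)
    cases = sorted(table[case_col].unique())
    batches = sorted(table["_batch"].unique())
    counts = table.groupby([case_col, "_batch"]).size()
    full = pd.MultiIndex.from_product([cases, batches])
    counts = counts.reindex(full, fill_value=0)
    if counts.nunique() != 1 or counts.iloc[0] == 0:
        missing = counts[counts == 0].index.tolist()
        raise ValueError(f"unbalanced design; empty/unequal cells: {missing[:5]}")
    r = int(counts.iloc[0])

    sample_order = table.sort_values([case_col, "_batch"])["sample_id"].tolist()
    X = m.values[sample_order].to_numpy()          # genes x n
    n = X.shape[1]
    a, b = len(cases), len(batches)
    grand = X.mean(axis=1, keepdims=True)
    ss_total = ((X - grand) ** 2).sum(axis=1)

    case_labels = table.set_index("sample_id").loc[sample_order, case_col].to_numpy()
    batch_labels = table.set_index("sample_id").loc[sample_order, "_batch"].to_numpy()
    case_means = np.stack([X[:, case_labels == c].mean(axis=1) for c in cases], axis=1)
    batch_means = np.stack([X[:, batch_labels == g].mean(axis=1) for g in batches], axis=1)
    ss_case = (b * r) * ((case_means - grand) ** 2).sum(axis=1)
    ss_batch = (a * r) * ((batch_means - grand) ** 2).sum(axis=1)
    ss_res = ss_total - ss_case - ss_batch

    df_case, df_batch = a - 1, b - 1
    df_res = n - 1 - df_case - df_batch
    ms_case = ss_case / df_case
    ms_batch = ss_batch / df_batch
    ms_res = np.maximum(ss_res, 0.0) / df_res
    with np.errstate(divide="ignore", invalid="ignore"):
        f_case = np.where(ms_res > 0, ms_case / ms_res, np.inf)

    out = pd.DataFrame(
        {"ss_sample": ss_case, "ss_batch": ss_batch, "ss_residual": ss_res,
         "ms_sample": ms_case, "ms_batch": ms_batch, "ms_residual": ms_res,
         "f_sample": f_case},
        index=m.values.index)
    frac = float((out["ms_sample"] > out["ms_residual"]).mean())
    return AnovaResult(table=out, fraction_above_diagonal=frac,
                       df_case=df_case, df_batch=df_batch, df_residual=df_res)
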