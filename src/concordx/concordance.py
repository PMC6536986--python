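"""Cross-platform concordance: gene mapping, fold changes, classifiers.

The comparison asks whether between-group expression *changes*, not absolute
levels, agree between a count platform and a hybridization-intensity
platform.  Per gene and platform the ratio-of-means fold change is

    log2FC = log2( (mean_A + eps) / (mean_B + eps) ),   eps = 0.5,

with group means on the linear (normalized) scale.  Two classifiers label
each mapped gene:

* **2-fold tiers** — ``within2fold`` if |log2FC| < 1 on both platforms;
  otherwise ``concordant_change`` if the two platform fold changes share a
  sign; ``discordant`` if they have opposite signs with |log2FC| >= 1 on both
  platforms (opposite signs with one platform below threshold count as
  within2fold, keeping the tiers a partition).
* **regression band** — OLS of the count-platform fold change on the
  array-platform fold change; genes whose residual exceeds z * residual_sd
  (z = 1.96) are out of band and split by fold-change sign agreement.  The
  band absorbs systematic slope/offset differences (e.g. array signal
  compression), so its concordant fraction is at least that of the fixed
  2-fold rule on pooled data.

Both classifiers are symmetric under swapping the platforms' fold-change
columns (for the discordant set) and under negating both fold changes
(relabeling the groups).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_io import CodeClass, ExpressionMatrix, PanelAnnotation, SampleTable, Scale

__all__ = [
    "GeneMap",
    "build_gene_map",
    "cross_platform_sample_r",
    "fold_change_table",
    "stratified_fc_correlation",
    "classify_twofold",
    "BandFit",
    "classify_regression_band",
    "pooling_curve",
]

EPS = 0.5  # pseudocount added to group means before ratios

TIER_WITHIN = "within2fold"
TIER_CONCORDANT = "concordant_change"
TIER_DISCORDANT = "discordant"
BAND_IN = "in_band"
BAND_SAME = "out_band_same_dir"
BAND_OPPOSITE = "out_band_opposite"


# ---------------------------------------------------------------------------
# Gene mapping
# ---------------------------------------------------------------------------

@dataclass
class GeneMap:
    """Panel gene -> single array row after collapsing multi-probe-set genes."""

    resolved: dict[str, str]        # gene_symbol -> array row id
    unmapped: list[str]             # panel genes with no array probe set
    collapse_rule: str

    @property
    def genes(self) -> list[str]:
        return list(self.resolved)


def build_gene_map(
    panel: PanelAnnotation,
    array_annotation: pd.DataFrame,
    array_matrix: ExpressionMatrix,
    collapse_rule: str = "max_mean",
) -> GeneMap:
    """Map endogenous + housekeeping panel genes to one array row each.

    Control probes (positive/negative) are excluded.  Genes with several
    probe sets are collapsed by ``collapse_rule``:

    * ``max_mean`` (default) — keep the probe set with the highest mean
      expression across samples;
    * ``best_single`` — alias of max_mean kept for config compatibility;
    * ``mean_of_sets`` — not a row selection; resolved to the probe set
      closest to the per-gene mean profile.

    Unmapped genes are reported, not fatal.
    """
    keep = panel.table["code_class"].isin([CodeClass.ENDOGENOUS, CodeClass.HOUSEKEEPING])
    genes = panel.table.loc[keep, "gene_symbol"].tolist()
    by_gene = array_annotation.groupby("gene_symbol")["probeset_id"].apply(list).to_dict()
    means = array_matrix.values.mean(axis=1)
    resolved: dict[str, str] = {}
    unmapped: list[str] = []
    for gene in genes:
        candidates = [p for p in by_gene.get(gene, []) if p in array_matrix.values.index]
        if not candidates:
            unmapped.append(gene)
            continue
        if len(candidates) == 1 or collapse_rule in ("max_mean", "best_single"):
            resolved[gene] = max(candidates, key=lambda p: (means[p], p))
        elif collapse_rule == "mean_of_sets":
            target = float(np.mean([means[p] for p in candidates]))
            resolved[gene] = min(candidates, key=lambda p: (abs(means[p] - target), p))
        else:
            raise ValueError(f"unknown collapse_rule {collapse_rule!r}")
    return GeneMap(resolved=resolved, unmapped=unmapped, collapse_rule=collapse_rule)


# ---------------------------------------------------------------------------
# Absolute-level correlation
# ---------------------------------------------------------------------------

def cross_platform_sample_r(
    m_count: ExpressionMatrix,
    m_array: ExpressionMatrix,
    gene_map: GeneMap,
    pairing: dict[str, str] | None = None,
) -> dict:
    """Within- vs between-platform sample correlation summary (log2 scale).

    ``pairing`` maps count-platform sample ids to array sample ids (identity
    on the shared ids by default).  Mapped genes only; needs >= 3 genes.
    Returns ranges and medians for within-platform pairwise r on each
    platform and for the paired between-platform r.
    """
    if m_count.scale != Scale.LOG2 or m_array.scale != Scale.LOG2:
        raise ValueError("cross-platform correlation expects log2 matrices")
    genes = gene_map.genes
    if len(genes) < 3:
        raise ValueError("need >= 3 mapped genes")
    if pairing is None:
        shared = [s for s in m_count.values.columns if s in m_array.values.columns]
        pairing = {s: s for s in shared}
    count_block = m_count.values.loc[genes, list(pairing)]
    array_block = m_array.values.loc[[gene_map.resolved[g] for g in genes],
                                     [pairing[s] for s in pairing]]

    def offdiag(df: pd.DataFrame) -> np.ndarray:
        corr = np.corrcoef(df.to_numpy(), rowvar=False)
        return corr[np.triu_indices_from(corr, k=1)]

    within_count = offdiag(count_block)
    within_array = offdiag(array_block)
    between = np.array([
        np.corrcoef(count_block[s].to_numpy(), array_block.to_numpy()[:, i])[0, 1]
        for i, s in enumerate(pairing)
    ])
    return {
        "within_count_r_range": (float(within_count.min()), float(within_count.max())),
        "within_count_r_median": float(np.median(within_count)),
        "within_array_r_range": (float(within_array.min()), float(within_array.max())),
        "within_array_r_median": float(np.median(within_array)),
        "between_r_range": (float(between.min()), float(between.max())),
        "between_r_median": float(np.median(between)),
        "n_genes": len(genes),
        "n_pairs": len(pairing),
    }


# ---------------------------------------------------------------------------
# Fold changes
# ---------------------------------------------------------------------------

def _tertile_strata(avg_log2_expr: pd.Series) -> pd.Series:
    """Partition genes into low/medium/high thirds (sizes within +-1).

    Boundaries come from the rank order of the cross-platform average log2
    expression; ties break by gene order (stable sort).
    """
    order = np.argsort(avg_log2_expr.to_numpy(), kind="stable")
    n = len(order)
    sizes = [n // 3 + (1 if i < n % 3 else 0) for i in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    for name, size in zip(("low", "medium", "high"), sizes):
        labels[order[start:start + size]] = name
        start += size
    return pd.Series(labels, index=avg_log2_expr.index, name="mean_expr_stratum")


def fold_change_table(
    m_count: ExpressionMatrix,
    m_array: ExpressionMatrix,
    meta: SampleTable,
    gene_map: GeneMap,
    group_a: str = "ERpos",
    group_b: str = "TNB",
    samples_a: list[str] | None = None,
    samples_b: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene ratio-of-means log2 fold change on each platform.

    Group A over group B (default ER+/TNB), linear-scale means with a 0.5
    pseudocount.  Samples may be restricted explicitly (pooling analyses);
    otherwise all samples of each subtype present on a platform are used.
    The returned table carries means, fold changes, the cross-platform
    average log2 expression, and the tertile stratum.
    """
    for m in (m_count, m_array):
        if m.scale != Scale.NORMALIZED:
            raise ValueError("fold changes are computed on the normalized (linear) scale")

    def group_samples(matrix: ExpressionMatrix, subtype: str, explicit) -> list[str]:
        if explicit is not None:
            samples = [s for s in explicit if s in matrix.values.columns]
        else:
            samples = [s for s in meta.samples_where(subtype=subtype)
                       if s in matrix.values.columns]
        if not samples:
            raise ValueError(f"no samples for group {subtype!r}")
        return samples

    genes = gene_map.genes
    array_rows = [gene_map.resolved[g] for g in genes]
    rows = {}
    for platform, matrix, row_ids in (("count", m_count, genes), ("array", m_array, array_rows)):
        a = group_samples(matrix, group_a, samples_a)
        b = group_samples(matrix, group_b, samples_b)
        block = matrix.values.loc[row_ids]
        rows[f"mean_a_{platform}"] = block[a].mean(axis=1).to_numpy()
        rows[f"mean_b_{platform}"] = block[b].mean(axis=1).to_numpy()
    fc = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"))
    fc["all_zero_flag"] = ((fc["mean_a_count"] + fc["mean_b_count"] == 0)
                           | (fc["mean_a_array"] + fc["mean_b_array"] == 0))
    fc["log2fc_count"] = np.log2((fc["mean_a_count"] + EPS) / (fc["mean_b_count"] + EPS))
    fc["log2fc_array"] = np.log2((fc["mean_a_array"] + EPS) / (fc["mean_b_array"] + EPS))
    avg_expr = 0.5 * (
        np.log2(0.5 * (fc["mean_a_count"] + fc["mean_b_count"]) + 1.0)
        + np.log2(0.5 * (fc["mean_a_array"] + fc["mean_b_array"]) + 1.0))
    fc["avg_log2_expr"] = avg_expr
    fc["mean_expr_stratum"] = _tertile_strata(avg_expr)
    return fc


def stratified_fc_correlation(fc: pd.DataFrame) -> dict:
    """Pearson r of the two platforms' fold changes, overall and per stratum.

    Strata with fewer than 3 genes are reported as NaN.
    """
    def safe_r(block: pd.DataFrame) -> float:
        if len(block) < 3:
            return float("nan")
        return float(np.corrcoef(block["log2fc_count"], block["log2fc_array"])[0, 1])

    out = {"overall": safe_r(fc)}
    for stratum in ("low", "medium", "high"):
        out[stratum] = safe_r(fc[fc["mean_expr_stratum"] == stratum])
    return out


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def classify_twofold(fc: pd.DataFrame, threshold_log2: float = 1.0) -> tuple[pd.Series, dict]:
    """Fixed 2-fold tiering of each gene; returns (tiers, summary)."""
    x = fc["log2fc_count"].to_numpy()
    y = fc["log2fc_array"].to_numpy()
    both_small = (np.abs(x) < threshold_log2) & (np.abs(y) < threshold_log2)
    opposite = np.sign(x) * np.sign(y) < 0
    both_large = (np.abs(x) >= threshold_log2) & (np.abs(y) >= threshold_log2)
    tiers = np.where(opposite & both_large, TIER_DISCORDANT,
                     np.where(both_small | opposite, TIER_WITHIN, TIER_CONCORDANT))
    tiers = pd.Series(tiers, index=fc.index, name="tier_twofold")
    counts = tiers.value_counts().to_dict()
    n = len(tiers)
    concordant = counts.get(TIER_WITHIN, 0) + counts.get(TIER_CONCORDANT, 0)
    summary = {
        "n_genes": n,
        "n_within2fold": counts.get(TIER_WITHIN, 0),
        "n_concordant_change": counts.get(TIER_CONCORDANT, 0),
        "n_discordant": counts.get(TIER_DISCORDANT, 0),
        "concordant_fraction": concordant / n if n else float("nan"),
    }
    return tiers, summary


@dataclass
class BandFit:
    """OLS fit of count fold change on array fold change, with its band."""

    slope: float
    intercept: float
    residual_sd: float              # n-2 denominator
    z: float

    @property
    def band_halfwidth(self) -> float:
        return self.z * self.residual_sd


def classify_regression_band(
    fc: pd.DataFrame, z: float = 1.96, response: str = "count"
) -> tuple[BandFit, pd.Series, dict]:
    """Residual-band tiering around the cross-platform regression line.

    ``response`` selects which platform's fold change is regressed on the
    other (default: count on array).  Genes within z * residual_sd of the
    line are ``in_band``; the rest split by fold-change sign agreement.
    """
    if len(fc) < 3:
        raise ValueError("need >= 3 genes for the regression band")
    if response == "count":
        y = fc["log2fc_count"].to_numpy()
        x = fc["log2fc_array"].to_numpy()
    elif response == "array":
        y = fc["log2fc_array"].to_numpy()
        x = fc["log2fc_count"].to_numpy()
    else:
        raise ValueError("response must be 'count' or 'array'")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: zero predictor variance")
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    residual_sd = float(np.sqrt((residuals ** 2).sum() / (len(x) - 2)))
    fit = BandFit(slope=float(slope), intercept=float(intercept),
                  residual_sd=residual_sd, z=float(z))
    in_band = np.abs(residuals) <= fit.band_halfwidth
    same_dir = (np.sign(fc["log2fc_count"].to_numpy())
                * np.sign(fc["log2fc_array"].to_numpy())) >= 0
    tiers = np.where(in_band, BAND_IN, np.where(same_dir, BAND_SAME, BAND_OPPOSITE))
    tiers = pd.Series(tiers, index=fc.index, name="tier_band")
    counts = tiers.value_counts().to_dict()
    n = len(tiers)
    concordant = counts.get(BAND_IN, 0) + counts.get(BAND_SAME, 0)
    summary = {
        "n_genes": n,
        "n_in_band": counts.get(BAND_IN, 0),
        "n_out_band_same_dir": counts.get(BAND_SAME, 0),
        "n_out_band_opposite": counts.get(BAND_OPPOSITE, 0),
        "concordant_fraction": concordant / n if n else float("nan"),
    }
    return fit, tiers, summary


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

def pooling_curve(
    m_count: ExpressionMatrix,
    m_array: ExpressionMatrix,
    meta: SampleTable,
    gene_map: GeneMap,
    pool_sizes: list[int],
    group_a: str = "ERpos",
    group_b: str = "TNB",
    n_resamples: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fold-change correlation as a function of samples pooled per group.

    For each pool size n the deterministic subset is the first n sorted
    sample_ids per group; with ``n_resamples`` > 0 random n-subsets are also
    drawn and the median r reported.
    """
    shared = [s for s in m_count.values.columns if s in m_array.values.columns]
    avail = meta.subset(shared)
    samples_a = sorted(avail.samples_where(subtype=group_a))
    samples_b = sorted(avail.samples_where(subtype=group_b))
    rng = np.random.default_rng(seed)
    rows = []
    for n in pool_sizes:
        if n > len(samples_a) or n > len(samples_b):
            raise ValueError(f"pool size {n} exceeds group size "
                             f"({len(samples_a)}, {len(samples_b)})")
        fc = fold_change_table(m_count, m_array, meta, gene_map,
                               group_a=group_a, group_b=group_b,
                               samples_a=samples_a[:n], samples_b=samples_b[:n])
        r = stratified_fc_correlation(fc)["overall"]
        resampled = []
        for _ in range(n_resamples):
            sub_a = list(rng.choice(samples_a, size=n, replace=False))
            sub_b = list(rng.choice(samples_b, size=n, replace=False))
            fc_i = fold_change_table(m_count, m_array, meta, gene_map,
                                     group_a=group_a, group_b=group_b,
                                     samples_a=sub_a, samples_b=sub_b)
            resampled.append(stratified_fc_correlation(fc_i)["overall"])
        rows.append({"pool_size": n, "r": r,
                     "r_resample_median": float(np.median(resampled)) if resampled else np.nan,
                     "n_resamples": n_resamples})
    return pd.DataFrame(rows)
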