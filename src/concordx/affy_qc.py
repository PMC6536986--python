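"""Simplified array-platform QC on probe-level intensity data.

Three per-sample metrics, computed from a probe x sample matrix in which
selected control genes are represented by K probes ordered 5' -> 3':

* **scale factor** — target / trimmed mean of all probe intensities; large
  factors indicate dim arrays;
* **3'/5' ratio** — intensity of the 3'-most probe over the 5'-most probe of
  a control transcript; elevated ratios indicate RNA degradation (FFPE
  material loses 5' signal under 3'-anchored amplification);
* **degradation slope** — per probe position, average intensity over control
  genes; the series is standardized (mean 0, sd 1) and regressed on position,
  so the slope is scale-free and grows with 5'->3' signal gain.

Detection ("percent present") in the vendor sense needs mismatch probes and
a signed-rank detection test; here a simpler fraction of probes above a
background quantile is reported informationally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import ExpressionMatrix, Scale

__all__ = [
    "ArrayQCThresholds",
    "array_scale_factor",
    "three_prime_five_prime_ratio",
    "rna_degradation_slope",
    "fraction_above_background",
    "array_qc_report",
]


@dataclass
class ArrayQCThresholds:
    """Conservative defaults; the report always carries the raw values."""

    scale_factor_max: float = 10.0
    three_five_ratio_max: float = 10.0
    degradation_slope_max: float = 0.6


def array_scale_factor(
    probe_level: ExpressionMatrix, target: float = 500.0, trim: float = 0.02
) -> pd.Series:
    """Per-sample ``target / trimmed_mean``; ``trim`` removed from each tail."""
    if probe_level.scale != Scale.RAW:
        raise ValueError("scale factor is computed on raw probe intensities")
    values = probe_level.values
    trimmed = values.apply(lambda col: stats.trim_mean(col.to_numpy(), trim), axis=0)
    if (trimmed <= 0).any():
        bad = trimmed.index[trimmed <= 0].tolist()
        raise ValueError(f"all-zero or non-positive sample(s): {bad}")
    return (target / trimmed).rename("scale_factor")


def three_prime_five_prime_ratio(
    probe_level: ExpressionMatrix, control_map: dict[str, list[str]]
) -> pd.DataFrame:
    """3'/5' ratio per control gene per sample.

    ``control_map`` maps gene -> probe ids ordered 5' -> 3' (>= 2 probes).
    """
    out = {}
    for gene, probes in control_map.items():
        if len(probes) < 2:
            raise ValueError(f"{gene}: need >= 2 ordered probes")
        five = probe_level.values.loc[probes[0]]
        three = probe_level.values.loc[probes[-1]]
        if (five == 0).any():
            raise ValueError(f"{gene}: zero 5' probe intensity")
        out[gene] = three / five
    return pd.DataFrame(out)


def control_map_from_positions(positions: pd.DataFrame) -> dict[str, list[str]]:
    """Build gene -> ordered probe ids from a probe_id/gene_symbol/position table."""
    ordered = positions.sort_values(["gene_symbol", "position"])
    return {g: grp["probe_id"].tolist() for g, grp in ordered.groupby("gene_symbol")}


def rna_degradation_slope(
    probe_level: ExpressionMatrix, positions: pd.DataFrame
) -> pd.Series:
    """Slope of the standardized mean-intensity-by-position series per sample.

    Every control gene contributes K ordered probes; for each position p the
    intensities are averaged over genes, the K-point series is standardized
    within the sample (subtract mean, divide by sd, n-1), and an OLS slope
    versus p is returned.  Standardization makes the slope invariant to
    per-sample intensity scaling.
    """
    pos = positions.set_index("probe_id")["position"]
    k_values = sorted(pos.unique())
    if len(k_values) < 3:
        raise ValueError("need K >= 3 probe positions")
    by_position = probe_level.values.groupby(pos).mean()   # position x sample
    by_position = by_position.loc[k_values]
    arr = by_position.to_numpy()
    sd = arr.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)                         # flat profile -> slope 0
    z = (arr - arr.mean(axis=0)) / sd
    p = np.asarray(k_values, dtype=float)
    pc = p - p.mean()
    slopes = (pc @ z) / (pc @ pc)
    return pd.Series(slopes, index=by_position.columns, name="degradation_slope")


def fraction_above_background(
    probe_level: ExpressionMatrix, background_quantile: float = 0.05
) -> pd.Series:
    """Fraction of probes above a global low-intensity quantile (informational)."""
    threshold = float(np.quantile(probe_level.values.to_numpy(), background_quantile))
    return (probe_level.values > threshold).mean(axis=0).rename("fraction_present")


def array_qc_report(
    probe_level: ExpressionMatrix,
    positions: pd.DataFrame,
    thresholds: ArrayQCThresholds | None = None,
    target: float = 500.0,
    trim: float = 0.02,
) -> pd.DataFrame:
    """All array QC metrics per sample with flags and a pass column."""
    thresholds = thresholds or ArrayQCThresholds()
    sf = array_scale_factor(probe_level, target=target, trim=trim)
    ratios = three_prime_five_prime_ratio(probe_level, control_map_from_positions(positions))
    slope = rna_degradation_slope(probe_level, positions)
    present = fraction_above_background(probe_level)
    report = pd.DataFrame({"scale_factor": sf, "degradation_slope": slope,
                           "fraction_present": present})
    for gene in ratios.columns:
        report[f"ratio_3p5p_{gene}"] = ratios[gene]
    flags = []
    for sid in report.index:
        f = []
        if report.loc[sid, "scale_factor"] > thresholds.scale_factor_max:
            f.append("scale_factor")
        if report.loc[sid, "degradation_slope"] > thresholds.degradation_slope_max:
            f.append("degradation_slope")
        if (ratios.loc[sid] > thresholds.three_five_ratio_max).any():
            f.append("three_five_ratio")
        flags.append(";".join(f))
    report["flags"] = flags
    report["pass"] = [f == "" for f in flags]
    return report
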