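"""Lane QC and the three-step normalization chain for count-platform data.

The chain is the canonical configuration of nCounter-style normalization:

1. **positive-control scaling** — each sample is scaled by
   ``geomean_over_samples(g) / g_s`` where ``g_s`` is the geometric mean of
   its positive-control counts, removing lane-efficiency differences;
2. **background subtraction** — each endogenous/housekeeping value has the
   sample's negative-control background removed (default: mean + 2 sd of the
   8 negative probes, sample sd), floored at 1 so log2 stays defined;
3. **housekeeping scaling** — each sample is scaled by
   ``geomean_over_samples(h) / h_s`` where ``h_s`` is the geometric mean of
   its housekeeping probes, removing RNA-content differences.

Both scaling factors have geometric mean 1 across samples by construction.
Because the reference in steps 1 and 3 is an ensemble geometric mean, the
chain is exactly invariant under per-sample rescalings of the raw counts
whose scale factors have geometric mean 1; an arbitrary per-sample rescaling
moves every output value by the single global constant
``geomean(scales)`` (see docs/methods.md).

Lane QC mirrors the vendor's standard metrics: imaging (fields of view
counted / requested), binding density, positive-control linearity (R^2 of
log2 count vs log2 nominal concentration, lowest ladder point excluded), and
limit of detection (a designated low positive control must exceed
mean + 2 sd of the negatives).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import (
    ExpressionMatrix,
    LaneCounts,
    PanelAnnotation,
    Platform,
    Scale,
)

logger = logging.getLogger("concordx")

__all__ = [
    "QCThresholds",
    "LaneQCReport",
    "NormalizationFactors",
    "qc_lane",
    "qc_lanes",
    "normalize_positive",
    "subtract_background",
    "normalize_housekeeping",
    "log2_transform",
    "normalize_chain",
]


@dataclass
class QCThresholds:
    """Lane QC pass/fail limits (vendor conventions, all overridable)."""

    min_fov_ratio: float = 0.75
    binding_density_range: tuple[float, float] = (0.1, 2.25)
    min_pos_r2: float = 0.95
    #: positive probe used for the limit-of-detection check; None selects the
    #: probe with the second-lowest nominal concentration (0.5 fM on the
    #: standard ladder, the conventional LOD probe)
    lod_probe: str | None = None


@dataclass
class LaneQCReport:
    sample_id: str
    fov_ratio: float
    binding_density: float
    pos_control_r2: float
    lod_pass: bool
    flags: list[str]

    @property
    def passed(self) -> bool:
        return not self.flags


@dataclass
class NormalizationFactors:
    """Per-sample factors from the chain; geometric mean of each factor
    column is 1 across samples."""

    pos_factor: pd.Series | None = None
    background: pd.Series | None = None
    hk_factor: pd.Series | None = None

    def as_frame(self) -> pd.DataFrame:
        cols = {}
        for name in ("pos_factor", "background", "hk_factor"):
            value = getattr(self, name)
            if value is not None:
                cols[name] = value
        return pd.DataFrame(cols)


def _lod_probe_id(panel: PanelAnnotation, thresholds: QCThresholds) -> str:
    if thresholds.lod_probe is not None:
        return thresholds.lod_probe
    ladder = panel.positive_ladder()          # descending conc
    if len(ladder) < 2:
        return ladder.index[-1]
    return ladder.index[-2]                   # second-lowest concentration


def qc_lane(
    lane: LaneCounts,
    panel: PanelAnnotation,
    thresholds: QCThresholds | None = None,
) -> LaneQCReport:
    """Compute the four lane QC metrics and flag failures."""
    thresholds = thresholds or QCThresholds()
    ladder = panel.positive_ladder()
    if len(ladder) < 3:
        raise ValueError("positive-control R^2 undefined with fewer than 3 positive probes")

    flags: list[str] = []
    fov_ratio = lane.fov_ratio
    if fov_ratio < thresholds.min_fov_ratio:
        flags.append("fov_ratio")
    lo, hi = thresholds.binding_density_range
    if not lo <= lane.binding_density <= hi:
        flags.append("binding_density")

    # linearity across the ladder, lowest point excluded (vendor convention)
    probes = ladder.index[:-1]
    counts = lane.counts[probes].to_numpy(dtype=float)
    log_counts = np.log2(np.where(counts > 0, counts, 0.5))
    fit = stats.linregress(np.log2(ladder[probes].to_numpy()), log_counts)
    pos_r2 = float(fit.rvalue ** 2)
    if pos_r2 < thresholds.min_pos_r2:
        flags.append("pos_control_r2")

    neg = lane.counts[panel.negative].to_numpy(dtype=float)
    lod_threshold = neg.mean() + 2.0 * neg.std(ddof=1) if len(neg) > 1 else neg.mean()
    lod_pass = bool(lane.counts[_lod_probe_id(panel, thresholds)] > lod_threshold)
    if not lod_pass:
        flags.append("lod")

    return LaneQCReport(sample_id=lane.sample_id, fov_ratio=fov_ratio,
                        binding_density=lane.binding_density,
                        pos_control_r2=pos_r2, lod_pass=lod_pass, flags=flags)


def qc_lanes(
    lanes: list[LaneCounts],
    panel: PanelAnnotation,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """QC every lane; one row per lane with metrics, flags and pass."""
    reports = [qc_lane(lane, panel, thresholds) for lane in lanes]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reports],
            "fov_ratio": [r.fov_ratio for r in reports],
            "binding_density": [r.binding_density for r in reports],
            "pos_control_r2": [r.pos_control_r2 for r in reports],
            "lod_pass": [r.lod_pass for r in reports],
            "flags": [";".join(r.flags) for r in reports],
            "pass": [r.passed for r in reports],
        }
    ).set_index("sample_id")


def _geomean_columns(values: pd.DataFrame, rows: list[str], what: str) -> pd.Series:
    """Per-sample geometric mean over ``rows``; zeros get a +0.5 offset."""
    block = values.loc[rows]
    if (block.to_numpy() == 0).any():
        warnings.warn(f"zero {what} count(s); applying +0.5 offset for geometric mean",
                      stacklevel=3)
        block = block + 0.5
    return np.exp(np.log(block).mean(axis=0))


def _require_scale(m: ExpressionMatrix, scale: Scale, op: str) -> None:
    if m.scale != scale:
        raise ValueError(f"{op} requires scale={scale.value!r}, got {m.scale.value!r}")


def normalize_positive(
    m: ExpressionMatrix, panel: PanelAnnotation
) -> tuple[ExpressionMatrix, NormalizationFactors]:
    """Positive-control geometric-mean scaling of a raw count matrix."""
    _require_scale(m, Scale.RAW, "normalize_positive")
    if m.platform != Platform.COUNT:
        raise ValueError("normalize_positive applies to the count platform")
    g = _geomean_columns(m.values, panel.positive, "positive-control")
    factors = np.exp(np.log(g).mean()) / g
    out = m.values.mul(factors, axis=1)
    return (ExpressionMatrix(values=out, platform=m.platform, scale=Scale.NORMALIZED),
            NormalizationFactors(pos_factor=factors.rename("pos_factor")))


def subtract_background(
    m: ExpressionMatrix,
    panel: PanelAnnotation,
    method: str = "mean_plus_2sd",
    floor: float = 1.0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Remove per-sample negative-control background from endogenous + HK rows.

    ``method`` is one of ``mean_plus_2sd`` (default; sample sd, n-1),
    ``mean``, ``max``.  Values are floored at ``floor`` after subtraction.
    """
    _require_scale(m, Scale.NORMALIZED, "subtract_background")
    neg = m.values.loc[panel.negative]
    if method == "mean_plus_2sd":
        b = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    elif method == "mean":
        b = neg.mean(axis=0)
    elif method == "max":
        b = neg.max(axis=0)
    else:
        raise ValueError(f"unknown background method {method!r}")
    out = m.values.copy()
    target = panel.endogenous + panel.housekeeping
    out.loc[target] = np.maximum(out.loc[target].sub(b, axis=1), floor)
    return m.with_values(out), b.rename("background")


def normalize_housekeeping(
    m: ExpressionMatrix, panel: PanelAnnotation
) -> tuple[ExpressionMatrix, NormalizationFactors]:
    """Housekeeping geometric-mean scaling; equalizes HK geomeans across samples."""
    _require_scale(m, Scale.NORMALIZED, "normalize_housekeeping")
    h = _geomean_columns(m.values, panel.housekeeping, "housekeeping")
    factors = np.exp(np.log(h).mean()) / h
    out = m.values.copy()
    target = panel.endogenous + panel.housekeeping
    out.loc[target] = out.loc[target].mul(factors, axis=1)
    return (m.with_values(out),
            NormalizationFactors(hk_factor=factors.rename("hk_factor")))


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """value -> log2(value + offset); advances the scale tag to log2."""
    if m.scale == Scale.LOG2:
        raise ValueError("matrix is already on log2 scale")
    if offset <= 0:
        raise ValueError("offset must be positive")
    if (m.values.to_numpy() < 0).any():
        raise ValueError("negative input value")
    return ExpressionMatrix(values=np.log2(m.values + offset),
                            platform=m.platform, scale=Scale.LOG2)


def normalize_chain(
    m: ExpressionMatrix,
    panel: PanelAnnotation,
    background_method: str = "mean_plus_2sd",
    use_positive: bool = True,
    use_background: bool = True,
    use_housekeeping: bool = True,
) -> tuple[ExpressionMatrix, NormalizationFactors]:
    """The full chain; each step optional.  Returns the normalized matrix."""
    factors = NormalizationFactors()
    if use_positive:
        m, f = normalize_positive(m, panel)
        factors.pos_factor = f.pos_factor
    elif m.scale == Scale.RAW:
        m = ExpressionMatrix(values=m.values, platform=m.platform, scale=Scale.NORMALIZED)
    if use_background:
        m, factors.background = subtract_background(m, panel, method=background_method)
    if use_housekeeping:
        m, f = normalize_housekeeping(m, panel)
        factors.hk_factor = f.hk_factor
    logger.info("normalization chain done: %d genes x %d samples",
                m.values.shape[0], m.values.shape[1])
    return m, factors
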