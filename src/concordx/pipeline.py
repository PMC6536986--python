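"""End-to-end orchestration: simulate -> normalize -> QC -> reproducibility
-> concordance, with a run manifest and a rendered summary.

A run is driven by a config mapping (YAML on disk) with one section per
stage; every stage can be disabled.  The manifest is written first and
updated as stages finish; ``summary.md`` is written last.  QC-failed lanes
are excluded before the reproducibility and concordance stages (override
with ``keep_qc_failures``), and every exclusion is recorded in the manifest
with the failing metric names as the reason code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import affy_qc as aq
from . import concordance as cc
from . import nanostring as ns
from . import reproducibility as rp
from . import synthetic_data as sd
from .panel_io import (
    ExpressionMatrix,
    SampleTable,
    Scale,
    read_expression_matrix,
    read_panel_annotation,
    read_rcc_lite,
    read_sample_table,
    write_expression_matrix,
)

logger = logging.getLogger("concordx")

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "render_summary"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "keep_qc_failures": False,
    "simulate": {"enabled": True},           # extra keys -> SimulationConfig
    "normalize": {"enabled": True, "background_method": "mean_plus_2sd"},
    "array_qc": {"enabled": True},
    "reproducibility": {"enabled": True, "outlier_k": 3.0},
    "concordance": {"enabled": True, "z": 1.96, "threshold_log2": 1.0,
                    "pool_sizes": [3, 15], "n_resamples": 25},
    "inputs": {},                            # used when simulate is disabled
}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Merge a YAML config over the defaults; unknown top-level keys refused."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is None:
        return config
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(config)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key, value in user.items():
        if isinstance(value, dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_pipeline(config: dict[str, Any] | str | Path, out_dir: str | Path) -> Path:
    """Run the configured stages; returns the report directory.

    Deterministic given seed: rerunning with the same config produces
    byte-identical TSV/JSON outputs.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 1))
    manifest: dict[str, Any] = {
        "config": config, "seed": seed, "stages": {}, "excluded_samples": [],
        "input_digests": {}, "version": _package_version(),
    }
    _write_json(manifest, out / "manifest.json")

    def finish(stage: str, status: str, t0: float, **extra) -> None:
        manifest["stages"][stage] = {"status": status,
                                     "seconds": round(time.time() - t0, 3), **extra}
        _write_json(manifest, out / "manifest.json")

    analysis_stages = ("normalize", "array_qc", "reproducibility", "concordance")
    if not config["simulate"].get("enabled", True) and not any(
            config[s].get("enabled", True) for s in analysis_stages):
        _write_json(manifest, out / "manifest.json")
        _write_summary_md(out)
        return out

    # ---- load or simulate -------------------------------------------------
    t0 = time.time()
    try:
        if config["simulate"].get("enabled", True):
            sim_keys = {k: v for k, v in config["simulate"].items() if k != "enabled"}
            for key in ("labs", "subgroup_cases", "outliers"):
                if key in sim_keys:
                    sim_keys[key] = tuple(tuple(x) if isinstance(x, list) else x
                                          for x in sim_keys[key]) if key == "outliers" \
                        else tuple(sim_keys[key])
            sim_config = sd.SimulationConfig(**sim_keys)
            ds = sd.simulate_dataset(sim_config, seed=seed)
            sd.write_dataset(ds, out / "data")
            panel, design = ds.panel, ds.design
            lanes, count_raw = ds.lanes, ds.count_raw
            array_norm, probe_level = ds.array_norm, ds.probe_level
            annotation, positions = ds.array_annotation, ds.probe_positions
            truth = ds.truth
        else:
            inputs = config["inputs"]
            required = ("panel", "samples", "rcc_dir", "array_matrix")
            missing = [k for k in required if k not in inputs]
            if missing:
                raise FileNotFoundError(f"missing input path(s): {missing}")
            panel = read_panel_annotation(inputs["panel"])
            design = read_sample_table(inputs["samples"])
            rcc_dir = Path(inputs["rcc_dir"])
            lane_files = sorted(rcc_dir.glob("*.csv"))
            if not lane_files:
                raise FileNotFoundError(f"no RCC-lite files in {rcc_dir}")
            lanes = [read_rcc_lite(p, panel) for p in lane_files]
            from .panel_io import lanes_to_matrix
            count_raw = lanes_to_matrix(lanes, panel)
            array_norm = read_expression_matrix(inputs["array_matrix"])
            probe_level = (read_expression_matrix(inputs["probe_matrix"])
                           if "probe_matrix" in inputs else None)
            positions = (pd.read_csv(inputs["probe_positions"])
                         if "probe_positions" in inputs else None)
            annotation = (pd.read_csv(inputs["array_annotation"])
                          if "array_annotation" in inputs
                          else pd.DataFrame({"gene_symbol": array_norm.gene_ids,
                                             "probeset_id": array_norm.gene_ids}))
            truth = None
            for name, p in inputs.items():
                p = Path(p)
                if p.is_file():
                    manifest["input_digests"][name] = _digest(p)
    except Exception as exc:
        finish("load", "error", t0, error=str(exc))
        raise StageError("load", str(exc)) from exc
    finish("load", "ok", t0, n_samples=len(design.sample_ids))

    # ---- lane QC + normalization -----------------------------------------
    qc_passed = design.sample_ids
    norm = log2_count = None
    if config["normalize"].get("enabled", True):
        t0 = time.time()
        try:
            qc = ns.qc_lanes(lanes, panel)
            qc.to_csv(out / "lane_qc.csv")
            failed = qc.index[~qc["pass"]].tolist()
            for sid in failed:
                manifest["excluded_samples"].append(
                    {"sample_id": sid, "reason": f"qc_fail:{qc.loc[sid, 'flags']}"})
            norm, factors = ns.normalize_chain(
                count_raw, panel, background_method=config["normalize"]["background_method"])
            factors.as_frame().to_csv(out / "normalization_factors.csv")
            write_expression_matrix(norm, out / "count_normalized.tsv")
            log2_count = ns.log2_transform(norm)
            if not config.get("keep_qc_failures", False):
                qc_passed = [s for s in qc_passed if s not in failed]
        except Exception as exc:
            finish("normalize", "error", t0, error=str(exc))
            raise StageError("normalize", str(exc)) from exc
        finish("normalize", "ok", t0, n_qc_failed=len(design.sample_ids) - len(qc_passed))

    # ---- array QC ---------------------------------------------------------
    if config["array_qc"].get("enabled", True) and probe_level is not None and positions is not None:
        t0 = time.time()
        try:
            report = aq.array_qc_report(probe_level, positions)
            report.to_csv(out / "array_qc.csv")
        except Exception as exc:
            finish("array_qc", "error", t0, error=str(exc))
            raise StageError("array_qc", str(exc)) from exc
        finish("array_qc", "ok", t0)

    # ---- reproducibility --------------------------------------------------
    if config["reproducibility"].get("enabled", True) and norm is not None:
        t0 = time.time()
        try:
            repro = _reproducibility_stage(config, out, panel, design, count_raw,
                                           norm, log2_count, qc_passed)
        except Exception as exc:
            finish("reproducibility", "error", t0, error=str(exc))
            raise StageError("reproducibility", str(exc)) from exc
        finish("reproducibility", "ok", t0)
        _write_json(repro, out / "reproducibility_summary.json")

    # ---- concordance ------------------------------------------------------
    if config["concordance"].get("enabled", True) and norm is not None:
        t0 = time.time()
        try:
            concord = _concordance_stage(config, out, panel, design, norm,
                                         array_norm, annotation, qc_passed, seed)
        except Exception as exc:
            finish("concordance", "error", t0, error=str(exc))
            raise StageError("concordance", str(exc)) from exc
        finish("concordance", "ok", t0)
        _write_json(concord, out / "concordance_summary.json")

    _write_json(manifest, out / "manifest.json")
    _write_summary_md(out)
    return out


def _reproducibility_stage(config, out: Path, panel, design: SampleTable,
                           count_raw, norm, log2_count, qc_passed) -> dict:
    endo = panel.endogenous + panel.housekeeping
    raw_log2 = ns.log2_transform(
        ExpressionMatrix(values=count_raw.values, platform=count_raw.platform,
                         scale=Scale.NORMALIZED))
    outliers = rp.flag_distribution_outliers(
        raw_log2.subset_genes(endo), k=config["reproducibility"]["outlier_k"])

    kept = [s for s in qc_passed]
    m = log2_count.subset_genes(endo).subset_samples(kept)
    corr = rp.pairwise_pearson(m)
    corr.to_csv(out / "pairwise_pearson.tsv", sep="\t")

    scores, evr = rp.pca_scores(m)
    scores.to_csv(out / "pca_scores.tsv", sep="\t")
    labels, _ = rp.hierarchical_cluster(m, k=2)
    labels.to_csv(out / "cluster_labels.tsv", sep="\t")

    meta_kept = design.subset(kept)
    prec = rp.precision_report(norm.subset_genes(endo).subset_samples(kept), meta_kept)
    prec.intra_cv.to_csv(out / "precision_intra_cv.tsv", sep="\t")
    prec.inter_cv.to_csv(out / "precision_inter_cv.tsv", sep="\t")

    # between-lab pooled correlation over (case, day) pairs present in both labs
    labs = sorted(design.table["lab"].unique())
    pairing = {}
    if len(labs) == 2:
        t = design.subset(kept).table
        a = t[t["lab"] == labs[0]].set_index(["case_id", "day"])["sample_id"]
        b = t[t["lab"] == labs[1]].set_index(["case_id", "day"])["sample_id"]
        for key in a.index.intersection(b.index):
            pairing[a[key]] = b[key]
    between_lab_r = (rp.between_group_scatter_r(m, m, pairing) if pairing else float("nan"))

    # per-gene ANOVA per subtype on QC-passed samples, restricted to complete
    # lab x day batches so the two-way layout stays balanced
    anova = {}
    full_log2 = log2_count.subset_genes(endo)
    for subtype in ("TNB", "ERpos"):
        t = design.subset(kept).table
        t = t[t["subtype"] == subtype]
        n_cases = t["case_id"].nunique()
        batch_sizes = t.groupby(["lab", "day"])["case_id"].nunique()
        complete = batch_sizes[batch_sizes == n_cases].index
        t = t[t.set_index(["lab", "day"]).index.isin(complete)]
        if t.groupby(["lab", "day"]).ngroups < 2:
            anova[subtype] = float("nan")
            continue
        samples = t["sample_id"].tolist()
        res = rp.anova_ms(full_log2.subset_samples(samples), design.subset(samples))
        res.table.to_csv(out / f"anova_ms_{subtype}.tsv", sep="\t")
        anova[subtype] = res.fraction_above_diagonal

    return {
        "flagged_outliers": outliers,
        "n_samples_analyzed": len(kept),
        "between_lab_pooled_r": between_lab_r,
        "pca_explained_variance": list(map(float, evr)),
        "precision": prec.summary(),
        "anova_fraction_above_diagonal": anova,
    }


def _concordance_stage(config, out: Path, panel, design, norm, array_norm,
                       annotation, qc_passed, seed) -> dict:
    gmap = cc.build_gene_map(panel, annotation, array_norm)
    kept = [s for s in qc_passed if s in array_norm.values.columns]
    m_count = norm.subset_samples([s for s in kept if s in norm.values.columns])
    m_array = array_norm.subset_samples(kept)
    meta = design.subset(kept)

    levels = cc.cross_platform_sample_r(
        ns.log2_transform(m_count), ns.log2_transform(m_array), gmap)

    fc = cc.fold_change_table(m_count, m_array, meta, gmap)
    tiers2, summary2 = cc.classify_twofold(fc, threshold_log2=config["concordance"]["threshold_log2"])
    fit, tiers_band, summary_band = cc.classify_regression_band(fc, z=config["concordance"]["z"])
    fc_out = fc.copy()
    fc_out["tier_twofold"] = tiers2
    fc_out["tier_band"] = tiers_band
    fc_out.to_csv(out / "foldchange_table.tsv", sep="\t")
    _write_json(dataclasses.asdict(fit) | {"band_halfwidth": fit.band_halfwidth},
                out / "bandfit.json")

    strat = cc.stratified_fc_correlation(fc)
    group_max = min(len(meta.samples_where(subtype="ERpos")),
                    len(meta.samples_where(subtype="TNB")))
    pool_sizes = sorted({min(int(n), group_max)
                         for n in config["concordance"]["pool_sizes"]})
    pool = cc.pooling_curve(m_count, m_array, meta, gmap,
                            pool_sizes=pool_sizes,
                            n_resamples=config["concordance"]["n_resamples"],
                            seed=seed)
    pool.to_csv(out / "pooling_curve.tsv", sep="\t", index=False)

    return {
        "n_mapped_genes": len(gmap.genes),
        "n_unmapped_genes": len(gmap.unmapped),
        "sample_level_correlation": levels,
        "fc_correlation": strat,
        "twofold": summary2,
        "band": summary_band,
        "pooling": pool.to_dict(orient="records"),
    }


def _package_version() -> str:
    from . import __version__
    return __version__


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _write_summary_md(out: Path) -> None:
    lines = ["# concordx run summary", ""]
    manifest = json.loads((out / "manifest.json").read_text())
    lines.append(f"- seed: {manifest['seed']}")
    for stage, info in manifest["stages"].items():
        lines.append(f"- stage {stage}: {info['status']} ({info['seconds']} s)")
    if manifest["excluded_samples"]:
        lines.append("- excluded samples:")
        for item in manifest["excluded_samples"]:
            lines.append(f"  - {item['sample_id']}: {item['reason']}")
    for name in ("reproducibility_summary.json", "concordance_summary.json"):
        p = out / name
        if p.exists():
            lines += ["", f"## {name}", "```json", p.read_text().strip(), "```"]
    (out / "summary.md").write_text("\n".join(lines) + "\n")


def render_summary(report_dir: str | Path) -> list[Path]:
    """Render the figure set from the stage TSV/JSON outputs.

    Every figure is backed by a text table written by the pipeline, so all
    plotted numbers are testable without image parsing.  Returns the figure
    paths; raises if a required stage output is missing.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(report_dir)
    figures: list[Path] = []

    def need(name: str) -> Path:
        p = out / name
        if not p.exists():
            raise FileNotFoundError(f"missing stage output: {p}")
        return p

    raw = read_expression_matrix(need("data/count_raw.tsv"))
    fig, ax = plt.subplots(figsize=(12, 4))
    log_raw = np.log2(raw.values + 1.0)
    ax.boxplot([log_raw[c] for c in log_raw.columns], tick_labels=list(log_raw.columns),
               showfliers=False)
    ax.set_ylabel("log2(raw count + 1)")
    ax.tick_params(axis="x", rotation=90, labelsize=5)
    fig.tight_layout()
    figures.append(out / "fig_boxplot.png")
    fig.savefig(figures[-1], dpi=120)
    plt.close(fig)

    corr = pd.read_csv(need("pairwise_pearson.tsv"), sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), vmin=0.8, vmax=1.0, cmap="RdBu_r")
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title("pairwise sample correlation")
    figures.append(out / "fig_correlation_heatmap.png")
    fig.savefig(figures[-1], dpi=120)
    plt.close(fig)

    scores = pd.read_csv(need("pca_scores.tsv"), sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(scores["PC1"], scores["PC2"], s=12)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    figures.append(out / "fig_pca.png")
    fig.savefig(figures[-1], dpi=120)
    plt.close(fig)

    labels = pd.read_csv(need("cluster_labels.tsv"), sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.bar(range(len(labels)), labels["cluster"])
    ax.set_ylabel("cluster")
    fig.tight_layout()
    figures.append(out / "fig_dendrogram_labels.png")
    fig.savefig(figures[-1], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    for subtype, marker in (("TNB", "o"), ("ERpos", "s")):
        p = out / f"anova_ms_{subtype}.tsv"
        if p.exists():
            t = pd.read_csv(p, sep="\t", index_col=0)
            ax.scatter(t["ms_residual"], t["ms_sample"], s=6, marker=marker,
                       label=subtype, alpha=0.5)
    lim = ax.get_xlim()
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("residual MS")
    ax.set_ylabel("case MS")
    ax.legend()
    fig.tight_layout()
    figures.append(out / "fig_anova_ms.png")
    fig.savefig(figures[-1], dpi=120)
    plt.close(fig)

    fc = pd.read_csv(need("foldchange_table.tsv"), sep="\t", index_col=0)
    bandfit = json.loads(need("bandfit.json").read_text())
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"in_band": "0.6", "out_band_same_dir": "tab:green",
              "out_band_opposite": "tab:red"}
    for tier, color in colors.items():
        sub = fc[fc["tier_band"] == tier]
        ax.scatter(sub["log2fc_array"], sub["log2fc_count"], s=8, c=color, label=tier)
    xs = np.linspace(fc["log2fc_array"].min(), fc["log2fc_array"].max(), 50)
    mid = bandfit["slope"] * xs + bandfit["intercept"]
    ax.plot(xs, mid, "k-", lw=1)
    for sign in (-1, 1):
        ax.plot(xs, mid + sign * bandfit["band_halfwidth"], "r--", lw=1)
    ax.set_xlabel("log2 FC (array)")
    ax.set_ylabel("log2 FC (count)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    figures.append(out / "fig_fc_band.png")
    fig.savefig(figures[-1], dpi=120)
    plt.close(fig)

    return figures
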