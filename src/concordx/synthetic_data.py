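"""Dual-platform synthetic data with a complete planted truth.

The generator emulates the analytical-validation study design this package
analyzes: 10 biological breast-tumor cases (5 triple-negative, 5 ER+, with an
ER+ two-subgroup substructure), each extracted in 2 labs on 3 days (6
technical replicates per case, 60 samples), measured on

* a **count platform** (nCounter-style): a 346-probe codeset — 325 endogenous
  genes, 7 housekeeping, 6 positive controls on a known fM ladder, 8 negative
  controls — with negative-binomial observation noise, per-lane imaging
  attributes, and planted degraded outlier lanes;
* an **array platform** (hybridization-intensity style): gene-level signal
  related to the same underlying abundances through independent per-gene
  probe affinities and a compressive response exponent, plus a probe-level
  matrix (K ordered probes per control gene with a 3'->5' decay) for array QC
  metrics.

Shared biology (baselines, subtype effects, ER+ subgroup shifts, lab/day
batch offsets) is planted once; platform-specific affinities and the
compression exponent make absolute levels disagree across platforms while
fold changes remain comparable — the phenomenon the concordance stage
measures.  A configurable subset of genes is planted *discordant*: its
between-subtype effect has opposite signs on the two platforms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel_io import (
    CodeClass,
    ExpressionMatrix,
    LaneCounts,
    PanelAnnotation,
    Platform,
    SampleTable,
    Scale,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "default_panel",
    "build_design",
    "generate_truth",
    "simulate_count_platform",
    "simulate_array_platform",
    "simulate_dataset",
    "simulate_precision_fixture",
    "write_dataset",
]

HOUSEKEEPING_SYMBOLS = ("ACTB", "GAPDH", "GUSB", "PGK1", "PPIA", "RPLP0", "TBP")
#: conventional six-step positive spike-in ladder, fM, 4-fold steps
POSITIVE_LADDER_FM = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)


@dataclass
class SimulationConfig:
    """All generator knobs with the study-design defaults.

    Effect sizes are log2; baselines and concentrations are linear.
    """

    # panel / design
    n_genes: int = 325                    # endogenous probes
    n_housekeeping: int = 7
    n_positive: int = 6
    n_negative: int = 8
    n_cases_per_subtype: int = 5
    labs: tuple[str, ...] = ("Lab1", "Lab2")
    n_days: int = 3
    # biology
    baseline_log2_mean: float = 7.5       # endogenous mean log2 count at reference
    baseline_log2_sd: float = 2.0
    hk_baseline_log2_mean: float = 9.5    # housekeeping: high, stable
    hk_baseline_log2_sd: float = 0.7
    frac_de: float = 0.6                  # endogenous genes with an ER+/TNB effect
    subtype_effect_sd: float = 2.5        # log2 ER+/TNB, shared across platforms
    frac_subgroup: float = 0.25           # genes shifted in ER+ subgroup cases
    subgroup_shift_sd: float = 2.0        # log2, applied to ER+ cases 4-5 only
    # (within-subgroup sample correlation ~0.98, across ~0.9)
    subgroup_cases: tuple[int, ...] = (4, 5)
    n_discordant: int = 16                # ~5% of endogenous genes
    min_discordant_lfc: float = 2.0       # |log2 effect| floor, both platforms
    max_discordant_lfc: float = 2.3       # |log2 effect| cap for planted discordance
    min_discordant_baseline: float = 2000.0
    # batch structure
    lab_effect_sd: float = 0.04           # per-gene per-lab log2 offset
    day_effect_sd: float = 0.04           # per-gene per-day log2 offset
    # count platform observation model
    lane_effect_log2_sd: float = 0.8      # per-lane efficiency (pos factors ~[1/3, 3])
    nb_dispersion: float = 0.003
    pos_dispersion: float = 0.002
    counts_per_fm: float = 400.0          # positive-control response slope
    neg_mean: float = 30.0                # negative-control background counts
    count_nonspec_median: float = 10.0    # per-gene cross-hybridization counts
    count_nonspec_log2_sd: float = 1.5
    fov_requested: int = 280
    fov_success_rate: float = 0.985
    # planted outlier lanes: (case_index_within_subtype, subtype, lab, day, severity)
    outliers: tuple[tuple[str, str, int, float], ...] = (
        ("TNB4", "Lab2", 2, 1.0),
        ("ER5", "Lab2", 2, 1.0),
    )
    outlier_count_scale: float = 0.02     # lane counts multiplied by scale**severity
    outlier_extra_dispersion: float = 0.3
    outlier_fov_drop: float = 0.45        # fov success multiplied by (1 - drop*severity)
    # cross-platform divergence
    affinity_log2_sd: float = 2.0         # per-gene per-platform, independent
    compression_exponent: float = 0.7     # array response exponent in (0, 1]
    compression_pivot: float = 1000.0     # intensity at which the response is 1:1
    # array platform observation model
    array_noise_log2_sd: float = 0.15     # multiplicative lognormal
    array_additive_sd: float = 5.0
    array_floor: float = 20.0             # hybridization background floor
    array_nonspec_median: float = 80.0    # per-gene nonspecific hybridization signal
    array_nonspec_log2_sd: float = 1.5
    array_bg_subtract: float | None = None  # global background removed by the
    # summarization pipeline; None -> array_nonspec_median
    rna_mass_ng: float = 100.0            # array input mass; noise ~ sqrt(ref/mass)
    rna_mass_ref_ng: float = 100.0
    outlier_rna_mass_ng: float = 20.0     # recorded mass for planted outlier preps
    frac_multi_probeset: float = 0.1      # genes represented by 2 array probe sets
    # probe-level matrix for array QC
    probe_decay: float = 0.1              # per-step 5' signal loss d
    probes_per_gene: int = 11
    n_probe_control_genes: int = 7        # housekeeping genes expanded to probes

    def __post_init__(self) -> None:
        if self.n_discordant > self.n_genes:
            raise ValueError("n_discordant exceeds n_genes")
        if not 0 < self.compression_exponent <= 1:
            raise ValueError("compression_exponent must be in (0, 1]")
        if not 0 <= self.probe_decay < 1:
            raise ValueError("probe_decay must be in [0, 1)")


def default_panel(config: SimulationConfig | None = None) -> PanelAnnotation:
    """The default 346-probe codebook (325 + 7 + 6 + 8)."""
    config = config or SimulationConfig()
    rows = []
    for i in range(config.n_genes):
        name = f"GENE{i + 1:03d}"
        rows.append((name, name, CodeClass.ENDOGENOUS.value, 0.0))
    for i in range(config.n_housekeeping):
        name = HOUSEKEEPING_SYMBOLS[i] if i < len(HOUSEKEEPING_SYMBOLS) else f"HK{i + 1}"
        rows.append((name, name, CodeClass.HOUSEKEEPING.value, 0.0))
    for i in range(config.n_positive):
        conc = POSITIVE_LADDER_FM[i] if i < len(POSITIVE_LADDER_FM) else POSITIVE_LADDER_FM[-1] / 4 ** (i - 5)
        rows.append((f"POS_{chr(65 + i)}", f"POS_{chr(65 + i)}", CodeClass.POSITIVE.value, conc))
    for i in range(config.n_negative):
        rows.append((f"NEG_{chr(65 + i)}", f"NEG_{chr(65 + i)}", CodeClass.NEGATIVE.value, 0.0))
    return PanelAnnotation(pd.DataFrame(rows, columns=["probe_id", "gene_symbol", "code_class", "nominal_conc"]))


def build_design(config: SimulationConfig | None = None) -> SampleTable:
    """The replicate design: cases x labs x days, one sample per cell."""
    config = config or SimulationConfig()
    outlier_keys = {(case, lab, day) for case, lab, day, _ in config.outliers}
    rows = []
    for subtype, prefix in (("TNB", "TNB"), ("ERpos", "ER")):
        for c in range(1, config.n_cases_per_subtype + 1):
            case_id = f"{prefix}{c}"
            for lab in config.labs:
                for day in range(1, config.n_days + 1):
                    sample_id = f"{case_id}-{lab}-D{day}"
                    mass = (config.outlier_rna_mass_ng
                            if (case_id, lab, day) in outlier_keys
                            else config.rna_mass_ng)
                    rows.append((sample_id, case_id, subtype, lab, day,
                                 f"{lab}-OP1", mass, True))
    return SampleTable(pd.DataFrame(
        rows, columns=["sample_id", "case_id", "subtype", "lab", "day",
                       "operator", "rna_mass_ng", "qc_pass"]))


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    """Planted parameters for one simulated study.

    Indexed by gene for the 325 + 7 endogenous/housekeeping genes; controls
    are handled by the count simulator directly from the panel.
    """

    seed: int
    config: SimulationConfig
    gene_ids: list[str]                 # endogenous + housekeeping, panel order
    housekeeping_ids: list[str]
    gene_baseline: pd.Series            # mean count at reference condition
    effect_count: pd.Series             # log2 ER+/TNB effect, count platform
    effect_array: pd.Series             # log2 ER+/TNB effect, array platform
    discordant_genes: list[str]
    er_subgroup_shift: pd.Series        # log2, ER+ subgroup cases only
    subgroup_case_ids: list[str]
    lab_effect: pd.DataFrame            # genes x labs, log2
    day_effect: pd.DataFrame            # genes x days (columns "1".."3"), log2
    outlier_samples: list[tuple[str, float]]   # (sample_id, severity)
    affinity_count: pd.Series
    affinity_array: pd.Series
    count_background: pd.Series         # per-gene cross-hybridization counts
    array_background: pd.Series         # per-gene nonspecific hybridization signal
    compression_exponent: float
    multi_probeset_genes: list[str]
    probeset_rel_intensity: pd.Series   # secondary/primary mean ratio per gene

    # -- expected (noise-free) signals -------------------------------------

    def _log2_effect_term(self, sample: pd.Series, platform: Platform) -> pd.Series:
        effect = self.effect_count if platform == Platform.COUNT else self.effect_array
        term = pd.Series(0.0, index=self.gene_ids)
        if sample["subtype"] == "ERpos":
            term = term + effect
            if sample["case_id"] in self.subgroup_case_ids:
                term = term + self.er_subgroup_shift
        term = term + self.lab_effect[sample["lab"]]
        term = term + self.day_effect[str(int(sample["day"]))]
        return term

    def expected_count_mean(self, sample: pd.Series) -> pd.Series:
        """Planted negative-binomial mean for one sample (endogenous + HK),
        including the gene's nonspecific cross-hybridization background."""
        term = self._log2_effect_term(sample, Platform.COUNT)
        return self.gene_baseline * np.exp2(term) * self.affinity_count + self.count_background

    def expected_array_signal(self, sample: pd.Series) -> pd.Series:
        """Noise-free array signal before flooring, for one sample.

        The compressive hybridization response is anchored at a pivot
        intensity: ``signal = pivot**(1-c) * linear**c``, so log2 fold
        changes are attenuated by the factor c while intensities near the
        pivot keep their scale (and c = 1 is the identity).
        """
        term = self._log2_effect_term(sample, Platform.ARRAY)
        linear = self.gene_baseline * np.exp2(term) * self.affinity_array
        c = self.compression_exponent
        pivot = self.config.compression_pivot
        return pivot ** (1.0 - c) * linear ** c + self.array_background

    # -- serialization ------------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
            "gene_ids": self.gene_ids,
            "housekeeping_ids": self.housekeeping_ids,
            "gene_baseline": self.gene_baseline.to_dict(),
            "effect_count": self.effect_count.to_dict(),
            "effect_array": self.effect_array.to_dict(),
            "discordant_genes": self.discordant_genes,
            "er_subgroup_shift": self.er_subgroup_shift.to_dict(),
            "subgroup_case_ids": self.subgroup_case_ids,
            "lab_effect": self.lab_effect.to_dict(),
            "day_effect": self.day_effect.to_dict(),
            "outlier_samples": [[s, v] for s, v in self.outlier_samples],
            "affinity_count": self.affinity_count.to_dict(),
            "affinity_array": self.affinity_array.to_dict(),
            "count_background": self.count_background.to_dict(),
            "array_background": self.array_background.to_dict(),
            "compression_exponent": self.compression_exponent,
            "multi_probeset_genes": self.multi_probeset_genes,
            "probeset_rel_intensity": self.probeset_rel_intensity.to_dict(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticTruth":
        cfg = d["config"]
        for key in ("labs", "subgroup_cases"):
            cfg[key] = tuple(cfg[key])
        cfg["outliers"] = tuple(tuple(o) for o in cfg["outliers"])
        genes = d["gene_ids"]

        def series(name: str) -> pd.Series:
            return pd.Series(d[name]).reindex(genes)

        return cls(
            seed=d["seed"],
            config=SimulationConfig(**cfg),
            gene_ids=genes,
            housekeeping_ids=d["housekeeping_ids"],
            gene_baseline=series("gene_baseline"),
            effect_count=series("effect_count"),
            effect_array=series("effect_array"),
            discordant_genes=d["discordant_genes"],
            er_subgroup_shift=series("er_subgroup_shift"),
            subgroup_case_ids=d["subgroup_case_ids"],
            lab_effect=pd.DataFrame(d["lab_effect"]).reindex(genes),
            day_effect=pd.DataFrame(d["day_effect"]).reindex(genes),
            outlier_samples=[(s, float(v)) for s, v in d["outlier_samples"]],
            affinity_count=series("affinity_count"),
            affinity_array=series("affinity_array"),
            count_background=series("count_background"),
            array_background=series("array_background"),
            compression_exponent=d["compression_exponent"],
            multi_probeset_genes=d["multi_probeset_genes"],
            probeset_rel_intensity=pd.Series(d["probeset_rel_intensity"], dtype=float),
        )


def generate_truth(config: SimulationConfig | None = None, seed: int = 1) -> SyntheticTruth:
    """Draw all planted parameters.  Same config + seed -> identical truth."""
    config = config or SimulationConfig()
    rng = np.random.default_rng([int(seed), 7])
    panel = default_panel(config)
    endo = panel.endogenous
    hk = panel.housekeeping
    genes = endo + hk
    gidx = pd.Index(genes, name="gene_id")

    baseline = pd.Series(0.0, index=gidx)
    baseline[endo] = np.exp2(rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, len(endo)))
    baseline[hk] = np.exp2(rng.normal(config.hk_baseline_log2_mean, config.hk_baseline_log2_sd, len(hk)))

    # shared subtype effect for a fraction of endogenous genes, zero elsewhere
    effect = pd.Series(0.0, index=gidx)
    n_de = int(round(config.frac_de * len(endo)))
    de_genes = rng.choice(endo, size=n_de, replace=False)
    effect[de_genes] = rng.normal(0.0, config.subtype_effect_sd, n_de)

    effect_count = effect.copy()
    effect_array = effect.copy()

    # planted discordance: opposite-signed effects, |log2FC| >= floor on both
    discordant = sorted(rng.choice(endo, size=config.n_discordant, replace=False))
    if discordant:
        signs = rng.choice([-1.0, 1.0], size=len(discordant))
        mag_c = rng.uniform(config.min_discordant_lfc, config.max_discordant_lfc, len(discordant))
        mag_a = rng.uniform(config.min_discordant_lfc, config.max_discordant_lfc, len(discordant))
        effect_count[discordant] = signs * mag_c
        effect_array[discordant] = -signs * mag_a
        baseline[discordant] = np.maximum(baseline[discordant], config.min_discordant_baseline)

    subgroup_shift = pd.Series(0.0, index=gidx)
    n_sub = int(round(config.frac_subgroup * len(endo)))
    sub_genes = rng.choice(endo, size=n_sub, replace=False)
    subgroup_shift[sub_genes] = rng.normal(0.0, config.subgroup_shift_sd, n_sub)

    lab_effect = pd.DataFrame(
        rng.normal(0.0, config.lab_effect_sd, (len(genes), len(config.labs))),
        index=gidx, columns=list(config.labs))
    day_effect = pd.DataFrame(
        rng.normal(0.0, config.day_effect_sd, (len(genes), config.n_days)),
        index=gidx, columns=[str(d) for d in range(1, config.n_days + 1)])

    affinity_count = pd.Series(np.exp2(rng.normal(0.0, config.affinity_log2_sd, len(genes))), index=gidx)
    affinity_array = pd.Series(np.exp2(rng.normal(0.0, config.affinity_log2_sd, len(genes))), index=gidx)
    # housekeeping probes are chosen for robust detection: keep their response
    # in a mid range so they never fall near background on either platform
    affinity_count[hk] = np.clip(affinity_count[hk], 0.5, 2.0)
    affinity_array[hk] = np.clip(affinity_array[hk], 0.5, 2.0)
    count_background = pd.Series(
        config.count_nonspec_median * np.exp2(rng.normal(0.0, config.count_nonspec_log2_sd, len(genes))),
        index=gidx)
    array_background = pd.Series(
        config.array_nonspec_median * np.exp2(rng.normal(0.0, config.array_nonspec_log2_sd, len(genes))),
        index=gidx)
    if discordant:
        # detectability guarantee for planted discordance: like the baseline
        # floor, the probe response of a planted discordant gene is kept in a
        # measurable range on both platforms so its opposite-signed effect is
        # observable rather than buried in probe-specific background.
        affinity_count[discordant] = np.clip(affinity_count[discordant], 0.5, 2.0)
        affinity_array[discordant] = np.clip(affinity_array[discordant], 0.5, 2.0)
        count_background[discordant] = np.minimum(count_background[discordant], config.count_nonspec_median)
        array_background[discordant] = np.minimum(array_background[discordant], config.array_nonspec_median)

    n_multi = int(round(config.frac_multi_probeset * len(endo)))
    multi = sorted(rng.choice(endo, size=n_multi, replace=False))
    rel = pd.Series(rng.uniform(0.2, 0.7, len(multi)), index=pd.Index(multi, name="gene_id"))

    outliers = [(f"{case}-{lab}-D{day}", float(sev)) for case, lab, day, sev in config.outliers]
    subgroup_cases = [f"ER{c}" for c in config.subgroup_cases]

    return SyntheticTruth(
        seed=int(seed), config=config, gene_ids=genes, housekeeping_ids=hk,
        gene_baseline=baseline, effect_count=effect_count, effect_array=effect_array,
        discordant_genes=discordant, er_subgroup_shift=subgroup_shift,
        subgroup_case_ids=subgroup_cases, lab_effect=lab_effect, day_effect=day_effect,
        outlier_samples=outliers, affinity_count=affinity_count,
        affinity_array=affinity_array, count_background=count_background,
        array_background=array_background,
        compression_exponent=config.compression_exponent,
        multi_probeset_genes=multi, probeset_rel_intensity=rel)


# ---------------------------------------------------------------------------
# Count platform
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial (gamma-Poisson) draw; Poisson in the dispersion->0 limit."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_count_platform(
    truth: SyntheticTruth,
    design: SampleTable,
    panel: PanelAnnotation | None = None,
) -> tuple[list[LaneCounts], ExpressionMatrix]:
    """Simulate one lane per design row; returns lanes and the raw matrix."""
    config = truth.config
    panel = panel or default_panel(config)
    unknown = set(design.table["case_id"]) - {
        f"{p}{c}" for p in ("TNB", "ER") for c in range(1, config.n_cases_per_subtype + 1)}
    if unknown:
        raise ValueError(f"design references unknown case_id(s): {sorted(unknown)}")
    rng = np.random.default_rng([truth.seed, 101])
    severity = dict(truth.outlier_samples)
    ladder = panel.positive_ladder()        # probe_id -> fM, descending
    lanes: list[LaneCounts] = []
    for _, sample in design.table.iterrows():
        sid = sample["sample_id"]
        sev = float(severity.get(sid, 0.0))
        lane_scale = float(np.exp2(rng.normal(0.0, config.lane_effect_log2_sd)))
        scale = lane_scale * config.outlier_count_scale ** sev
        disp = config.nb_dispersion + config.outlier_extra_dispersion * sev

        mean = truth.expected_count_mean(sample).to_numpy() * scale
        gene_counts = _nb_draw(rng, mean, disp)
        pos_counts = _nb_draw(rng, config.counts_per_fm * ladder.to_numpy() * scale,
                              config.pos_dispersion + config.outlier_extra_dispersion * sev)
        neg_counts = rng.poisson(config.neg_mean * scale, len(panel.negative))

        counts = pd.Series(0, index=panel.probe_ids, dtype=np.int64)
        counts[truth.gene_ids] = gene_counts
        counts[ladder.index] = pos_counts
        counts[panel.negative] = neg_counts

        fov_p = config.fov_success_rate * (1.0 - config.outlier_fov_drop * sev)
        fov_counted = int(rng.binomial(config.fov_requested, fov_p))
        binding_density = 0.05 + float(counts.sum()) / 2e6

        lanes.append(LaneCounts(sample_id=sid, counts=counts,
                                fov_requested=config.fov_requested,
                                fov_counted=fov_counted,
                                binding_density=binding_density))
    from .panel_io import lanes_to_matrix
    return lanes, lanes_to_matrix(lanes, panel)


# ---------------------------------------------------------------------------
# Array platform
# ---------------------------------------------------------------------------

def simulate_array_platform(
    truth: SyntheticTruth,
    design: SampleTable,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate the hybridization platform.

    Returns ``(gene_level, probe_level, array_annotation, probe_positions)``:

    * gene_level — probe-set x sample matrix, ``normalized`` scale (the
      upstream summarization step is outside this package's scope);
    * probe_level — K ordered probes per control gene, ``raw`` scale, with a
      3'->5' decay so a 3'/5' intensity ratio of ``(1/(1-d))**(K-1)`` is
      planted;
    * array_annotation — gene_symbol -> probeset_id table (some genes carry
      two probe sets, exercising the gene-map collapse rule);
    * probe_positions — probe_id, gene_symbol, position (1 = 5'-most).
    """
    config = truth.config
    rng = np.random.default_rng([truth.seed, 202])
    genes = truth.gene_ids
    samples = design.table

    noise_scale = np.sqrt(config.rna_mass_ref_ng / config.rna_mass_ng)
    signal = {}
    for _, sample in samples.iterrows():
        signal[sample["sample_id"]] = truth.expected_array_signal(sample).to_numpy()
    clean = pd.DataFrame(signal, index=pd.Index(genes, name="gene_id"))

    # the summarization pipeline subtracts one global background estimate, so
    # each gene keeps a residual background error (its true nonspecific signal
    # minus the global estimate) that does not average out across samples
    bg_subtract = (config.array_nonspec_median if config.array_bg_subtract is None
                   else config.array_bg_subtract)

    def observe(base: pd.DataFrame, extra_rel_noise: float = 0.0) -> pd.DataFrame:
        mult = np.exp2(rng.normal(0.0, config.array_noise_log2_sd * noise_scale + extra_rel_noise,
                                  base.shape))
        add = rng.normal(0.0, config.array_additive_sd * noise_scale, base.shape)
        out = base.to_numpy() * mult + add - bg_subtract
        return pd.DataFrame(np.maximum(out, config.array_floor),
                            index=base.index, columns=base.columns)

    # primary probe set per gene, plus a dimmer secondary set for some genes
    primary = observe(clean)
    primary.index = pd.Index([f"{g}_at" for g in genes], name="gene_id")
    ann_rows = [(g, f"{g}_at") for g in genes]
    if truth.multi_probeset_genes:
        rel = truth.probeset_rel_intensity
        secondary_base = clean.loc[truth.multi_probeset_genes].mul(rel, axis=0)
        secondary = observe(secondary_base, extra_rel_noise=0.1)
        secondary.index = pd.Index([f"{g}_x_at" for g in truth.multi_probeset_genes], name="gene_id")
        ann_rows += [(g, f"{g}_x_at") for g in truth.multi_probeset_genes]
        values = pd.concat([primary, secondary])
    else:
        values = primary
    gene_level = ExpressionMatrix(values=values, platform=Platform.ARRAY, scale=Scale.NORMALIZED)
    annotation = pd.DataFrame(ann_rows, columns=["gene_symbol", "probeset_id"])

    # probe-level matrix for the control (housekeeping) genes
    control_genes = truth.housekeeping_ids[: config.n_probe_control_genes]
    K, d = config.probes_per_gene, config.probe_decay
    decay = (1.0 - d) ** (K - 1 - np.arange(K))      # position 1 (5') most attenuated
    probe_rows, probe_ids, pos_rows = [], [], []
    for g in control_genes:
        base = clean.loc[g].to_numpy()               # per-sample clean signal
        for p in range(K):
            probe_ids.append(f"{g}_p{p + 1:02d}")
            pos_rows.append((f"{g}_p{p + 1:02d}", g, p + 1))
            probe_rows.append(base * decay[p])
    probe_base = pd.DataFrame(np.asarray(probe_rows),
                              index=pd.Index(probe_ids, name="gene_id"),
                              columns=samples["sample_id"].tolist())
    mult = np.exp2(rng.normal(0.0, config.array_noise_log2_sd * noise_scale, probe_base.shape))
    probe_values = np.maximum(probe_base.to_numpy() * mult, 1e-6)
    probe_level = ExpressionMatrix(
        values=pd.DataFrame(probe_values, index=probe_base.index, columns=probe_base.columns),
        platform=Platform.ARRAY, scale=Scale.RAW)
    positions = pd.DataFrame(pos_rows, columns=["probe_id", "gene_symbol", "position"])
    return gene_level, probe_level, annotation, positions


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one simulated study produces."""

    truth: SyntheticTruth
    panel: PanelAnnotation
    design: SampleTable
    lanes: list[LaneCounts]
    count_raw: ExpressionMatrix
    array_norm: ExpressionMatrix
    probe_level: ExpressionMatrix
    array_annotation: pd.DataFrame
    probe_positions: pd.DataFrame


def simulate_dataset(config: SimulationConfig | None = None, seed: int = 1) -> SyntheticDataset:
    """Generate truth + both platforms for the full design."""
    config = config or SimulationConfig()
    truth = generate_truth(config, seed)
    panel = default_panel(config)
    design = build_design(config)
    lanes, count_raw = simulate_count_platform(truth, design, panel)
    array_norm, probe_level, annotation, positions = simulate_array_platform(truth, design)
    return SyntheticDataset(truth=truth, panel=panel, design=design, lanes=lanes,
                            count_raw=count_raw, array_norm=array_norm,
                            probe_level=probe_level, array_annotation=annotation,
                            probe_positions=positions)


def simulate_precision_fixture(
    noise_cv: float,
    config: SimulationConfig | None = None,
    seed: int = 1,
) -> tuple[ExpressionMatrix, SampleTable]:
    """Replicate matrix with a planted per-gene coefficient of variation.

    Values are ``baseline * LogNormal`` with the lognormal sigma chosen so the
    true CV equals ``noise_cv`` exactly; no batch effects, no outliers.  Used
    to check the intra-/inter-assay precision machinery against a known CV.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng([int(seed), 303])
    truth = generate_truth(config, seed)
    design = build_design(config)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    base = truth.gene_baseline.to_numpy()[:, None]
    noise = np.exp(rng.normal(0.0, sigma, (len(truth.gene_ids), len(design.sample_ids))))
    # mean-preserving lognormal: E[exp(N(-s^2/2, s^2))] = 1
    values = base * noise * np.exp(-sigma ** 2 / 2)
    m = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(truth.gene_ids, name="gene_id"),
                            columns=design.sample_ids),
        platform=Platform.COUNT, scale=Scale.NORMALIZED)
    return m, design


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, str]:
    """Write the full dataset as plain-text files; returns name -> path."""
    from .panel_io import (write_expression_matrix, write_panel_annotation,
                           write_rcc_lite, write_sample_table)
    out = Path(out_dir)
    (out / "rcc").mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    write_panel_annotation(ds.panel, out / "panel.csv")
    paths["panel"] = str(out / "panel.csv")
    write_sample_table(ds.design, out / "samples.csv")
    paths["samples"] = str(out / "samples.csv")
    for lane in ds.lanes:
        write_rcc_lite(lane, ds.panel, out / "rcc" / f"{lane.sample_id}.rcc.csv")
    paths["rcc_dir"] = str(out / "rcc")
    write_expression_matrix(ds.count_raw, out / "count_raw.tsv")
    paths["count_raw"] = str(out / "count_raw.tsv")
    write_expression_matrix(ds.array_norm, out / "array_normalized.tsv")
    paths["array_norm"] = str(out / "array_normalized.tsv")
    write_expression_matrix(ds.probe_level, out / "array_probe_level.tsv")
    paths["probe_level"] = str(out / "array_probe_level.tsv")
    ds.array_annotation.to_csv(out / "array_annotation.csv", index=False)
    paths["array_annotation"] = str(out / "array_annotation.csv")
    ds.probe_positions.to_csv(out / "probe_positions.csv", index=False)
    paths["probe_positions"] = str(out / "probe_positions.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(ds.truth.to_json_dict(), fh, indent=1)
    paths["truth"] = str(out / "truth.json")
    return paths
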