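"""Data model and file I/O for panel annotations, lane counts, matrices, metadata.

Every downstream stage consumes only these types.  Three plain-text formats
are defined here:

* **panel CSV** — the codebook: ``probe_id,gene_symbol,code_class,nominal_conc``
  with ``code_class`` one of Endogenous / Housekeeping / Positive / Negative
  and ``nominal_conc`` the spike-in concentration in fM (positive controls
  only, 0 otherwise).
* **RCC-lite CSV** — a simplified sectioned dialect of the nCounter per-lane
  raw-count file: a ``<Lane_Attributes>`` block (ID, FovCount, FovCounted,
  BindingDensity) followed by a ``<Code_Summary>`` block
  (CodeClass,Name,Accession,Count).
* **matrix TSV** — gene x sample table, first column ``gene_id``, preceded by
  two sidecar header lines ``# platform=...`` and ``# scale=...`` so stages
  can refuse wrong-scale input.

Sample metadata travels as a CSV with columns
``sample_id,case_id,subtype,lab,day,operator,rna_mass_ng,qc_pass``.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("concordx")

__all__ = [
    "CodeClass",
    "Platform",
    "Scale",
    "PanelAnnotation",
    "LaneCounts",
    "ExpressionMatrix",
    "SampleTable",
    "FileFormatError",
    "read_panel_annotation",
    "write_panel_annotation",
    "read_rcc_lite",
    "write_rcc_lite",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "write_sample_table",
    "lanes_to_matrix",
]


class FileFormatError(ValueError):
    """Raised when an input file violates its documented layout."""


class CodeClass(str, Enum):
    ENDOGENOUS = "Endogenous"
    HOUSEKEEPING = "Housekeeping"
    POSITIVE = "Positive"
    NEGATIVE = "Negative"


class Platform(str, Enum):
    COUNT = "count_platform"
    ARRAY = "array_platform"


class Scale(str, Enum):
    RAW = "raw"
    NORMALIZED = "normalized"
    LOG2 = "log2"


# ---------------------------------------------------------------------------
# Panel annotation
# ---------------------------------------------------------------------------

@dataclass
class PanelAnnotation:
    """The probe codebook: class labels plus positive-control ladder.

    ``table`` has columns probe_id, gene_symbol, code_class (CodeClass),
    nominal_conc (fM; > 0 iff Positive).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["probe_id", "gene_symbol", "code_class", "nominal_conc"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FileFormatError(f"panel table missing columns: {missing}")
        if len(t) == 0:
            raise FileFormatError("no probes in panel")
        if t["probe_id"].duplicated().any():
            dups = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
            raise FileFormatError(f"duplicate probe_id(s): {dups}")
        try:
            t["code_class"] = t["code_class"].map(CodeClass)
        except ValueError as exc:  # unknown label
            raise FileFormatError(f"unknown code_class: {exc}") from exc
        conc = t["nominal_conc"].astype(float)
        pos = t["code_class"] == CodeClass.POSITIVE
        if (conc[pos] <= 0).any():
            bad = t.loc[pos & (conc <= 0), "probe_id"].tolist()
            raise FileFormatError(f"Positive probe(s) with nominal_conc <= 0: {bad}")
        if (conc[~pos] != 0).any():
            bad = t.loc[~pos & (conc != 0), "probe_id"].tolist()
            raise FileFormatError(f"non-Positive probe(s) with nominal_conc != 0: {bad}")
        ladder = np.sort(conc[pos].to_numpy())
        if len(ladder) != len(np.unique(ladder)):
            raise FileFormatError("positive-control nominal concentrations must be distinct")
        t["nominal_conc"] = conc
        self.table = t.reset_index(drop=True)

    # -- accessors ----------------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def probes(self, code_class: CodeClass) -> list[str]:
        """probe_ids of one class, in panel order."""
        mask = self.table["code_class"] == code_class
        return self.table.loc[mask, "probe_id"].tolist()

    @property
    def endogenous(self) -> list[str]:
        return self.probes(CodeClass.ENDOGENOUS)

    @property
    def housekeeping(self) -> list[str]:
        return self.probes(CodeClass.HOUSEKEEPING)

    @property
    def positive(self) -> list[str]:
        return self.probes(CodeClass.POSITIVE)

    @property
    def negative(self) -> list[str]:
        return self.probes(CodeClass.NEGATIVE)

    def class_counts(self) -> dict[str, int]:
        return {c.value: int((self.table["code_class"] == c).sum()) for c in CodeClass}

    def positive_ladder(self) -> pd.Series:
        """Positive-control nominal concentrations (fM), indexed by probe_id,
        sorted descending (the conventional ladder order)."""
        pos = self.table[self.table["code_class"] == CodeClass.POSITIVE]
        s = pos.set_index("probe_id")["nominal_conc"].astype(float)
        return s.sort_values(ascending=False)


def read_panel_annotation(path: str | Path) -> PanelAnnotation:
    """Read and validate a panel CSV; logs the per-class probe counts."""
    df = pd.read_csv(path, dtype={"probe_id": str, "gene_symbol": str, "code_class": str})
    if len(df) == 0:
        raise FileFormatError(f"no probes in panel file {path}")
    panel = PanelAnnotation(df)
    logger.info("panel %s: class counts %s", path, panel.class_counts())
    return panel


def write_panel_annotation(panel: PanelAnnotation, path: str | Path) -> None:
    out = panel.table.copy()
    out["code_class"] = out["code_class"].map(lambda c: c.value)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Lane counts (RCC-lite)
# ---------------------------------------------------------------------------

@dataclass
class LaneCounts:
    """One lane's raw probe counts plus imaging QC attributes."""

    sample_id: str
    counts: pd.Series  # index = probe_id, integer counts
    fov_requested: int
    fov_counted: int
    binding_density: float

    def __post_init__(self) -> None:
        if self.fov_requested <= 0:
            raise ValueError("fov_requested must be positive")
        if not 0 <= self.fov_counted <= self.fov_requested:
            raise ValueError("fov_counted must be in [0, fov_requested]")
        if self.binding_density < 0:
            raise ValueError("binding_density must be non-negative")
        counts = pd.Series(self.counts)
        if (counts < 0).any():
            raise ValueError("negative counts")
        self.counts = counts.astype(np.int64)

    @property
    def fov_ratio(self) -> float:
        return self.fov_counted / self.fov_requested


def read_rcc_lite(path: str | Path, panel: PanelAnnotation) -> LaneCounts:
    """Parse an RCC-lite lane file and align its counts to ``panel``.

    Probes present in the file but absent from the panel are dropped with a
    warning; a panel probe missing from the file is an error.  Row order in
    Code_Summary is irrelevant: counts are re-indexed to panel order.
    """
    text = Path(path).read_text()
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("</") and line.endswith(">"):
            current = None
        elif line.startswith("<") and line.endswith(">"):
            current = line[1:-1]
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    for required in ("Lane_Attributes", "Code_Summary"):
        if required not in sections:
            raise FileFormatError(f"{path}: missing <{required}> section")

    attrs: dict[str, str] = {}
    for line in sections["Lane_Attributes"]:
        key, _, value = line.partition(",")
        attrs[key.strip()] = value.strip()
    for key in ("ID", "FovCount", "FovCounted", "BindingDensity"):
        if key not in attrs:
            raise FileFormatError(f"{path}: Lane_Attributes missing {key}")

    body = "\n".join(sections["Code_Summary"])
    code = pd.read_csv(io.StringIO(body))
    for col in ("CodeClass", "Name", "Count"):
        if col not in code.columns:
            raise FileFormatError(f"{path}: Code_Summary missing column {col}")
    if code["Name"].duplicated().any():
        dups = code.loc[code["Name"].duplicated(), "Name"].tolist()
        raise FileFormatError(f"{path}: duplicate probe Name(s) {dups}")

    counts = code.set_index("Name")["Count"].astype(np.int64)
    unknown = counts.index.difference(panel.probe_ids)
    if len(unknown) > 0:
        warnings.warn(
            f"{path}: {len(unknown)} probe(s) not in panel dropped: "
            f"{sorted(unknown)[:5]}...",
            stacklevel=2,
        )
        counts = counts.drop(unknown)
    absent = panel.probe_ids.difference(counts.index)
    if len(absent) > 0:
        raise FileFormatError(f"{path}: panel probe(s) absent from lane: {sorted(absent)[:5]}")
    counts = counts.reindex(panel.probe_ids)

    return LaneCounts(
        sample_id=attrs["ID"],
        counts=counts,
        fov_requested=int(attrs["FovCount"]),
        fov_counted=int(attrs["FovCounted"]),
        binding_density=float(attrs["BindingDensity"]),
    )


def write_rcc_lite(lane: LaneCounts, panel: PanelAnnotation, path: str | Path) -> None:
    cls = panel.table.set_index("probe_id")["code_class"]
    lines = [
        "<Lane_Attributes>",
        f"ID,{lane.sample_id}",
        f"FovCount,{lane.fov_requested}",
        f"FovCounted,{lane.fov_counted}",
        f"BindingDensity,{lane.binding_density!r}",
        "</Lane_Attributes>",
        "<Code_Summary>",
        "CodeClass,Name,Accession,Count",
    ]
    for probe_id, count in lane.counts.items():
        lines.append(f"{cls[probe_id].value},{probe_id},SYN_{probe_id},{int(count)}")
    lines.append("</Code_Summary>")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples matrix tagged with platform and scale.

    The scale tag advances only raw -> normalized -> log2; operations check it
    so a matrix cannot be background-subtracted twice or log-transformed on
    the wrong scale.
    """

    values: pd.DataFrame  # index = gene_id, columns = sample_id
    platform: Platform
    scale: Scale

    def __post_init__(self) -> None:
        v = self.values
        self.platform = Platform(self.platform)
        self.scale = Scale(self.scale)
        if v.index.duplicated().any():
            raise ValueError(f"duplicate gene_id(s): {v.index[v.index.duplicated()].tolist()}")
        if v.columns.duplicated().any():
            raise ValueError(f"duplicate sample_id(s): {v.columns[v.columns.duplicated()].tolist()}")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("missing cells in expression matrix")
        # linear-scale intensities cannot be negative; log2 values may be
        if self.scale != Scale.LOG2 and (arr < 0).any():
            raise ValueError("negative expression values")
        self.values = v.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def with_values(self, values: pd.DataFrame, scale: Scale | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, platform=self.platform,
                                scale=self.scale if scale is None else scale)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample_id(s): {missing}")
        return self.with_values(self.values[list(sample_ids)])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"unknown gene_id(s): {missing}")
        return self.with_values(self.values.loc[list(gene_ids)])


def _float_repr(x: float) -> str:
    """Shortest decimal string that round-trips, integers without '.0'."""
    if x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(float(x))


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix TSV with sidecar ``# platform=`` / ``# scale=`` lines.

    Float formatting uses the shortest round-tripping representation so
    write -> read -> write is byte-identical.
    """
    with open(path, "w") as fh:
        fh.write(f"# platform={m.platform.value}\n")
        fh.write(f"# scale={m.scale.value}\n")
        fh.write("gene_id\t" + "\t".join(map(str, m.sample_ids)) + "\n")
        arr = m.values.to_numpy(dtype=float)
        for gene, row in zip(m.gene_ids, arr):
            fh.write(str(gene) + "\t" + "\t".join(_float_repr(x) for x in row) + "\n")


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    for key in ("platform", "scale"):
        if key not in meta:
            raise FileFormatError(f"{path}: missing sidecar header '# {key}='")
    if body_start >= len(lines):
        raise FileFormatError(f"{path}: no table body")
    header = lines[body_start].split("\t")
    if header[0] != "gene_id":
        raise FileFormatError(f"{path}: first column must be gene_id, got {header[0]!r}")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FileFormatError(f"{path}: duplicate sample column name")
    n_cols = len(header)
    genes: list[str] = []
    rows: list[list[float]] = []
    for ln, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise FileFormatError(f"{path}:{ln}: ragged row ({len(fields)} fields, expected {n_cols})")
        genes.append(fields[0])
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise FileFormatError(f"{path}:{ln}: non-numeric cell ({exc})") from exc
    if len(set(genes)) != len(genes):
        raise FileFormatError(f"{path}: duplicate gene_id")
    values = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    return ExpressionMatrix(values=values, platform=Platform(meta["platform"]), scale=Scale(meta["scale"]))


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

SUBTYPES = ("TNB", "ERpos")
LABS = ("Lab1", "Lab2")


@dataclass
class SampleTable:
    """Per-sample study metadata (case, subtype, lab, day, operator, mass)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["sample_id", "case_id", "subtype", "lab", "day",
                    "operator", "rna_mass_ng", "qc_pass"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FileFormatError(f"sample table missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            raise FileFormatError("duplicate sample_id in sample table")
        bad_subtype = set(t["subtype"]) - set(SUBTYPES)
        if bad_subtype:
            raise FileFormatError(f"unknown subtype(s): {sorted(bad_subtype)}")
        if t.duplicated(subset=["case_id", "lab", "day"]).any():
            raise FileFormatError("(case_id, lab, day) not unique")
        t["day"] = t["day"].astype(int)
        t["rna_mass_ng"] = t["rna_mass_ng"].astype(float)
        if (t["rna_mass_ng"] <= 0).any():
            raise FileFormatError("rna_mass_ng must be positive")
        t["qc_pass"] = t["qc_pass"].astype(bool)
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def samples_where(self, **conditions) -> list[str]:
        """sample_ids matching all column=value conditions (value may be a list)."""
        mask = pd.Series(True, index=self.table.index)
        for col, value in conditions.items():
            if isinstance(value, (list, tuple, set, frozenset)):
                mask &= self.table[col].isin(list(value))
            else:
                mask &= self.table[col] == value
        return self.table.loc[mask, "sample_id"].tolist()

    def lookup(self, sample_id: str) -> pd.Series:
        row = self.table[self.table["sample_id"] == sample_id]
        if len(row) != 1:
            raise KeyError(sample_id)
        return row.iloc[0]

    def subset(self, sample_ids: Iterable[str]) -> "SampleTable":
        ids = list(sample_ids)
        return SampleTable(self.table[self.table["sample_id"].isin(ids)].copy())


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, dtype={"sample_id": str, "case_id": str, "operator": str})
    return SampleTable(df)


def write_sample_table(meta: SampleTable, path: str | Path) -> None:
    meta.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def lanes_to_matrix(lanes: Sequence[LaneCounts], panel: PanelAnnotation) -> ExpressionMatrix:
    """Stack lane count vectors into a raw count-platform matrix (panel order)."""
    if len(lanes) == 0:
        raise ValueError("no lanes")
    ids = [lane.sample_id for lane in lanes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate lane sample_id")
    values = pd.DataFrame(
        {lane.sample_id: lane.counts.reindex(panel.probe_ids) for lane in lanes},
        index=pd.Index(panel.probe_ids, name="gene_id"),
    )
    if values.isna().any().any():
        raise ValueError("lane counts not aligned to panel")
    return ExpressionMatrix(values=values, platform=Platform.COUNT, scale=Scale.RAW)
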