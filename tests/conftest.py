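"""Shared fixtures: the default simulated study, built once per session."""

from __future__ import annotations

import warnings

import pytest

from concordx import concordance as cc
from concordx import nanostring as ns
from concordx import synthetic_data as sd


@pytest.fixture(scope="session")
def dataset() -> sd.SyntheticDataset:
    """Default study: 346 probes, 60 samples, 2 planted outliers, 16 planted
    discordant genes, seed 1."""
    return sd.simulate_dataset(sd.SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def normalized(dataset):
    """(normalized count matrix, factors) from the full chain."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ns.normalize_chain(dataset.count_raw, dataset.panel)


@pytest.fixture(scope="session")
def qc_passed(dataset) -> list[str]:
    qc = ns.qc_lanes(dataset.lanes, dataset.panel)
    return qc.index[qc["pass"]].tolist()


@pytest.fixture(scope="session")
def gene_map(dataset) -> cc.GeneMap:
    return cc.build_gene_map(dataset.panel, dataset.array_annotation, dataset.array_norm)


@pytest.fixture(scope="session")
def fold_changes(dataset, normalized, qc_passed, gene_map):
    """Pooled ER+/TNB fold-change table on QC-passed samples."""
    norm, _ = normalized
    meta = dataset.design.subset(qc_passed)
    return cc.fold_change_table(
        norm.subset_samples(qc_passed),
        dataset.array_norm.subset_samples(qc_passed),
        meta, gene_map)


@pytest.fixture(scope="session")
def log2_endogenous(dataset, normalized, qc_passed):
    """log2 normalized endogenous+housekeeping matrix, QC-passed samples."""
    norm, _ = normalized
    genes = dataset.panel.endogenous + dataset.panel.housekeeping
    return ns.log2_transform(norm).subset_genes(genes).subset_samples(qc_passed)
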