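"""Shared fixtures: small simulated datasets and matrix-building helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from popseq import calls as C
from popseq.genotype_io import GenotypeMatrix
from popseq.popsim import SimConfig, simulate


def make_matrix(
    rows: list[str],
    population_type: str = "RIL",
    quality: list[float] | None = None,
    depth: np.ndarray | None = None,
    gq: np.ndarray | None = None,
    contig_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from call strings like ``"ABHU"`` (one per site)."""
    calls = np.vstack([C.from_strings(list(r)) for r in rows])
    n_sites, n_ind = calls.shape
    sites = pd.DataFrame(
        {
            "marker_id": [f"s{i + 1}" for i in range(n_sites)],
            "contig_id": contig_ids or [f"c{i + 1}" for i in range(n_sites)],
            "position": np.arange(1, n_sites + 1),
            "quality": quality if quality is not None else [99.0] * n_sites,
        }
    )
    return GenotypeMatrix(
        sites=sites,
        calls=calls,
        individuals=[f"ind{j + 1}" for j in range(n_ind)],
        population_type=population_type,
        depth=depth,
        gq=gq,
    )


@pytest.fixture(scope="session")
def sim_small():
    """A small but complete simulated experiment (shared, read-only)."""
    cfg = SimConfig(
        n_framework_markers=300,
        n_contigs=400,
        n_individuals=60,
        n_clones=40,
        seed=42,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def sim_denovo():
    """High-SNP contigs for de novo map construction (shared, read-only)."""
    cfg = SimConfig(
        n_chromosomes=3,
        n_framework_markers=60,
        n_contigs=240,
        snps_per_contig_min=10,
        snps_per_contig_mean=20,
        n_individuals=90,
        n_clones=0,
        seed=42,
    )
    return simulate(cfg)
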