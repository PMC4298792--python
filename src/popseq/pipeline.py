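"""End-to-end pipeline driver and run configuration.

A run executes: genotype filtering -> framework map (loaded, simulated or
built de novo) -> SNP placement -> contig anchoring -> optional validation,
and writes every stage output as plain TSV plus a JSON run manifest (inputs,
parameters, per-stage counts, seed, version).  Reruns with the same
configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .anchoring import anchor_all, write_anchors
from .concordance import pair_concordance
from .framework import FrameworkMap, read_framework, write_framework
from .genotype_io import (
    GenotypeMatrix,
    filter_genotypes,
    filter_sites,
    read_matrix,
    read_vcf,
    write_matrix,
)
from .mapbuilder import MapBuilderParams, build_map
from .placement import PlacementParams, place_all, write_placed
from .popsim import SimConfig, simulate, write_outputs

log = logging.getLogger(__name__)


@dataclass
class FilterParams:
    """Genotype- and site-level filter thresholds (see genotype_io)."""

    hom_min_depth: int = 1
    hom_min_gq: float = 3.0
    het_min_depth: int = 3
    het_min_gq: float = 5.0
    min_quality: float = 40.0
    max_het_frac: float = 0.10
    max_missing_frac: float = 0.80
    min_maf: float = 0.05


@dataclass
class AnchorParams:
    min_chrom_frac: float = 0.80
    max_mad_cm: float = 5.0
    denominator: str = "mapped"


@dataclass
class RunConfig:
    """Full pipeline configuration; serializable to/from YAML.

    Exactly one input source: either ``sim`` (the built-in simulator) or
    ``vcf``/``matrix`` paths.  ``framework`` is a framework-map TSV path or
    the string ``"denovo"`` to build the map from the population data itself.
    """

    outdir: str = "popseq_run"
    seed: int = 0
    population_type: str = "DH"
    vcf: str | None = None
    matrix: str | None = None
    framework: str | None = None
    lengths: str | None = None
    links: str | None = None
    sim: SimConfig | None = None
    filter: FilterParams = field(default_factory=FilterParams)
    placement: PlacementParams = field(default_factory=PlacementParams)
    anchor: AnchorParams = field(default_factory=AnchorParams)
    mapbuilder: MapBuilderParams = field(default_factory=MapBuilderParams)


def _build_dataclass(cls, data: dict):
    """Instantiate a (possibly nested) dataclass from a dict, rejecting unknown keys."""
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        sub = {
            "sim": SimConfig, "filter": FilterParams, "placement": PlacementParams,
            "anchor": AnchorParams, "mapbuilder": MapBuilderParams,
        }.get(key)
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _build_dataclass(sub, value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build_dataclass(RunConfig, data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}

    # --- inputs -----------------------------------------------------------
    lengths = None
    links = None
    fmap: FrameworkMap | None = None
    if cfg.sim is not None:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed,
                                      population_type=cfg.population_type)
        sim = simulate(sim_cfg)
        write_outputs(sim, outdir / "sim")
        matrix = sim.matrix
        lengths = sim.contig_lengths
        links = sim.links
        if cfg.framework != "denovo":
            fmap = sim.framework
    else:
        if cfg.vcf:
            matrix = read_vcf(cfg.vcf, population_type=cfg.population_type)
        elif cfg.matrix:
            matrix = read_matrix(cfg.matrix, population_type=cfg.population_type)
        else:
            raise ValueError("no input: set sim, vcf or matrix in the configuration")
        if cfg.framework and cfg.framework != "denovo":
            fmap = read_framework(cfg.framework)
            if set(fmap.individuals) <= set(matrix.individuals) and set(
                fmap.individuals
            ) != set(matrix.individuals):
                # drop extra VCF columns (e.g. parents) not in the map population
                keep = [matrix.individuals.index(i) for i in fmap.individuals]
                matrix = GenotypeMatrix(
                    sites=matrix.sites,
                    calls=matrix.calls[:, keep],
                    individuals=list(fmap.individuals),
                    population_type=matrix.population_type,
                    depth=None if matrix.depth is None else matrix.depth[:, keep],
                    gq=None if matrix.gq is None else matrix.gq[:, keep],
                )
        if cfg.lengths:
            import pandas as pd

            lengths = pd.read_csv(cfg.lengths, sep="\t")
        if cfg.links:
            import pandas as pd

            links = pd.read_csv(cfg.links, sep="\t")
    counts["n_sites_input"] = matrix.n_sites
    counts["n_individuals"] = matrix.n_individuals

    # --- filtering --------------------------------------------------------
    f = cfg.filter
    if matrix.depth is not None:
        matrix = filter_genotypes(matrix, f.hom_min_depth, f.hom_min_gq,
                                  f.het_min_depth, f.het_min_gq)
    matrix = filter_sites(matrix, f.min_quality, f.max_het_frac,
                          f.max_missing_frac, f.min_maf)
    counts["n_sites_filtered"] = matrix.n_sites
    write_matrix(matrix, outdir / "matrix_filtered.tsv")

    # --- framework --------------------------------------------------------
    if cfg.framework == "denovo":
        fmap, build_report = build_map(matrix, cfg.mapbuilder)
        counts["mapbuilder"] = build_report
    if fmap is None:
        raise ValueError("no framework map: set framework to a path or 'denovo'")
    write_framework(fmap, outdir / "framework_used.tsv")
    counts["n_framework_markers"] = fmap.n_markers

    # --- placement and anchoring -----------------------------------------
    placed = place_all(matrix, fmap, cfg.placement)
    write_placed(placed, outdir / "placed.tsv")
    status_counts: dict[str, int] = {}
    for p in placed:
        status_counts[p.status] = status_counts.get(p.status, 0) + 1
    counts["placement"] = status_counts

    anchors, summary = anchor_all(
        placed, lengths, cfg.anchor.min_chrom_frac, cfg.anchor.max_mad_cm,
        cfg.anchor.denominator,
    )
    write_anchors(anchors, outdir / "anchors.tsv")
    counts["anchoring"] = dataclasses.asdict(summary)

    # --- validation -------------------------------------------------------
    if links is not None and len(links):
        report = pair_concordance(anchors, links)
        counts["concordance"] = dataclasses.asdict(report)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
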