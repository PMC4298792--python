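"""Synthetic bi-parental population sequencing with full ground truth.

The generator is the test substrate for every other module.  It emulates a
POPSEQ experiment end to end:

* a genome of ``n_chromosomes`` chromosomes of ``chrom_length_cm`` cM each,
  with framework markers and WGS contigs placed uniformly at random; a subset
  of contigs is bundled into clones (groups of physically adjacent contigs at
  one genetic position, standing in for ~100-200 kb BAC inserts);
* a doubled-haploid (DH) or recombinant-inbred (RIL) population from an F1:
  crossovers are Poisson with no interference (Haldane model), one meiosis
  per DH individual, ``ril_generations - 1`` rounds of selfing for RILs
  (leaving residual heterozygosity of about ``0.5^(g-1)`` per locus);
* a shallow-sequencing observation model: every true call is observed
  independently with probability ``call_rate`` (the Lander-Waterman covered
  fraction links this to fold-coverage), flipped to the opposite parental
  class with probability ``genotype_error``, and dressed with a plausible
  read depth and genotype quality so the genotype filters are exercisable.

SNPs on one contig are perfectly co-inherited.  The framework map receives
the *true* genotypes (array genotyping is essentially complete and
error-free) with one adjustment that real maps share: markers with identical
segregation patterns are genetically inseparable, so each co-segregation
group is collapsed to a single cM position (the median of its generating
positions).  All randomness flows from ``SimConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calls as C
from .concordance import lander_waterman_covered_fraction
from .framework import FrameworkMap, write_framework
from .genotype_io import GenotypeMatrix, write_matrix, write_vcf

log = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study conditions of a simulated POPSEQ experiment.

    Defaults emulate a 90-line DH population sequenced at ~1x per line
    (``call_rate`` 0.35 of 90 gives a mean of ~31-32 present calls per
    marker) against a 2,000-marker framework map on 7 x 150 cM chromosomes.
    """

    n_chromosomes: int = 7
    chrom_length_cm: float = 150.0
    n_framework_markers: int = 2000
    n_contigs: int = 5000
    snps_per_contig_mean: float = 3.0
    snps_per_contig_min: int = 1
    contig_length_median_bp: float = 1000.0
    contig_length_sigma: float = 0.7
    population_type: str = "DH"
    ril_generations: int = 8
    n_individuals: int = 90
    call_rate: float = 0.35
    genotype_error: float = 0.005
    residual_het: float = 0.0
    n_clones: int = 150
    clone_size_min: int = 2
    clone_size_max: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("call_rate", "genotype_error", "residual_het"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_chromosomes", "n_framework_markers", "n_contigs",
                     "n_individuals"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.population_type not in ("DH", "RIL"):
            raise ValueError("population_type must be DH or RIL")
        if self.snps_per_contig_mean < self.snps_per_contig_min:
            raise ValueError("snps_per_contig_mean must be >= snps_per_contig_min")


@dataclass
class SimTruth:
    """Ground truth of one simulated genome.

    ``framework``: marker_id, chromosome, cm; ``contigs``: contig_id,
    chromosome, cm, length_bp, n_snps, clone_id ('' = none); ``snps``:
    marker_id, contig_id, position, chromosome, cm; ``clones``: clone_id,
    clone_length.  ``crossovers`` (DH only) maps (individual index,
    chromosome) to the breakpoint positions of that gamete.
    """

    framework: pd.DataFrame
    contigs: pd.DataFrame
    snps: pd.DataFrame
    clones: pd.DataFrame
    chromosomes: list[str]
    crossovers: dict | None = None


@dataclass
class SimResult:
    """Everything a downstream pipeline consumes, plus the truth."""

    cfg: SimConfig
    truth: SimTruth
    framework: FrameworkMap
    matrix: GenotypeMatrix
    framework_calls: np.ndarray
    contig_calls: np.ndarray

    @property
    def contig_lengths(self) -> pd.DataFrame:
        return self.truth.contigs[["contig_id", "length_bp"]].copy()

    @property
    def links(self) -> pd.DataFrame:
        """Clone membership table (clone_id, contig_id, clone_length)."""
        members = self.truth.contigs.loc[
            self.truth.contigs["clone_id"] != "", ["clone_id", "contig_id"]
        ]
        return members.merge(self.truth.clones, on="clone_id", how="left").reset_index(
            drop=True
        )


def call_rate_from_depth(depth: float) -> float:
    """Expected genotype call rate at a given per-individual fold-coverage."""
    return lander_waterman_covered_fraction(depth)


# ---------------------------------------------------------------------------
# genome


def simulate_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Draw the framework-marker and contig skeleton of the genome."""
    rng = rng or np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    f_chrom = rng.integers(cfg.n_chromosomes, size=cfg.n_framework_markers)
    f_cm = rng.uniform(0, cfg.chrom_length_cm, size=cfg.n_framework_markers)
    order = np.lexsort((f_cm, f_chrom))
    framework = pd.DataFrame(
        {
            "marker_id": [f"fm{i:05d}" for i in range(cfg.n_framework_markers)],
            "chromosome": [chroms[c] for c in f_chrom[order]],
            "cm": f_cm[order],
        }
    )

    # clones first: bundles of co-located contigs
    clone_rows, contig_chrom, contig_cm, contig_clone = [], [], [], []
    if cfg.n_clones > 0:
        sizes = rng.integers(cfg.clone_size_min, cfg.clone_size_max + 1,
                             size=cfg.n_clones)
        while sizes.sum() > cfg.n_contigs and len(sizes):
            sizes = sizes[:-1]
        for k, size in enumerate(sizes):
            cid = f"clone{k:04d}"
            ch = int(rng.integers(cfg.n_chromosomes))
            cm = float(rng.uniform(0, cfg.chrom_length_cm))
            clone_rows.append((cid, int(rng.integers(100_000, 190_000))))
            for _ in range(size):
                contig_chrom.append(ch)
                contig_cm.append(cm)
                contig_clone.append(cid)
    n_free = cfg.n_contigs - len(contig_cm)
    contig_chrom += list(rng.integers(cfg.n_chromosomes, size=n_free))
    contig_cm += list(rng.uniform(0, cfg.chrom_length_cm, size=n_free))
    contig_clone += [""] * n_free

    lengths = np.maximum(
        rng.lognormal(np.log(cfg.contig_length_median_bp), cfg.contig_length_sigma,
                      size=cfg.n_contigs),
        200.0,
    ).astype(np.int64)
    if cfg.snps_per_contig_mean > cfg.snps_per_contig_min:
        p = 1.0 / (cfg.snps_per_contig_mean - cfg.snps_per_contig_min + 1)
        n_snps = cfg.snps_per_contig_min - 1 + rng.geometric(p, size=cfg.n_contigs)
    else:
        n_snps = np.full(cfg.n_contigs, cfg.snps_per_contig_min, dtype=np.int64)
    n_snps = np.minimum(n_snps, lengths)

    contigs = pd.DataFrame(
        {
            "contig_id": [f"ctg{i:05d}" for i in range(cfg.n_contigs)],
            "chromosome": [chroms[c] for c in contig_chrom],
            "cm": contig_cm,
            "length_bp": lengths,
            "n_snps": n_snps,
            "clone_id": contig_clone,
        }
    )

    snp_rows = []
    for row in contigs.itertuples(index=False):
        pos = np.sort(rng.choice(int(row.length_bp), size=int(row.n_snps),
                                 replace=False)) + 1
        for p_ in pos:
            snp_rows.append(
                (f"{row.contig_id}_{p_}", row.contig_id, int(p_),
                 row.chromosome, row.cm)
            )
    snps = pd.DataFrame(
        snp_rows, columns=["marker_id", "contig_id", "position", "chromosome", "cm"]
    )
    clones = pd.DataFrame(clone_rows, columns=["clone_id", "clone_length"])
    return SimTruth(framework, contigs, snps, clones, chroms)


# ---------------------------------------------------------------------------
# population


def _meiosis(h1: np.ndarray, h2: np.ndarray, pos: np.ndarray, length_cm: float,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a pair of haplotypes: Poisson crossovers, no interference.

    Returns (gamete allele vector over ``pos``, breakpoint positions).
    """
    k = rng.poisson(length_cm / 100.0)
    cuts = np.sort(rng.uniform(0, length_cm, size=k))
    phase = (int(rng.integers(2)) + np.searchsorted(cuts, pos)) % 2
    return np.where(phase == 0, h1, h2), cuts


def simulate_population(
    truth: SimTruth, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """True genotypes of every framework marker and contig across individuals.

    Returns ``(framework_calls, contig_calls)`` int8 arrays aligned with
    ``truth.framework`` / ``truth.contigs`` rows.  SNPs on a contig are
    perfectly co-inherited, so contigs carry one genotype column each.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n_ind = cfg.n_individuals
    fcalls = np.empty((len(truth.framework), n_ind), dtype=np.int8)
    ccalls = np.empty((len(truth.contigs), n_ind), dtype=np.int8)
    crossovers: dict = {}

    for ch in truth.chromosomes:
        fidx = np.flatnonzero(truth.framework["chromosome"].to_numpy() == ch)
        cidx = np.flatnonzero(truth.contigs["chromosome"].to_numpy() == ch)
        pos = np.concatenate(
            [truth.framework["cm"].to_numpy()[fidx], truth.contigs["cm"].to_numpy()[cidx]]
        )
        nf = len(fidx)
        L = cfg.chrom_length_cm
        zeros = np.zeros(len(pos), dtype=np.int8)
        ones = np.ones(len(pos), dtype=np.int8)
        for ind in range(n_ind):
            if cfg.population_type == "DH":
                gamete, cuts = _meiosis(zeros, ones, pos, L, rng)
                geno = np.where(gamete == 0, C.A, C.B).astype(np.int8)
                crossovers[(ind, ch)] = cuts
            else:  # RIL: selfing from the F1 for (generations - 1) meioses
                h1, h2 = zeros, ones
                for _ in range(max(cfg.ril_generations - 1, 0)):
                    g1, _ = _meiosis(h1, h2, pos, L, rng)
                    g2, _ = _meiosis(h1, h2, pos, L, rng)
                    h1, h2 = g1, g2
                geno = np.where(
                    h1 == h2, np.where(h1 == 0, C.A, C.B), C.H
                ).astype(np.int8)
            if cfg.residual_het > 0:
                het = rng.random(len(pos)) < cfg.residual_het
                geno = np.where(het, C.H, geno).astype(np.int8)
            fcalls[fidx, ind] = geno[:nf]
            ccalls[cidx, ind] = geno[nf:]
    truth.crossovers = crossovers if cfg.population_type == "DH" else None
    return fcalls, ccalls


def framework_map_from_truth(
    truth: SimTruth, framework_calls: np.ndarray, individuals: list[str]
) -> FrameworkMap:
    """Assemble the framework map, collapsing co-segregation groups to one cM.

    Markers with identical true genotype vectors on one chromosome are
    genetically inseparable; each such group receives the median of its
    generating positions, as an estimated genetic map would.
    """
    cm = truth.framework["cm"].to_numpy().copy()
    chrom = truth.framework["chromosome"].to_numpy()
    for ch in truth.chromosomes:
        idx = np.flatnonzero(chrom == ch)
        groups: dict[bytes, list[int]] = {}
        for i in idx:
            groups.setdefault(framework_calls[i].tobytes(), []).append(i)
        for members in groups.values():
            cm[members] = np.median(cm[members])
    markers = pd.DataFrame(
        {
            "marker_id": truth.framework["marker_id"],
            "chromosome": chrom,
            "cm": cm,
        }
    )
    order = np.lexsort((cm, pd.factorize(chrom)[0]))
    return FrameworkMap(
        markers=markers.iloc[order].reset_index(drop=True),
        calls=framework_calls[order],
        individuals=list(individuals),
    )


# ---------------------------------------------------------------------------
# observation model


def _truncated_poisson(lam: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated Poisson sample (every observed call has >= 1 read)."""
    out = rng.poisson(lam, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = out == 0
    return out


def observe(
    truth: SimTruth,
    contig_calls: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Shallow-sequencing observation of every contig SNP.

    Each true call is observed with probability ``call_rate`` (else U) and
    flipped to the opposite parental class with probability
    ``genotype_error``; observed calls receive a zero-truncated Poisson read
    depth and a genotype quality of three per supporting read, sites a
    quality score around 75.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    contig_index = {c: i for i, c in enumerate(truth.contigs["contig_id"])}
    rows = truth.snps["contig_id"].map(contig_index).to_numpy()
    true = contig_calls[rows]  # (n_snps, n_ind)
    n_snps, n_ind = true.shape

    seen = rng.random(true.shape) < cfg.call_rate
    obs = np.where(seen, true, C.U).astype(np.int8)
    flip = seen & (rng.random(true.shape) < cfg.genotype_error)
    obs[flip & (true == C.A)] = C.B
    obs[flip & (true == C.B)] = C.A  # heterozygous calls are never flipped

    depth = np.full(true.shape, -1, dtype=np.int32)
    nz = int(seen.sum())
    depth[seen] = _truncated_poisson(1.0, nz, rng)
    gq = np.where(seen, np.minimum(depth * 3, 99), np.nan).astype(np.float32)

    qual = np.round(np.clip(rng.normal(75.0, 12.0, size=n_snps), 0, None), 1)
    sites = pd.DataFrame(
        {
            "marker_id": truth.snps["marker_id"],
            "contig_id": truth.snps["contig_id"],
            "position": truth.snps["position"].astype(np.int64),
            "quality": qual,
        }
    )
    return GenotypeMatrix(
        sites=sites,
        calls=obs,
        individuals=[f"ind{i + 1:03d}" for i in range(n_ind)],
        population_type=cfg.population_type,
        depth=depth,
        gq=gq,
    )


# ---------------------------------------------------------------------------
# driver


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full generator: genome -> population -> framework map -> observation."""
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_genome(cfg, rng)
    fcalls, ccalls = simulate_population(truth, cfg, rng)
    individuals = [f"ind{i + 1:03d}" for i in range(cfg.n_individuals)]
    fmap = framework_map_from_truth(truth, fcalls, individuals)
    matrix = observe(truth, ccalls, cfg, rng)
    return SimResult(cfg, truth, fmap, matrix, fcalls, ccalls)


def write_outputs(sim: SimResult, outdir: str | Path) -> dict[str, str]:
    """Write all simulator artifacts (TSV + VCF) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "framework": outdir / "framework.tsv",
        "vcf": outdir / "genotypes.vcf",
        "matrix": outdir / "matrix.tsv",
        "contig_lengths": outdir / "contig_lengths.tsv",
        "links": outdir / "links.tsv",
        "truth_framework": outdir / "truth_framework.tsv",
        "truth_contigs": outdir / "truth_contigs.tsv",
    }
    write_framework(sim.framework, paths["framework"])
    write_vcf(sim.matrix, paths["vcf"])
    write_matrix(sim.matrix, paths["matrix"])
    sim.contig_lengths.to_csv(paths["contig_lengths"], sep="\t", index=False)
    sim.links.to_csv(paths["links"], sep="\t", index=False)
    sim.truth.framework.to_csv(paths["truth_framework"], sep="\t", index=False,
                               float_format="%.6f")
    sim.truth.contigs.to_csv(paths["truth_contigs"], sep="\t", index=False,
                             float_format="%.6f")
    return {k: str(v) for k, v in paths.items()}
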