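"""Population genotype matrices: VCF input, TSV round-trip and the call/site filters.

The central container is :class:`GenotypeMatrix`, a sites x individuals matrix
of parental-origin calls (see :mod:`popseq.calls`) with per-site metadata
(contig, position, site quality) and, when read from a VCF, per-call read
depth and genotype quality.

Filtering happens in two stages and in this order:

1. :func:`filter_genotypes` -- per-call thresholds on supporting read depth
   and genotype quality.  Homozygous calls need at least one supporting read
   and genotype quality >= 3; heterozygous calls need at least three reads and
   quality >= 5.  In a doubled-haploid (DH) population heterozygous calls are
   always discarded, since a DH individual cannot be heterozygous.
2. :func:`filter_sites` -- whole-site thresholds: site quality >= 40, at most
   10% of all samples heterozygous, at most 80% missing data, and minor allele
   frequency (computed on the non-missing calls, with H contributing half an
   allele to each parent) >= 5%.

The denominators are deliberately asymmetric: the heterozygosity and
missingness fractions are taken over *all* samples, whereas MAF is taken over
the non-missing calls only.

:func:`gbs_map_site_filter` applies the stricter site criteria used before
constructing a genetic map from genotyping-by-sequencing (GBS) calls: <= 10%
missing, <= 10% heterozygous, and a parental allele-count imbalance
``|A - B| / (A + B) <= 0.648`` (H contributes half to each side), which in the
absence of heterozygous calls equals a minimum MAF of 17.6%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import calls as C

log = logging.getLogger(__name__)

POPULATION_TYPES = ("RIL", "DH")

#: columns of the per-site metadata frame
SITE_COLUMNS = ["marker_id", "contig_id", "position", "quality"]


@dataclass
class SiteRecord:
    """One variant site: metadata plus the call vector across the population."""

    marker_id: str
    contig_id: str
    position: int
    quality: float
    calls: np.ndarray
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None


@dataclass
class GenotypeMatrix:
    """Sites x individuals matrix of parental-origin genotype calls.

    Attributes
    ----------
    sites:
        DataFrame with columns ``marker_id, contig_id, position, quality``.
    calls:
        ``(n_sites, n_individuals)`` int8 array of call codes.
    individuals:
        Ordered sample ids; unique.
    population_type:
        ``"RIL"`` or ``"DH"``.
    depth, gq:
        Optional per-call read depth (int, ``-1`` = absent) and genotype
        quality (float, ``NaN`` = absent), same shape as ``calls``.
    """

    sites: pd.DataFrame
    calls: np.ndarray
    individuals: list[str]
    population_type: str
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.population_type not in POPULATION_TYPES:
            raise ValueError(f"population_type must be one of {POPULATION_TYPES}")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.individuals)):
            raise ValueError("calls shape does not match sites x individuals")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("individual ids are not unique")
        key = self.sites[["contig_id", "position"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                f"duplicate site {dup.contig_id}:{dup.position} in genotype matrix"
            )
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def site_records(self) -> Iterator[SiteRecord]:
        for i, row in enumerate(self.sites.itertuples(index=False)):
            yield SiteRecord(
                marker_id=row.marker_id,
                contig_id=row.contig_id,
                position=int(row.position),
                quality=float(row.quality),
                calls=self.calls[i],
                depth=None if self.depth is None else self.depth[i],
                gq=None if self.gq is None else self.gq[i],
            )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to sites where ``mask`` is True (order kept)."""
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            calls=self.calls[mask],
            individuals=list(self.individuals),
            population_type=self.population_type,
            depth=None if self.depth is None else self.depth[mask],
            gq=None if self.gq is None else self.gq[mask],
        )


# ---------------------------------------------------------------------------
# VCF input / output


def read_vcf(
    path: str | Path,
    individuals: Sequence[str] | None = None,
    population_type: str = "RIL",
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept (multi-allelic and indel records are
    skipped with a logged count).  The REF allele maps to A -- reads are
    assumed to have been mapped against the reference parent's assembly --
    ALT to B, heterozygous calls to H and missing genotypes to U.

    Parameters
    ----------
    individuals:
        Optional subset (and ordering) of sample ids to keep; must be a subset
        of the VCF samples.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    if individuals is not None:
        missing = [s for s in individuals if s not in samples]
        if missing:
            raise ValueError(f"individuals not present in VCF: {missing}")
        keep_idx = np.array([samples.index(s) for s in individuals])
        samples = list(individuals)
    else:
        keep_idx = None

    # cyvcf2 gt_types with gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
    gt_map = np.array([C.A, C.H, C.B, C.U], dtype=np.int8)

    rows, mids, ctgs, poss, quals, dps, gqs = [], [], [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if "GT" not in v.FORMAT:
            raise ValueError(f"record {v.CHROM}:{v.POS} has no GT field")
        if (not v.is_snp) or len(v.ALT) != 1:
            n_skipped += 1
            continue
        gt = gt_map[np.asarray(v.gt_types)]
        dp = v.format("DP")
        if dp is None:
            dp_row = np.full(len(vcf.samples), -1, dtype=np.int32)
        else:
            dp_row = dp.reshape(-1).astype(np.int32)
            dp_row[dp_row < 0] = -1
        gq = v.format("GQ")
        if gq is None:
            gq_row = np.full(len(vcf.samples), np.nan, dtype=np.float32)
        else:
            gq_row = gq.reshape(-1).astype(np.float32)
            gq_row[gq_row < 0] = np.nan
        if keep_idx is not None:
            gt, dp_row, gq_row = gt[keep_idx], dp_row[keep_idx], gq_row[keep_idx]
        rows.append(gt)
        dps.append(dp_row)
        gqs.append(gq_row)
        ctgs.append(v.CHROM)
        poss.append(v.POS)
        mids.append(f"{v.CHROM}_{v.POS}")
        quals.append(np.nan if v.QUAL is None else float(v.QUAL))
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    n = len(rows)
    sites = pd.DataFrame(
        {
            "marker_id": mids,
            "contig_id": ctgs,
            "position": np.asarray(poss, dtype=np.int64),
            "quality": np.asarray(quals, dtype=float),
        }
    )
    shape = (n, len(samples))
    return GenotypeMatrix(
        sites=sites,
        calls=np.vstack(rows) if n else np.empty(shape, dtype=np.int8),
        individuals=samples,
        population_type=population_type,
        depth=np.vstack(dps) if n else np.empty(shape, dtype=np.int32),
        gq=np.vstack(gqs) if n else np.empty(shape, dtype=np.float32),
    )


_GT_STR = {int(C.A): "0/0", int(C.B): "1/1", int(C.H): "0/1", int(C.U): "./."}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=popseq
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_vcf(
    m: GenotypeMatrix,
    path: str | Path,
    parents: tuple[str, str] | None = ("ParentA", "ParentB"),
    parent_depth: int = 20,
    parent_gq: int = 99,
) -> None:
    """Write the matrix as a minimal VCF 4.2 text file.

    CHROM is the contig id and POS the 1-based SNP position; REF/ALT bases are
    placeholders (the package only tracks parental origin, not nucleotides).
    When ``parents`` is given, two extra columns carry the fixed parental
    genotypes (A parent ``0/0``, B parent ``1/1``) so that REF/ALT
    polarization is testable downstream.
    """
    cols = list(m.individuals)
    if parents is not None:
        cols = list(parents) + cols
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for ctg in pd.unique(m.sites["contig_id"]):
            fh.write(f"##contig=<ID={ctg}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(cols) + "\n")
        for i, row in enumerate(m.sites.itertuples(index=False)):
            qual = "." if np.isnan(row.quality) else f"{row.quality:.1f}"
            fields = [row.contig_id, str(int(row.position)), row.marker_id,
                      "A", "T", qual, ".", ".", "GT:DP:GQ"]
            if parents is not None:
                fields.append(f"0/0:{parent_depth}:{parent_gq}")
                fields.append(f"1/1:{parent_depth}:{parent_gq}")
            for j in range(m.n_individuals):
                call = int(m.calls[i, j])
                if call == C.U:
                    fields.append("./.:.:.")
                    continue
                dp = 1 if m.depth is None else max(int(m.depth[i, j]), 0)
                gq = 0 if m.gq is None else m.gq[i, j]
                gq = 0 if np.isnan(gq) else int(round(float(gq)))
                fields.append(f"{_GT_STR[call]}:{dp}:{gq}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# genotype-matrix TSV round-trip


def write_matrix(m: GenotypeMatrix, path: str | Path) -> None:
    """Write the genotype-matrix TSV (gzip transparently if path ends in .gz).

    Header: ``marker_id  contig_id  position  <individual ids...>`` with calls
    coded A/B/H/U.  Depth/quality annotations are not carried (the TSV is the
    post-filtering interchange format).
    """
    df = pd.DataFrame(
        {
            "marker_id": m.sites["marker_id"],
            "contig_id": m.sites["contig_id"],
            "position": m.sites["position"].astype(np.int64),
        }
    )
    chars = C.to_strings(m.calls)
    for j, ind in enumerate(m.individuals):
        df[ind] = chars[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, population_type: str = "RIL") -> GenotypeMatrix:
    """Read a genotype-matrix TSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "marker_id": str})
    fixed = ["marker_id", "contig_id", "position"]
    if df.columns[: len(fixed)].tolist() != fixed:
        raise ValueError(f"matrix TSV must start with columns {fixed}")
    inds = df.columns[len(fixed):].tolist()
    calls = np.column_stack(
        [C.from_strings(df[c].astype(str).values) for c in inds]
    ) if inds else np.empty((len(df), 0), dtype=np.int8)
    sites = df[fixed].copy()
    sites["quality"] = np.nan
    return GenotypeMatrix(
        sites=sites,
        calls=calls,
        individuals=inds,
        population_type=population_type,
    )


# ---------------------------------------------------------------------------
# filters


def filter_genotypes(
    m: GenotypeMatrix,
    hom_min_depth: int = 1,
    hom_min_gq: float = 3.0,
    het_min_depth: int = 3,
    het_min_gq: float = 5.0,
) -> GenotypeMatrix:
    """Apply per-call depth/quality thresholds; failing calls become U.

    Calls lacking depth or genotype-quality annotations fail (shallow-coverage
    data should always carry depth).  For DH populations every heterozygous
    call is discarded regardless of its support.  Matrix shape is unchanged.
    """
    calls = m.calls.copy()
    n = calls.shape
    dp = m.depth if m.depth is not None else np.full(n, -1, dtype=np.int32)
    gq = m.gq if m.gq is not None else np.full(n, np.nan, dtype=np.float32)

    hom = (calls == C.A) | (calls == C.B)
    het = calls == C.H
    # NaN comparisons are False, so absent annotations fail the filter
    with np.errstate(invalid="ignore"):
        hom_ok = (dp >= hom_min_depth) & (gq >= hom_min_gq)
        het_ok = (dp >= het_min_depth) & (gq >= het_min_gq)
    calls[hom & ~hom_ok] = C.U
    if m.population_type == "DH":
        calls[het] = C.U
    else:
        calls[het & ~het_ok] = C.U
    n_dropped = int((calls != m.calls).sum())
    log.info("filter_genotypes: %d calls set to missing", n_dropped)
    return replace(m, calls=calls, sites=m.sites.copy())


def _call_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    na = (calls == C.A).sum(axis=1)
    nb = (calls == C.B).sum(axis=1)
    nh = (calls == C.H).sum(axis=1)
    nu = (calls == C.U).sum(axis=1)
    return na, nb, nh, nu


def minor_allele_frequency(calls: np.ndarray) -> np.ndarray:
    """Per-site MAF over non-missing calls; H contributes half to each allele.

    ``MAF = min(#A + #H/2, #B + #H/2) / (#A + #B + #H)``; 0 when no calls.
    """
    na, nb, nh, _ = _call_counts(np.atleast_2d(calls))
    denom = na + nb + nh
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.minimum(na + nh / 2.0, nb + nh / 2.0) / denom
    return np.where(denom > 0, maf, 0.0)


def filter_sites(
    m: GenotypeMatrix,
    min_quality: float = 40.0,
    max_het_frac: float = 0.10,
    max_missing_frac: float = 0.80,
    min_maf: float = 0.05,
) -> GenotypeMatrix:
    """Drop whole sites failing quality/heterozygosity/missingness/MAF rules.

    Retains exactly the sites with site quality >= ``min_quality``, H fraction
    (over all samples) <= ``max_het_frac``, missing fraction (over all
    samples) <= ``max_missing_frac`` and MAF >= ``min_maf``.  Retained calls
    are never altered; site order is preserved.  Expects genotype-level
    filtering (:func:`filter_genotypes`) to have been applied first.
    """
    n_ind = m.n_individuals
    _, _, nh, nu = _call_counts(m.calls)
    qual = m.sites["quality"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        keep = (
            (qual >= min_quality)
            & (nh / n_ind <= max_het_frac)
            & (nu / n_ind <= max_missing_frac)
            & (minor_allele_frequency(m.calls) >= min_maf)
        )
    out = m.subset_sites(keep)
    log.info("filter_sites: kept %d / %d sites", out.n_sites, m.n_sites)
    if out.n_sites == 0 and m.n_sites > 0:
        log.warning("filter_sites: no sites survived filtering")
    return out


def gbs_map_site_filter(
    m: GenotypeMatrix,
    max_missing: float = 0.10,
    max_het: float = 0.10,
    max_allele_imbalance: float = 0.648,
) -> GenotypeMatrix:
    """Site filter used before building a genetic map from GBS-style calls.

    Keeps sites with missing fraction <= ``max_missing``, heterozygous
    fraction <= ``max_het`` and parental allele imbalance
    ``|A - B| / (A + B) <= max_allele_imbalance`` where A, B are the parental
    allele counts with H contributing one half to each.  With no heterozygous
    calls, the default imbalance bound equals a minimum minor allele frequency
    of (1 - 0.648) / 2 = 17.6%.
    """
    n_ind = m.n_individuals
    na, nb, nh, nu = _call_counts(m.calls)
    denom = na + nb + nh  # |A' - B'| = |na - nb|; A' + B' = na + nb + nh
    with np.errstate(invalid="ignore", divide="ignore"):
        imbalance = np.where(denom > 0, np.abs(na - nb) / denom, 1.0)
    keep = (
        (nu / n_ind <= max_missing)
        & (nh / n_ind <= max_het)
        & (imbalance <= max_allele_imbalance)
    )
    out = m.subset_sites(keep)
    log.info("gbs_map_site_filter: kept %d / %d sites", out.n_sites, m.n_sites)
    return out
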