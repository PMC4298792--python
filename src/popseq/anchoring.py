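"""Aggregate placed SNPs per contig into a single genetic anchor.

A WGS contig is assigned a genetic position when its placed SNPs agree: at
least 80% of them on one chromosome and an (unscaled) median absolute
deviation of their cM coordinates below 5 cM.  The anchored cM is the median
cM of the SNPs on the winning chromosome.  By default the 80% denominator
counts only the SNPs that were themselves placed; ``denominator="all"``
counts every SNP detected on the contig instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .placement import PLACED, PlacedSNP

log = logging.getLogger(__name__)

ANCHORED = "ANCHORED"
REJECTED_CHROM = "REJECTED_CHROM"
REJECTED_MAD = "REJECTED_MAD"
NO_PLACED_SNPS = "NO_PLACED_SNPS"


@dataclass
class ContigAnchor:
    """A contig's final genetic assignment (the product the tool emits)."""

    contig_id: str
    status: str
    chromosome: str | None = None
    cm: float = np.nan
    n_snps_total: int = 0
    n_snps_placed: int = 0
    mad_cm: float = np.nan
    length_bp: int = 0


@dataclass
class AnchorSummary:
    """Per-run anchoring statistics (anchored count, cumulative and median length)."""

    n_contigs: int
    n_anchored: int
    anchored_length_bp: int
    median_anchored_length_bp: float


def anchor_contig(
    contig_id: str,
    placed: Iterable[PlacedSNP],
    min_chrom_frac: float = 0.80,
    max_mad_cm: float = 5.0,
    denominator: str = "mapped",
) -> ContigAnchor:
    """Anchor one contig from the placement records of its SNPs.

    Considering only PLACED SNPs: no placed SNP -> ``NO_PLACED_SNPS``; the
    majority chromosome must hold at least ``min_chrom_frac`` of the
    denominator (placed SNPs by default, all SNPs with ``denominator="all"``;
    chromosome ties reject); the MAD of the cM positions on that chromosome
    must be < ``max_mad_cm``.  Anchored cm = median cM on the winning
    chromosome.
    """
    placed = list(placed)
    bad = [p.contig_id for p in placed if p.contig_id != contig_id]
    if bad:
        raise ValueError(f"mixed contig ids for {contig_id!r}: found {bad[0]!r}")
    rec = ContigAnchor(contig_id, status=NO_PLACED_SNPS, n_snps_total=len(placed))
    ok = [p for p in placed if p.status == PLACED]
    rec.n_snps_placed = len(ok)
    if not ok:
        return rec
    chroms = pd.Series([p.chromosome for p in ok])
    counts = chroms.value_counts()
    top_count = counts.iloc[0]
    if (counts == top_count).sum() > 1:
        rec.status = REJECTED_CHROM
        return rec
    top = counts.index[0]
    denom = len(placed) if denominator == "all" else len(ok)
    if top_count / denom < min_chrom_frac:
        rec.status = REJECTED_CHROM
        return rec
    cm = np.array([p.cm for p in ok if p.chromosome == top])
    med = float(np.median(cm))
    mad = float(np.median(np.abs(cm - med)))
    rec.mad_cm = mad
    if mad >= max_mad_cm:
        rec.status = REJECTED_MAD
        return rec
    rec.status = ANCHORED
    rec.chromosome = top
    rec.cm = med
    return rec


def anchor_all(
    placed: Iterable[PlacedSNP],
    contig_lengths: Mapping[str, int] | pd.DataFrame | None = None,
    min_chrom_frac: float = 0.80,
    max_mad_cm: float = 5.0,
    denominator: str = "mapped",
) -> tuple[list[ContigAnchor], AnchorSummary]:
    """Anchor every contig appearing in ``placed`` (first-appearance order).

    Contigs missing from ``contig_lengths`` count with length 0 (warned).
    """
    if isinstance(contig_lengths, pd.DataFrame):
        contig_lengths = dict(
            zip(contig_lengths["contig_id"].astype(str), contig_lengths["length_bp"])
        )
    lengths = contig_lengths or {}
    groups: dict[str, list[PlacedSNP]] = {}
    for p in placed:
        groups.setdefault(p.contig_id, []).append(p)
    anchors: list[ContigAnchor] = []
    n_unknown_length = 0
    for cid, snps in groups.items():
        a = anchor_contig(cid, snps, min_chrom_frac, max_mad_cm, denominator)
        if cid in lengths:
            a.length_bp = int(lengths[cid])
        elif contig_lengths is not None:
            n_unknown_length += 1
        anchors.append(a)
    if n_unknown_length:
        log.warning(
            "anchor_all: %d contigs missing from the length table (length 0)",
            n_unknown_length,
        )
    anchored = [a for a in anchors if a.status == ANCHORED]
    summary = AnchorSummary(
        n_contigs=len(anchors),
        n_anchored=len(anchored),
        anchored_length_bp=int(sum(a.length_bp for a in anchored)),
        median_anchored_length_bp=(
            float(np.median([a.length_bp for a in anchored])) if anchored else 0.0
        ),
    )
    log.info(
        "anchor_all: %d/%d contigs anchored, %d bp cumulative",
        summary.n_anchored, summary.n_contigs, summary.anchored_length_bp,
    )
    return anchors, summary


def anchors_to_frame(anchors: Iterable[ContigAnchor]) -> pd.DataFrame:
    anchors = list(anchors)
    return pd.DataFrame(
        {
            "contig_id": [a.contig_id for a in anchors],
            "status": [a.status for a in anchors],
            "chromosome": [a.chromosome if a.chromosome else "" for a in anchors],
            "cm": [a.cm for a in anchors],
            "n_snps_total": [a.n_snps_total for a in anchors],
            "n_snps_placed": [a.n_snps_placed for a in anchors],
            "mad_cm": [a.mad_cm for a in anchors],
            "length_bp": [a.length_bp for a in anchors],
        }
    )


def write_anchors(anchors: Iterable[ContigAnchor], path: str | Path) -> None:
    df = anchors_to_frame(anchors)
    for col in ("cm", "mad_cm"):
        df[col] = df[col].map(lambda v: "" if np.isnan(v) else f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_anchors(path: str | Path) -> list[ContigAnchor]:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "chromosome": str})
    out = []
    for row in df.itertuples(index=False):
        chrom = row.chromosome if isinstance(row.chromosome, str) and row.chromosome else None
        out.append(
            ContigAnchor(
                contig_id=str(row.contig_id),
                status=row.status,
                chromosome=chrom,
                cm=float(row.cm) if not pd.isna(row.cm) else np.nan,
                n_snps_total=int(row.n_snps_total),
                n_snps_placed=int(row.n_snps_placed),
                mad_cm=float(row.mad_cm) if not pd.isna(row.mad_cm) else np.nan,
                length_bp=int(row.length_bp),
            )
        )
    return out
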