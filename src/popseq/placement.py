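"""Place population SNPs into a framework map by minimum-Hamming-distance search.

Each SNP's segregation pattern is compared against every framework marker;
the Hamming distance counts the individuals at which the two non-missing
calls differ.  All markers achieving the minimal distance are the SNP's
nearest neighbors (ties are kept, never broken).  A SNP is placed only if it
passes four sequential gates:

1. call rate  -- scored unequivocally (non-missing) on more than 20% of the
   individuals;
2. distance   -- minimal Hamming distance <= 2;
3. chromosome -- at least 80% of all nearest neighbors lie on one chromosome;
4. dispersion -- the median absolute deviation (MAD, unscaled) of the
   neighbors' cM positions on that chromosome is < 5 cM (15 for a map whose
   length is inflated by treating RILs as DH).

The placed cM is the median cM of the nearest neighbors on the winning
chromosome.  The batch search in :func:`place_all` uses one-hot matrix
products for speed but is contractually identical to the exhaustive
per-marker scan of :func:`nearest_neighbors`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calls as C
from .framework import FrameworkMap
from .genotype_io import GenotypeMatrix, SiteRecord

log = logging.getLogger(__name__)

PLACED = "PLACED"
REJECTED_CALLRATE = "REJECTED_CALLRATE"
REJECTED_DISTANCE = "REJECTED_DISTANCE"
REJECTED_CHROM = "REJECTED_CHROM"
REJECTED_MAD = "REJECTED_MAD"

STATUSES = (PLACED, REJECTED_CALLRATE, REJECTED_DISTANCE, REJECTED_CHROM, REJECTED_MAD)


@dataclass
class PlacementParams:
    """Thresholds of the four placement gates (defaults as described above)."""

    min_call_frac: float = 0.20
    max_distance: int = 2
    min_chrom_frac: float = 0.80
    max_mad_cm: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.min_call_frac < 1):
            raise ValueError("min_call_frac must be in (0, 1)")
        if self.max_distance < 0:
            raise ValueError("max_distance must be >= 0")
        if not (0.5 <= self.min_chrom_frac <= 1):
            raise ValueError("min_chrom_frac must be in [0.5, 1]")
        if self.max_mad_cm <= 0:
            raise ValueError("max_mad_cm must be > 0")


@dataclass
class PlacedSNP:
    """Outcome of placing one population SNP into the framework map."""

    marker_id: str
    contig_id: str
    position: int
    status: str
    chromosome: str | None = None
    cm: float = np.nan
    n_neighbors: int = 0
    min_distance: int | None = None
    winning_frac: float = np.nan
    mad_cm: float = np.nan


def hamming_distance(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    """Hamming distance between two call vectors.

    Returns ``(distance, overlap)``: overlap is the number of positions where
    both calls are non-missing, distance the number of those positions where
    the calls differ (A vs H and B vs H each count as one difference).
    """
    x = np.asarray(x, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    if x.shape != y.shape:
        raise ValueError(f"call vector length mismatch: {x.shape} vs {y.shape}")
    both = (x != C.U) & (y != C.U)
    return int((both & (x != y)).sum()), int(both.sum())


def nearest_neighbors(
    query: np.ndarray, fmap: FrameworkMap
) -> tuple[np.ndarray, int | None]:
    """All framework markers at minimal Hamming distance from ``query``.

    Markers with zero call overlap with the query are excluded from
    candidacy.  Returns ``(indices into fmap.markers, min_distance)``;
    an empty index array and ``None`` if no marker has positive overlap.
    """
    if fmap.n_markers == 0:
        raise ValueError("framework map is empty")
    query = np.asarray(query, dtype=np.int8)
    both = (fmap.calls != C.U) & (query != C.U)
    overlap = both.sum(axis=1)
    dist = (both & (fmap.calls != query)).sum(axis=1)
    cand = overlap > 0
    if not cand.any():
        return np.empty(0, dtype=np.int64), None
    dmin = int(dist[cand].min())
    return np.flatnonzero(cand & (dist == dmin)), dmin


def _gate(
    calls: np.ndarray,
    neigh: np.ndarray,
    dmin: int | None,
    chrom_codes: np.ndarray,
    chrom_names: list[str],
    cms: np.ndarray,
    params: PlacementParams,
    meta: tuple[str, str, int],
) -> PlacedSNP:
    """Apply the four sequential gates to a precomputed neighbor set."""
    marker_id, contig_id, position = meta
    rec = PlacedSNP(marker_id, contig_id, position, status=REJECTED_CALLRATE)
    n_ind = len(calls)
    n_called = int((calls != C.U).sum())
    if n_called <= params.min_call_frac * n_ind:
        return rec
    rec.min_distance = dmin
    rec.n_neighbors = len(neigh)
    if dmin is None or dmin > params.max_distance:
        rec.status = REJECTED_DISTANCE
        return rec
    counts = np.bincount(chrom_codes[neigh], minlength=len(chrom_names))
    top = int(counts.argmax())
    rec.winning_frac = counts[top] / len(neigh)
    if (counts == counts[top]).sum() > 1 or rec.winning_frac < params.min_chrom_frac:
        # a tie for the winning chromosome rejects deterministically
        rec.status = REJECTED_CHROM
        return rec
    on_top = neigh[chrom_codes[neigh] == top]
    cm = cms[on_top]
    med = float(np.median(cm))
    mad = float(np.median(np.abs(cm - med)))
    rec.mad_cm = mad
    if mad >= params.max_mad_cm:
        rec.status = REJECTED_MAD
        return rec
    rec.status = PLACED
    rec.chromosome = chrom_names[top]
    rec.cm = med
    return rec


def _chrom_arrays(fmap: FrameworkMap) -> tuple[np.ndarray, list[str], np.ndarray]:
    names = fmap.chromosomes
    rank = {c: i for i, c in enumerate(names)}
    codes = fmap.markers["chromosome"].map(rank).to_numpy(dtype=np.int64)
    return codes, names, fmap.markers["cm"].to_numpy(dtype=float)


def place_snp(
    site: SiteRecord | np.ndarray,
    fmap: FrameworkMap,
    params: PlacementParams | None = None,
) -> PlacedSNP:
    """Place a single SNP (see module docstring for the gate sequence)."""
    params = params or PlacementParams()
    if isinstance(site, SiteRecord):
        calls, meta = site.calls, (site.marker_id, site.contig_id, site.position)
    else:
        calls, meta = np.asarray(site, dtype=np.int8), ("", "", 0)
    if len(calls) != len(fmap.individuals):
        raise ValueError("site call vector length does not match map population")
    codes, names, cms = _chrom_arrays(fmap)
    # short-circuit: the call-rate gate precedes the neighbor search
    if int((calls != C.U).sum()) <= params.min_call_frac * len(calls):
        return PlacedSNP(*meta, status=REJECTED_CALLRATE)
    neigh, dmin = nearest_neighbors(calls, fmap)
    return _gate(calls, neigh, dmin, codes, names, cms, params, meta)


def _one_hot(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(stack of A/B/H indicator planes, non-missing indicator), float32."""
    planes = np.stack(
        [(calls == k).astype(np.float32) for k in (C.A, C.B, C.H)], axis=0
    )
    return planes, (calls != C.U).astype(np.float32)


def place_all(
    m: GenotypeMatrix,
    fmap: FrameworkMap,
    params: PlacementParams | None = None,
    chunk: int = 1024,
) -> list[PlacedSNP]:
    """Place every site of ``m``; one :class:`PlacedSNP` per site, order kept.

    The populations must coincide: same individual ids in both (a set
    mismatch is a hard error); if the orders differ the framework columns are
    aligned to the matrix order, which leaves all results unchanged.

    Distances are computed chunk-wise with one-hot matrix products
    (``distance = overlap - agreement``), exactly equal to the exhaustive
    scan of :func:`nearest_neighbors`.
    """
    params = params or PlacementParams()
    if set(m.individuals) != set(fmap.individuals):
        extra = sorted(set(m.individuals) ^ set(fmap.individuals))
        raise ValueError(f"individual sets differ between matrix and map: {extra}")
    fcalls = fmap.calls
    if list(m.individuals) != list(fmap.individuals):
        order = [fmap.individuals.index(i) for i in m.individuals]
        fcalls = fcalls[:, order]

    codes, names, cms = _chrom_arrays(fmap)
    mp, mn = _one_hot(fcalls)  # planes: (3, M, N); nonmissing: (M, N)

    out: list[PlacedSNP] = []
    meta_rows = list(
        zip(m.sites["marker_id"], m.sites["contig_id"], m.sites["position"])
    )
    for start in range(0, m.n_sites, chunk):
        q = m.calls[start : start + chunk]
        qp, qn = _one_hot(q)
        overlap = qn @ mn.T
        agree = sum(qp[k] @ mp[k].T for k in range(3))
        dist = overlap - agree
        for i in range(len(q)):
            cand = overlap[i] > 0
            if cand.any():
                dmin = int(dist[i][cand].min())
                neigh = np.flatnonzero(cand & (dist[i] == dmin))
            else:
                dmin, neigh = None, np.empty(0, dtype=np.int64)
            meta = meta_rows[start + i]
            out.append(
                _gate(q[i], neigh, dmin, codes, names, cms, params,
                      (str(meta[0]), str(meta[1]), int(meta[2])))
            )
    counts = pd.Series([r.status for r in out]).value_counts()
    log.info("place_all: %s", ", ".join(f"{k}={v}" for k, v in counts.items()))
    return out


def placed_to_frame(placed: list[PlacedSNP]) -> pd.DataFrame:
    """Tabulate placement outcomes (columns match the placed TSV format)."""
    return pd.DataFrame(
        {
            "marker_id": [p.marker_id for p in placed],
            "contig_id": [p.contig_id for p in placed],
            "position": [p.position for p in placed],
            "status": [p.status for p in placed],
            "chromosome": [p.chromosome if p.chromosome else "" for p in placed],
            "cm": [p.cm for p in placed],
            "min_distance": [-1 if p.min_distance is None else p.min_distance for p in placed],
            "n_neighbors": [p.n_neighbors for p in placed],
            "winning_frac": [p.winning_frac for p in placed],
            "mad_cm": [p.mad_cm for p in placed],
        }
    )


def write_placed(placed: list[PlacedSNP], path: str | Path) -> None:
    df = placed_to_frame(placed)
    for col in ("cm", "winning_frac", "mad_cm"):
        df[col] = df[col].map(lambda v: "" if np.isnan(v) else f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_placed(path: str | Path) -> list[PlacedSNP]:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "chromosome": str})
    out = []
    for row in df.itertuples(index=False):
        chrom = row.chromosome if isinstance(row.chromosome, str) and row.chromosome else None
        out.append(
            PlacedSNP(
                marker_id=str(row.marker_id),
                contig_id=str(row.contig_id),
                position=int(row.position),
                status=row.status,
                chromosome=chrom,
                cm=float(row.cm) if not pd.isna(row.cm) else np.nan,
                n_neighbors=int(row.n_neighbors),
                min_distance=None if row.min_distance < 0 else int(row.min_distance),
                winning_frac=float(row.winning_frac) if not pd.isna(row.winning_frac) else np.nan,
                mad_cm=float(row.mad_cm) if not pd.isna(row.mad_cm) else np.nan,
            )
        )
    return out
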