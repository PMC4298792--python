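"""Framework genetic maps: container, redundancy pruning and map projection.

A framework map is an ordered set of genetic markers, each with a chromosome,
a centiMorgan position and a genotype vector across the mapping population.
It is the target of the nearest-neighbor placement in :mod:`popseq.placement`.

Two maps of the same genome (e.g. built from different genotyping platforms)
live on different cM scales; :func:`project_map` translates coordinates
between them with a per-chromosome local linear (loess, tricube weights,
span 0.3 by default) regression fitted to anchor pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import calls as C

log = logging.getLogger(__name__)

MARKER_COLUMNS = ["marker_id", "chromosome", "cm"]


@dataclass
class FrameworkMarker:
    """One framework marker: id, chromosome, cM and its segregation pattern."""

    marker_id: str
    chromosome: str
    cm: float
    calls: np.ndarray


@dataclass
class FrameworkMap:
    """Ordered framework markers with their genotype vectors.

    ``markers`` has columns ``marker_id, chromosome, cm``; row ``i`` of
    ``calls`` is the genotype vector of marker ``i``.  Within each chromosome
    markers are sorted by non-decreasing cM (the constructor sorts, with a
    warning, if the input is not).  Chromosomes keep first-appearance order.
    """

    markers: pd.DataFrame
    calls: np.ndarray
    individuals: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.individuals)):
            raise ValueError("calls shape does not match markers x individuals")
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers.loc[self.markers["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r} in framework map")
        cm = pd.to_numeric(self.markers["cm"], errors="coerce")
        if cm.isna().any():
            bad = self.markers.loc[cm.isna(), "marker_id"].iloc[0]
            raise ValueError(f"non-numeric cm for marker {bad!r}")
        self.markers = self.markers.assign(cm=cm.astype(float)).reset_index(drop=True)

        chrom_rank = {c: i for i, c in enumerate(pd.unique(self.markers["chromosome"]))}
        key = np.lexsort(
            (self.markers["cm"].to_numpy(),
             self.markers["chromosome"].map(chrom_rank).to_numpy())
        )
        if not np.array_equal(key, np.arange(len(key))):
            log.warning("framework markers were not sorted by (chromosome, cm); sorting")
            self.markers = self.markers.iloc[key].reset_index(drop=True)
            self.calls = self.calls[key]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.markers["chromosome"]))

    def marker(self, i: int) -> FrameworkMarker:
        row = self.markers.iloc[i]
        return FrameworkMarker(row.marker_id, row.chromosome, float(row.cm), self.calls[i])


def read_framework(path: str | Path) -> FrameworkMap:
    """Read a framework map TSV: marker_id, chromosome, cm, then one column
    per individual with A/B/H/U calls."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    if df.columns[:3].tolist() != MARKER_COLUMNS:
        raise ValueError(f"framework TSV must start with columns {MARKER_COLUMNS}")
    inds = df.columns[3:].tolist()
    calls = (
        np.column_stack([C.from_strings(df[c].astype(str).values) for c in inds])
        if inds
        else np.empty((len(df), 0), dtype=np.int8)
    )
    return FrameworkMap(markers=df[MARKER_COLUMNS].copy(), calls=calls, individuals=inds)


def write_framework(fmap: FrameworkMap, path: str | Path) -> None:
    df = fmap.markers.copy()
    df["cm"] = df["cm"].map(lambda v: f"{v:.6f}")
    chars = C.to_strings(fmap.calls)
    for j, ind in enumerate(fmap.individuals):
        df[ind] = chars[:, j]
    df.to_csv(path, sep="\t", index=False)


def _compatible(x: np.ndarray, y: np.ndarray) -> bool:
    both = (x != C.U) & (y != C.U)
    return bool(np.all(x[both] == y[both]))


def prune_redundant(fmap: FrameworkMap) -> FrameworkMap:
    """Remove redundant markers: same (chromosome, cm) and a genotype vector
    that agrees at every position where both markers are non-missing.

    The agreement relation is not transitive, so groups are formed greedily in
    marker_id order: a marker is dropped iff it is compatible with an already
    retained marker at the same position.  The first marker at any
    (chromosome, cm) is always retained.
    """
    keep = np.ones(fmap.n_markers, dtype=bool)
    grouped = fmap.markers.groupby(["chromosome", "cm"], sort=False).indices
    for _, idx in grouped.items():
        idx = sorted(idx, key=lambda i: fmap.markers["marker_id"].iat[i])
        reps: list[int] = []
        for i in idx:
            if any(_compatible(fmap.calls[i], fmap.calls[r]) for r in reps):
                keep[i] = False
            else:
                reps.append(i)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("prune_redundant: removed %d redundant markers", n_drop)
    return FrameworkMap(
        markers=fmap.markers.loc[keep].reset_index(drop=True),
        calls=fmap.calls[keep],
        individuals=list(fmap.individuals),
    )


# ---------------------------------------------------------------------------
# loess map projection


def _loess_predict(
    x: np.ndarray, y: np.ndarray, xq: np.ndarray, span: float
) -> np.ndarray:
    """Local linear regression with tricube weights evaluated at ``xq``.

    For each query the ``k = ceil(span * n)`` nearest anchors define the
    neighborhood; weights are ``(1 - (d/h)^3)^3`` with ``h`` the neighborhood
    radius.  Queries outside the anchor range reuse the boundary neighborhood,
    i.e. they are linearly extrapolated from the boundary local fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = min(n, max(3, int(np.ceil(span * n))))
    out = np.empty(len(xq), dtype=float)
    for qi, q in enumerate(np.asarray(xq, dtype=float)):
        d = np.abs(x - q)
        h = np.partition(d, k - 1)[k - 1]
        if h <= 0:
            # all neighborhood anchors at the query position
            out[qi] = float(np.mean(y[d == 0]))
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        sw = w.sum()
        xm = (w @ x) / sw
        ym = (w @ y) / sw
        sxx = w @ (x - xm) ** 2
        if sxx <= 0:
            out[qi] = ym
            continue
        slope = (w @ ((x - xm) * (y - ym))) / sxx
        out[qi] = ym + slope * (q - xm)
    return out


def project_map(
    queries: Sequence[tuple[str, float]] | pd.DataFrame,
    anchors: pd.DataFrame | Mapping[str, Sequence[tuple[float, float]]],
    span: float = 0.3,
    min_anchors: int = 5,
) -> np.ndarray:
    """Project genetic positions from one map's scale onto another's.

    Parameters
    ----------
    queries:
        (chromosome, cm) pairs to project, or a DataFrame with columns
        ``chromosome`` and ``cm``.
    anchors:
        markers known on both maps: a DataFrame with columns ``chromosome,
        cm_source, cm_target`` or a mapping chromosome -> [(cm_source,
        cm_target), ...].
    span:
        loess smoother span (fraction of anchors in each local neighborhood).

    Returns
    -------
    Array of projected cm values, aligned with ``queries``; ``NaN`` for
    chromosomes with fewer than ``min_anchors`` anchors (warned).
    """
    if isinstance(queries, pd.DataFrame):
        q_chrom = queries["chromosome"].astype(str).to_numpy()
        q_cm = queries["cm"].to_numpy(dtype=float)
    else:
        q_chrom = np.array([str(c) for c, _ in queries])
        q_cm = np.array([float(v) for _, v in queries])
    if isinstance(anchors, pd.DataFrame):
        anchor_map = {
            str(ch): grp[["cm_source", "cm_target"]].to_numpy(dtype=float)
            for ch, grp in anchors.groupby("chromosome", sort=False)
        }
    else:
        anchor_map = {str(ch): np.asarray(p, dtype=float) for ch, p in anchors.items()}

    out = np.full(len(q_cm), np.nan)
    for ch in np.unique(q_chrom):
        sel = q_chrom == ch
        pairs = anchor_map.get(ch)
        if pairs is None or len(pairs) < min_anchors:
            log.warning(
                "project_map: chromosome %s has %d < %d anchors; returning NaN",
                ch, 0 if pairs is None else len(pairs), min_anchors,
            )
            continue
        out[sel] = _loess_predict(pairs[:, 0], pairs[:, 1], q_cm[sel], span)
    return out
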