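"""De novo framework-map construction from population-sequencing data alone.

Pipeline: contigs carrying many SNPs are *consensus genotyped* (each
individual's calls across the contig's SNPs are collapsed to a single A/B/U
call), pairwise recombination fractions and two-point LOD scores are computed
between all consensus markers, markers are clustered into linkage groups as
connected components of the LOD graph, each group is ordered along the
diameter path of its minimum-spanning tree, and cM positions are assigned by
accumulating map distances (Kosambi by default) between consecutive markers.

The two-point LOD is the log10 likelihood ratio of linkage at the estimated
recombination fraction r^ = k/n versus free recombination (r = 1/2)::

    LOD = k log10(r^) + (n - k) log10(1 - r^) + n log10(2)

with n informative meioses (both calls homozygous-parental) and k observed
recombinants; for k = 0 this is n log10(2), and for r^ = 1/2 it is 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import xlogy

from . import calls as C
from .framework import FrameworkMap
from .genotype_io import GenotypeMatrix

log = logging.getLogger(__name__)

_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# mapping functions


def _cap(d, cap_cm, fname):
    d = np.asarray(d, dtype=float)
    if cap_cm is not None and np.any(d > cap_cm):
        warnings.warn(f"{fname}: capping map distance at {cap_cm} cM")
        d = np.minimum(d, cap_cm)
    return d if d.ndim else float(d)


def _check_r(r, cap_cm, fname):
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError(f"{fname}: recombination fraction must be >= 0")
    if np.any(r >= 0.5):
        if cap_cm is None:
            raise ValueError(f"{fname}: r >= 0.5 has no finite map distance")
        warnings.warn(f"{fname}: r >= 0.5 capped at {cap_cm} cM")
    return r


def kosambi_cm(r, cap_cm: float | None = 1000.0):
    """Kosambi map distance ``25 ln((1+2r)/(1-2r))`` in cM.

    ``r >= 0.5`` maps to ``cap_cm`` with a warning (error if ``cap_cm`` is
    None).  Accepts scalars or arrays.
    """
    r = _check_r(r, cap_cm, "kosambi_cm")
    safe = np.minimum(r, 0.5 - 1e-12)
    d = 25.0 * np.log((1 + 2 * safe) / (1 - 2 * safe))
    if cap_cm is not None:
        d = np.where(r >= 0.5, cap_cm, d)
    return _cap(d, cap_cm, "kosambi_cm")


def kosambi_r(d):
    """Inverse Kosambi: ``r = tanh(d/50) / 2``."""
    d = np.asarray(d, dtype=float)
    r = 0.5 * np.tanh(d / 50.0)
    return r if r.ndim else float(r)


def haldane_cm(r, cap_cm: float | None = 1000.0):
    """Haldane map distance ``-50 ln(1-2r)`` in cM (no interference)."""
    r = _check_r(r, cap_cm, "haldane_cm")
    safe = np.minimum(r, 0.5 - 1e-12)
    d = -50.0 * np.log(1 - 2 * safe)
    if cap_cm is not None:
        d = np.where(r >= 0.5, cap_cm, d)
    return _cap(d, cap_cm, "haldane_cm")


def haldane_r(d):
    """Inverse Haldane: ``r = (1 - exp(-d/50)) / 2``."""
    d = np.asarray(d, dtype=float)
    r = 0.5 * (1.0 - np.exp(-d / 50.0))
    return r if r.ndim else float(r)


MAPPING_FUNCTIONS = {"kosambi": kosambi_cm, "haldane": haldane_cm}


# ---------------------------------------------------------------------------
# consensus genotyping


@dataclass
class ConsensusMarker:
    """A contig collapsed to one genotype per individual (A/B/U only)."""

    contig_id: str
    calls: np.ndarray
    n_snps: int
    n_called_individuals: int


def consensus_genotype(
    contig_id: str,
    snp_calls: np.ndarray,
    min_snps_per_contig: int = 10,
    min_calls_for_consensus: int = 3,
    conflict_threshold: int = 2,
    min_individuals: int = 75,
) -> tuple[ConsensusMarker | None, str]:
    """Collapse a contig's SNP calls to one consensus genotype per individual.

    ``snp_calls`` is the (n_snps, n_individuals) call matrix of one contig.
    Heterozygous calls are ignored.  Per individual, let a and b be the
    counts of A and B calls across the contig's SNPs:

    * if any individual has ``a >= conflict_threshold`` and
      ``b >= conflict_threshold`` the contig is set aside (``"CONFLICT"``) --
      calls from both parents in one individual indicate mis-genotyping or
      cross-contamination;
    * otherwise the consensus is the majority of a vs b when
      ``a + b >= min_calls_for_consensus`` (ties -> U), else U.

    Contigs with fewer than ``min_snps_per_contig`` SNPs
    (``"TOO_FEW_SNPS"``) or consensus-genotyped in fewer than
    ``min_individuals`` individuals (``"TOO_FEW_INDIVIDUALS"``) are rejected.
    Returns ``(marker, "OK")`` or ``(None, reason)``.
    """
    snp_calls = np.atleast_2d(np.asarray(snp_calls, dtype=np.int8))
    if snp_calls.shape[0] < min_snps_per_contig:
        return None, "TOO_FEW_SNPS"
    a = (snp_calls == C.A).sum(axis=0)
    b = (snp_calls == C.B).sum(axis=0)
    if np.any((a >= conflict_threshold) & (b >= conflict_threshold)):
        return None, "CONFLICT"
    cons = np.full(snp_calls.shape[1], C.U, dtype=np.int8)
    enough = (a + b) >= min_calls_for_consensus
    cons[enough & (a > b)] = C.A
    cons[enough & (b > a)] = C.B
    n_called = int((cons != C.U).sum())
    if n_called < min_individuals:
        return None, "TOO_FEW_INDIVIDUALS"
    return (
        ConsensusMarker(contig_id, cons, int(snp_calls.shape[0]), n_called),
        "OK",
    )


# ---------------------------------------------------------------------------
# two-point linkage


@dataclass
class TwoPointEstimate:
    """Recombination fraction and LOD score between one pair of markers."""

    pair: tuple[str, str]
    n_informative: int
    n_recombinant: int
    r_hat: float
    lod: float


def _lod(n, k):
    """Vectorized two-point LOD; NaN where n == 0."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(n > 0, k / np.maximum(n, 1), 0.0)
        lod = (xlogy(k, r) + xlogy(n - k, 1 - r)) / _LN10 + n * np.log10(2.0)
    lod = np.where(2 * k == n, 0.0, lod)  # r^ = 1/2: likelihood ratio of 1 exactly
    return np.where(n > 0, lod, np.nan)


def two_point(
    x: ConsensusMarker | np.ndarray, y: ConsensusMarker | np.ndarray
) -> TwoPointEstimate:
    """Two-point estimate between two markers (symmetric in its arguments).

    Only individuals where both calls are parental homozygotes (A or B) are
    informative.  ``r_hat = k/n`` (0 when n = 0, in which case the LOD is
    undefined and the pair is excluded from clustering).
    """
    xid, yid = "x", "y"
    if isinstance(x, ConsensusMarker):
        xid, x = x.contig_id, x.calls
    if isinstance(y, ConsensusMarker):
        yid, y = y.contig_id, y.calls
    x = np.asarray(x, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    if x.shape != y.shape:
        raise ValueError("call vector length mismatch")
    inf = ((x == C.A) | (x == C.B)) & ((y == C.A) | (y == C.B))
    n = int(inf.sum())
    k = int((inf & (x != y)).sum())
    r = k / n if n else 0.0
    lod = float(_lod(n, k)) if n else np.nan
    return TwoPointEstimate((xid, yid), n, k, r, lod)


def pairwise_two_point(
    X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs two-point estimates for a (markers x individuals) matrix.

    Returns ``(n_informative, n_recombinant, r_hat, lod)`` square matrices,
    computed with matrix products; exactly equal to looping
    :func:`two_point` over all pairs.
    """
    X = np.asarray(X, dtype=np.int8)
    P = np.zeros(X.shape, dtype=np.float32)
    P[X == C.A] = 1.0
    P[X == C.B] = -1.0
    N = (np.abs(P)).astype(np.float32)
    n = N @ N.T  # informative count
    s = P @ P.T  # concordant minus recombinant
    k = (n - s) / 2.0
    n = np.round(n).astype(np.int64)
    k = np.round(k).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(n > 0, k / np.maximum(n, 1), 0.0)
    return n, k, r, _lod(n, k)


# ---------------------------------------------------------------------------
# clustering and ordering


@dataclass
class LinkageGroup:
    """An ordered linkage group with cumulative cM positions (origin 0)."""

    group_id: int
    members: list[str]
    cm_positions: list[float]


class PairwiseEstimates:
    """Pairwise r/LOD matrices indexed by marker id (ordering substrate)."""

    def __init__(self, ids: Sequence[str], n_inf, r, lod):
        self.ids = list(ids)
        self.index = {m: i for i, m in enumerate(self.ids)}
        self.n_informative = np.asarray(n_inf)
        self.r = np.asarray(r, dtype=float)
        self.lod = np.asarray(lod, dtype=float)

    @classmethod
    def from_markers(cls, markers: Sequence[ConsensusMarker]) -> "PairwiseEstimates":
        X = np.vstack([m.calls for m in markers])
        n, _, r, lod = pairwise_two_point(X)
        return cls([m.contig_id for m in markers], n, r, lod)

    @classmethod
    def from_estimates(cls, estimates: Iterable[TwoPointEstimate]) -> "PairwiseEstimates":
        estimates = list(estimates)
        ids = sorted({m for e in estimates for m in e.pair})
        idx = {m: i for i, m in enumerate(ids)}
        g = len(ids)
        n = np.zeros((g, g), dtype=np.int64)
        r = np.zeros((g, g))
        lod = np.full((g, g), np.nan)
        for e in estimates:
            i, j = idx[e.pair[0]], idx[e.pair[1]]
            n[i, j] = n[j, i] = e.n_informative
            r[i, j] = r[j, i] = e.r_hat
            lod[i, j] = lod[j, i] = e.lod
        return cls(ids, n, r, lod)

    def r_of(self, a: str, b: str) -> float:
        return float(self.r[self.index[a], self.index[b]])


def _components(est: PairwiseEstimates, min_lod: float) -> list[list[str]]:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    with np.errstate(invalid="ignore"):
        adj = (est.lod >= min_lod) & (est.r < 0.5) & (est.n_informative > 0)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[str]] = {}
    for m, lab in zip(est.ids, labels):
        groups.setdefault(int(lab), []).append(m)
    out = [sorted(g) for g in groups.values()]
    out.sort(key=lambda g: (-len(g), g[0]))
    return out


def cluster_linkage_groups(
    estimates: Iterable[TwoPointEstimate] | PairwiseEstimates,
    markers: Sequence[str] | None = None,
    min_lod: float = 10.0,
) -> list[list[str]]:
    """Linkage groups as connected components of the thresholded LOD graph.

    Edges join pairs with ``lod >= min_lod`` and ``r_hat < 0.5`` (the latter
    avoids linking through repulsion artifacts).  Markers listed in
    ``markers`` but absent from every edge come back as singleton groups.
    Groups are sorted by size descending, then by smallest member id.
    """
    est = (
        estimates
        if isinstance(estimates, PairwiseEstimates)
        else PairwiseEstimates.from_estimates(estimates)
    )
    groups = _components(est, min_lod)
    if markers is not None:
        seen = {m for g in groups for m in g}
        extra = [[m] for m in sorted(set(markers) - seen)]
        groups = sorted(groups + extra, key=lambda g: (-len(g), g[0]))
    return groups


def order_linkage_group(
    group: Sequence[str],
    estimates: PairwiseEstimates | Iterable[TwoPointEstimate],
    mapping_function: str = "kosambi",
    group_id: int = 1,
) -> LinkageGroup:
    """Order one linkage group and assign cumulative cM positions.

    The minimum spanning tree of the group under edge weight r^ is built; its
    diameter path (longest path in map distance) is the backbone order, and
    every off-path marker is inserted immediately after the backbone marker
    its tree path first reaches, nearest first.  Positions are cumulative map
    distances (Kosambi by default) between consecutive markers, origin 0.
    Deterministic: ties are broken by marker id throughout.
    """
    est = (
        estimates
        if isinstance(estimates, PairwiseEstimates)
        else PairwiseEstimates.from_estimates(estimates)
    )
    to_cm = MAPPING_FUNCTIONS[mapping_function]
    nodes = sorted(group)
    if len(nodes) < 2:
        return LinkageGroup(group_id, list(nodes), [0.0] * len(nodes))
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            ia, ib = est.index[a], est.index[b]
            if est.n_informative[ia, ib] > 0 and est.r[ia, ib] < 0.5:
                r = est.r[ia, ib]
                G.add_edge(a, b, weight=float(r), cm=float(to_cm(r)))
    if not nx.is_connected(G):
        raise ValueError("pairwise estimates do not connect the group")
    T = nx.minimum_spanning_tree(G, weight="weight", algorithm="kruskal")

    def farthest(src: str) -> str:
        dist = nx.single_source_dijkstra_path_length(T, src, weight="cm")
        dmax = max(dist.values())
        return min(n for n, d in dist.items() if d == dmax)

    u = farthest(nodes[0])
    v = farthest(u)
    backbone = nx.shortest_path(T, u, v, weight="cm")
    if backbone[0] > backbone[-1]:
        backbone = backbone[::-1]
    on_path = set(backbone)

    # attach off-path markers after the backbone node their tree path reaches
    attach: dict[str, list[tuple[float, str]]] = {b: [] for b in backbone}
    for node in nodes:
        if node in on_path:
            continue
        path = nx.shortest_path(T, node, backbone[0], weight="cm")
        stop = next(p for p in path if p in on_path)
        d = nx.shortest_path_length(T, node, stop, weight="cm")
        attach[stop].append((float(d), node))
    order: list[str] = []
    for b in backbone:
        order.append(b)
        order.extend(n for _, n in sorted(attach[b]))

    cm = [0.0]
    for a, b in zip(order, order[1:]):
        ia, ib = est.index[a], est.index[b]
        if est.n_informative[ia, ib] > 0:
            step = float(to_cm(min(est.r[ia, ib], 0.5 - 1e-9)))
        else:  # no shared informative meioses; place at the same position
            step = 0.0
        cm.append(cm[-1] + step)
    return LinkageGroup(group_id, order, cm)


# ---------------------------------------------------------------------------
# full map construction


@dataclass
class MapBuilderParams:
    min_snps_per_contig: int = 10
    min_calls_for_consensus: int = 3
    conflict_threshold: int = 2
    min_individuals: int = 75
    min_lod: float = 10.0
    min_group_size: int = 3
    mapping_function: str = "kosambi"


def consensus_all(
    m: GenotypeMatrix, params: MapBuilderParams | None = None
) -> tuple[list[ConsensusMarker], dict[str, int]]:
    """Consensus-genotype every contig of the matrix; returns (markers, tally)."""
    params = params or MapBuilderParams()
    markers: list[ConsensusMarker] = []
    tally = {"OK": 0, "TOO_FEW_SNPS": 0, "CONFLICT": 0, "TOO_FEW_INDIVIDUALS": 0}
    contig_ids = m.sites["contig_id"].astype(str).to_numpy()
    # group rows per contig, preserving first-appearance order
    order: dict[str, list[int]] = {}
    for i, cid in enumerate(contig_ids):
        order.setdefault(cid, []).append(i)
    for cid, rows in order.items():
        marker, reason = consensus_genotype(
            cid,
            m.calls[rows],
            params.min_snps_per_contig,
            params.min_calls_for_consensus,
            params.conflict_threshold,
            params.min_individuals,
        )
        tally[reason] += 1
        if marker is not None:
            markers.append(marker)
    log.info("consensus_all: %s", tally)
    return markers, tally


def build_map(
    m: GenotypeMatrix, params: MapBuilderParams | None = None
) -> tuple[FrameworkMap, dict]:
    """Build a de novo framework map from a population genotype matrix.

    Runs consensus genotyping, all-pairs two-point estimation, LOD
    clustering, drops linkage groups smaller than ``min_group_size``, orders
    the remaining groups and returns them as a :class:`FrameworkMap` whose
    chromosomes are named LG1, LG2, ... by decreasing size.  The second
    return value is a diagnostics dict (consensus tally, group sizes,
    dropped-marker count).
    """
    params = params or MapBuilderParams()
    markers, tally = consensus_all(m, params)
    if not markers:
        raise ValueError(f"no contig survived consensus genotyping: {tally}")
    est = PairwiseEstimates.from_markers(markers)
    groups = cluster_linkage_groups(est, markers=est.ids, min_lod=params.min_lod)
    kept = [g for g in groups if len(g) >= params.min_group_size]
    n_dropped = sum(len(g) for g in groups) - sum(len(g) for g in kept)
    if n_dropped:
        log.info("build_map: dropped %d markers in undersized linkage groups", n_dropped)
    if not kept:
        raise ValueError(
            f"no linkage group of size >= {params.min_group_size}; "
            f"group sizes: {[len(g) for g in groups]}"
        )
    rows = []
    call_rows = []
    by_id = {mk.contig_id: mk for mk in markers}
    for gi, g in enumerate(kept, start=1):
        lg = order_linkage_group(g, est, params.mapping_function, group_id=gi)
        for mid, cm in zip(lg.members, lg.cm_positions):
            rows.append((mid, f"LG{gi}", cm))
            call_rows.append(by_id[mid].calls)
    fmap = FrameworkMap(
        markers=pd.DataFrame(rows, columns=["marker_id", "chromosome", "cm"]),
        calls=np.vstack(call_rows),
        individuals=list(m.individuals),
    )
    report = {
        "consensus": tally,
        "n_markers": len(markers),
        "group_sizes": [len(g) for g in groups],
        "n_groups_kept": len(kept),
        "n_markers_dropped": n_dropped,
    }
    return fmap, report
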