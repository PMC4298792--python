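"""De novo map construction: consensus, two-point linkage, clustering, ordering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from popseq import calls as C
from popseq.genotype_io import GenotypeMatrix
from popseq.mapbuilder import (
    MapBuilderParams,
    PairwiseEstimates,
    TwoPointEstimate,
    build_map,
    cluster_linkage_groups,
    consensus_genotype,
    haldane_cm,
    haldane_r,
    kosambi_cm,
    kosambi_r,
    order_linkage_group,
    pairwise_two_point,
    two_point,
)
from popseq.popsim import SimConfig, SimTruth, simulate, simulate_population

from conftest import make_matrix


# ---------------------------------------------------------------------------
# mapping functions


def test_mapping_function_closed_forms():
    assert kosambi_cm(0.0) == 0.0 and haldane_cm(0.0) == 0.0
    assert kosambi_cm(0.25) == pytest.approx(25 * np.log(3), abs=1e-10)
    assert kosambi_cm(0.25) == pytest.approx(27.47, abs=0.01)
    assert haldane_cm(0.25) == pytest.approx(-50 * np.log(0.5), abs=1e-10)
    assert haldane_cm(0.25) == pytest.approx(34.66, abs=0.01)


@pytest.mark.parametrize("r", [0.0, 0.01, 0.1, 0.25, 0.4, 0.49])
def test_mapping_functions_invert_exactly(r):
    assert kosambi_r(kosambi_cm(r)) == pytest.approx(r, abs=1e-10)
    assert haldane_r(haldane_cm(r)) == pytest.approx(r, abs=1e-10)


def test_mapping_function_capping_and_errors():
    with pytest.warns(UserWarning, match="capped"):
        assert kosambi_cm(0.5) == 1000.0
    with pytest.raises(ValueError, match="no finite"):
        kosambi_cm(0.5, cap_cm=None)
    with pytest.raises(ValueError):
        haldane_cm(-0.1)


# ---------------------------------------------------------------------------
# consensus genotyping


def consensus_of(columns: list[str], **kw):
    """columns: per-individual SNP call strings (transposed into a matrix)."""
    calls = np.column_stack([C.from_strings(list(col)) for col in columns])
    return consensus_genotype("c1", calls, **kw)


def test_consensus_majority_conflict_and_min_calls():
    kw = dict(min_snps_per_contig=4, min_individuals=1)
    marker, reason = consensus_of(["AAAB", "BBBB", "ABUU"], **kw)
    assert reason == "OK"
    # {A,A,A,B}: a=3 >= 3 calls, majority A, no conflict (b=1 < 2)
    # {A,B}: only two calls -> U
    assert list(C.to_strings(marker.calls)) == ["A", "B", "U"]
    assert marker.n_called_individuals == 2

    _, reason = consensus_of(["AABB", "BBBB"], **kw)
    assert reason == "CONFLICT"  # an individual with calls from both parents

    _, reason = consensus_of(["AABB"], min_snps_per_contig=5, min_individuals=1)
    assert reason == "TOO_FEW_SNPS"

    _, reason = consensus_of(["ABUU", "AAUU"], **dict(kw, min_individuals=2))
    assert reason == "TOO_FEW_INDIVIDUALS"


def test_consensus_tie_is_missing():
    # a=b=2 is a tie; with the conflict threshold relaxed it yields U, not A/B
    marker, reason = consensus_of(["AABB", "AAAA"], min_snps_per_contig=4,
                                  min_individuals=1, conflict_threshold=3)
    assert reason == "OK"
    assert list(C.to_strings(marker.calls)) == ["U", "A"]


def test_consensus_ignores_heterozygous_calls():
    marker, reason = consensus_of(["AAAH"], min_snps_per_contig=4, min_individuals=1)
    assert reason == "OK"
    assert list(C.to_strings(marker.calls)) == ["A"]


# ---------------------------------------------------------------------------
# two-point estimates


def test_two_point_closed_forms():
    x = C.from_strings("A" * 90)
    assert two_point(x, x).lod == pytest.approx(90 * np.log10(2), abs=1e-12)
    assert two_point(x, x).lod == pytest.approx(27.09, abs=0.01)

    y = C.from_strings("A" * 45 + "B" * 45)
    est = two_point(x, y)
    assert est.r_hat == 0.5 and est.lod == 0.0  # likelihood ratio of 1 exactly

    z = C.from_strings("B" * 5 + "A" * 45)
    est = two_point(C.from_strings("A" * 50), z)
    expected = 5 * np.log10(0.1) + 45 * np.log10(0.9) + 50 * np.log10(2)
    assert (est.n_informative, est.n_recombinant) == (50, 5)
    assert est.lod == pytest.approx(expected, abs=1e-12)
    assert est.lod == pytest.approx(7.99, abs=0.01)


def test_two_point_symmetry_and_informativeness():
    rng = np.random.default_rng(4)
    x = C.from_strings(rng.choice(list("ABHU"), size=40))
    y = C.from_strings(rng.choice(list("ABHU"), size=40))
    a, b = two_point(x, y), two_point(y, x)
    assert (a.n_informative, a.n_recombinant, a.r_hat, a.lod) == (
        b.n_informative, b.n_recombinant, b.r_hat, b.lod
    )
    # H and U never count as informative
    est = two_point(C.from_strings("HU"), C.from_strings("AB"))
    assert est.n_informative == 0 and np.isnan(est.lod)


def test_lod_strictly_decreasing_in_recombinants():
    from popseq.mapbuilder import _lod

    n = 60
    lods = _lod(np.full(n // 2, n), np.arange(n // 2))
    assert np.all(np.diff(lods) < 0)


def test_pairwise_matrix_equals_scalar_loop():
    rng = np.random.default_rng(5)
    X = np.vstack(
        [C.from_strings(rng.choice(list("ABU"), p=[0.45, 0.45, 0.1], size=30))
         for _ in range(12)]
    )
    n, k, r, lod = pairwise_two_point(X)
    for i in range(12):
        for j in range(12):
            est = two_point(X[i], X[j])
            assert n[i, j] == est.n_informative
            assert k[i, j] == est.n_recombinant
            assert r[i, j] == pytest.approx(est.r_hat, abs=1e-12)
            if est.n_informative:
                assert lod[i, j] == pytest.approx(est.lod, abs=1e-9)


# ---------------------------------------------------------------------------
# clustering and ordering


def test_cluster_lod_threshold():
    n90 = C.from_strings("A" * 90)
    est = [
        TwoPointEstimate(("a", "b"), 90, 0, 0.0, float(90 * np.log10(2))),
        TwoPointEstimate(("a", "c"), 90, 45, 0.5, 0.0),
        TwoPointEstimate(("b", "c"), 90, 45, 0.5, 0.0),
    ]
    groups = cluster_linkage_groups(est, markers=["a", "b", "c", "d"])
    assert groups == [["a", "b"], ["c"], ["d"]]


def _chain_estimates(rs: dict[tuple[str, str], float], n: int = 100):
    ids = sorted({m for pair in rs for m in pair})
    out = []
    for (a, b), r in rs.items():
        k = int(round(r * n))
        lod = float(
            (k * np.log10(max(r, 1e-12)) if k else 0.0)
            + (n - k) * np.log10(1 - r)
            + n * np.log10(2)
        )
        out.append(TwoPointEstimate((a, b), n, k, r, lod))
    return out, ids


def test_order_three_marker_chain():
    est, ids = _chain_estimates(
        {("m1", "m2"): 0.05, ("m2", "m3"): 0.05, ("m1", "m3"): 0.10}
    )
    lg = order_linkage_group(ids, est)
    assert lg.members in (["m1", "m2", "m3"], ["m3", "m2", "m1"])
    d = 25 * np.log(1.1 / 0.9)  # kosambi cm for r = 0.05
    assert lg.cm_positions == pytest.approx([0.0, d, 2 * d], abs=1e-9)
    assert lg.cm_positions[1] == pytest.approx(5.0, abs=0.05)


def test_order_two_markers_and_determinism():
    est, ids = _chain_estimates({("a", "b"): 0.1})
    lg = order_linkage_group(ids, est)
    assert lg.members == ["a", "b"]
    assert lg.cm_positions[1] == pytest.approx(float(kosambi_cm(0.1)), abs=1e-12)
    lg2 = order_linkage_group(ids, est)
    assert (lg.members, lg.cm_positions) == (lg2.members, lg2.cm_positions)


def test_order_recovers_simulated_chromosome(sim_denovo):
    from scipy.stats import spearmanr

    from popseq.genotype_io import filter_genotypes, filter_sites

    m = filter_sites(filter_genotypes(sim_denovo.matrix))
    fmap, report = build_map(m)
    assert report["n_groups_kept"] >= 3
    truth_cm = dict(zip(sim_denovo.truth.contigs["contig_id"],
                        sim_denovo.truth.contigs["cm"]))
    truth_ch = dict(zip(sim_denovo.truth.contigs["contig_id"],
                        sim_denovo.truth.contigs["chromosome"]))
    majors = fmap.markers["chromosome"].value_counts().index[:3]
    for lg in majors:
        ids = fmap.markers.loc[fmap.markers["chromosome"] == lg, "marker_id"].tolist()
        chroms = [truth_ch[i] for i in ids]
        assert max(chroms.count(c) for c in set(chroms)) == len(ids)  # pure group
        rho = spearmanr(range(len(ids)), [truth_cm[i] for i in ids]).statistic
        assert abs(rho) >= 0.97


def test_build_map_self_consistency(sim_denovo):
    """Consensus markers self-place at distance 0 against their own map."""
    from popseq.genotype_io import filter_genotypes, filter_sites
    from popseq.placement import PLACED, place_all

    m = filter_sites(filter_genotypes(sim_denovo.matrix))
    fmap, _ = build_map(m)
    matrix = GenotypeMatrix(
        sites=pd.DataFrame(
            {
                "marker_id": fmap.markers["marker_id"],
                "contig_id": fmap.markers["marker_id"],
                "position": 1,
                "quality": 99.0,
            }
        ),
        calls=fmap.calls.copy(),
        individuals=list(fmap.individuals),
        population_type="DH",
    )
    placed = place_all(matrix, fmap)
    ok = [p for p in placed if p.status == PLACED and p.min_distance == 0]
    assert len(ok) >= 0.99 * len(placed)


def test_build_map_single_chromosome_and_failure():
    cfg = SimConfig(
        n_chromosomes=1, chrom_length_cm=100, n_framework_markers=10,
        n_contigs=60, snps_per_contig_min=10, snps_per_contig_mean=15,
        n_individuals=90, n_clones=0, call_rate=0.6, seed=9,
    )
    sim = simulate(cfg)
    fmap, report = build_map(sim.matrix)
    assert fmap.chromosomes == ["LG1"]
    with pytest.raises(ValueError, match="no contig survived"):
        build_map(make_matrix(["AB", "BA"]), MapBuilderParams())


# ---------------------------------------------------------------------------
# simulation-backed linkage statistics


def _two_locus_truth(length_cm: float, gap_cm: float) -> SimTruth:
    framework = pd.DataFrame(
        {"marker_id": ["f1", "f2"], "chromosome": ["chr1", "chr1"],
         "cm": [0.0, gap_cm]}
    )
    contigs = pd.DataFrame(
        columns=["contig_id", "chromosome", "cm", "length_bp", "n_snps", "clone_id"]
    )
    snps = pd.DataFrame(
        columns=["marker_id", "contig_id", "position", "chromosome", "cm"]
    )
    return SimTruth(framework, contigs, snps,
                    pd.DataFrame(columns=["clone_id", "clone_length"]), ["chr1"])


def test_recombination_fraction_matches_haldane_expectation():
    """DH gametes at 50 cM should recombine at r = (1 - e^-1)/2 = 0.316."""
    truth = _two_locus_truth(50.0, 50.0)
    cfg = SimConfig(n_chromosomes=1, chrom_length_cm=50.0, n_individuals=90,
                    n_contigs=1, n_framework_markers=2, n_clones=0)
    total = rec = 0
    for rep in range(200):
        rng = np.random.default_rng(1000 + rep)
        fcalls, _ = simulate_population(truth, cfg, rng)
        rec += int((fcalls[0] != fcalls[1]).sum())
        total += cfg.n_individuals
    r_true = 0.5 * (1 - np.exp(-1.0))
    se = np.sqrt(r_true * (1 - r_true) / total)
    assert abs(rec / total - r_true) < 3 * se


def test_ril_map_length_inflation_vs_dh():
    """Treating an F8 RIL as DH inflates the map length: at tight linkage the
    observed recombinant fraction approaches 2r/(1+2r), roughly doubling map
    distances (the commonly cited factor reaches ~3 with residual noise)."""
    base = dict(
        n_chromosomes=1, chrom_length_cm=100.0, n_framework_markers=10,
        n_contigs=120, snps_per_contig_min=10, snps_per_contig_mean=15,
        n_individuals=90, n_clones=0, call_rate=0.6, genotype_error=0.0,
    )
    maps = {"DH": 0.0, "RIL": 0.0}
    for pop in maps:
        for seed in range(4):  # average out two-point sampling noise
            sim = simulate(SimConfig(population_type=pop, seed=seed, **base))
            fmap, _ = build_map(sim.matrix)
            maps[pop] += float(fmap.markers.groupby("chromosome")["cm"].max().sum())
    ratio = maps["RIL"] / maps["DH"]
    assert 1.7 <= ratio <= 3.0
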