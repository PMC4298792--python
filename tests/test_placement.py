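"""Hamming-distance nearest-neighbor search and the placement gates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from popseq import calls as C
from popseq.framework import FrameworkMap, prune_redundant
from popseq.genotype_io import GenotypeMatrix, SiteRecord
from popseq.placement import (
    PLACED,
    REJECTED_CALLRATE,
    REJECTED_CHROM,
    REJECTED_MAD,
    PlacementParams,
    hamming_distance,
    nearest_neighbors,
    place_all,
    place_snp,
)

from test_framework import make_map


def oracle_hamming(x: str, y: str) -> tuple[int, int]:
    dist = overlap = 0
    for a, b in zip(x, y):
        if a != "U" and b != "U":
            overlap += 1
            dist += a != b
    return dist, overlap


def test_hamming_examples():
    assert hamming_distance(C.from_strings("AABHU"), C.from_strings("AABHB")) == (0, 4)
    assert hamming_distance(C.from_strings("ABA"), C.from_strings("BAA")) == (2, 3)
    with pytest.raises(ValueError, match="length"):
        hamming_distance(C.from_strings("AB"), C.from_strings("A"))


@settings(derandomize=True, max_examples=200)
@given(st.integers(0, 2**32 - 1))
def test_hamming_matches_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    x = "".join(rng.choice(list("ABHU"), p=[0.35, 0.35, 0.1, 0.2], size=30))
    y = "".join(rng.choice(list("ABHU"), p=[0.35, 0.35, 0.1, 0.2], size=30))
    assert hamming_distance(C.from_strings(x), C.from_strings(y)) == oracle_hamming(x, y)


def test_nearest_neighbors_keeps_ties_and_skips_zero_overlap():
    fmap = make_map(
        [
            ("m1", "1H", 1.0, "AABB"),  # distance 1 to query
            ("m2", "1H", 2.0, "ABAB"),  # distance 1
            ("m3", "1H", 3.0, "BBBB"),  # distance 2
            ("m4", "2H", 0.0, "UUUU"),  # zero overlap: never a candidate
        ]
    )
    idx, dmin = nearest_neighbors(C.from_strings("AAAB"), fmap)
    assert dmin == 1
    assert fmap.markers["marker_id"].iloc[idx].tolist() == ["m1", "m2"]
    idx, dmin = nearest_neighbors(C.from_strings("UUUU"), fmap)
    assert dmin is None and len(idx) == 0


def test_place_snp_callrate_gate():
    fmap = make_map([("m1", "1H", 1.0, "A" * 90)])
    query = C.from_strings("A" * 17 + "U" * 73)  # 17/90 = 18.9% <= 20%
    assert place_snp(query, fmap).status == REJECTED_CALLRATE
    query = C.from_strings("A" * 19 + "U" * 71)  # 21.1% > 20%
    assert place_snp(query, fmap).status == PLACED


def test_place_snp_chromosome_and_mad_gates():
    pat = "AABB"
    # five markers tie at distance 0: chr2 at {10, 11, 12, 30}, chr5 at {40}
    fmap = make_map(
        [
            ("m1", "chr2", 10.0, pat),
            ("m2", "chr2", 11.0, pat),
            ("m3", "chr2", 12.0, pat),
            ("m4", "chr2", 30.0, pat),
            ("m5", "chr5", 40.0, pat),
        ]
    )
    rec = place_snp(C.from_strings(pat), fmap)
    assert rec.status == PLACED
    assert rec.chromosome == "chr2"
    assert rec.cm == pytest.approx(11.5)  # median of {10, 11, 12, 30}
    assert rec.mad_cm == pytest.approx(1.0)  # median of {1.5, 0.5, 0.5, 18.5}
    assert rec.winning_frac == pytest.approx(0.8)
    assert rec.n_neighbors == 5

    spread = make_map(
        [("m1", "chr2", 0.0, pat), ("m2", "chr2", 20.0, pat), ("m3", "chr2", 40.0, pat)]
    )
    rec = place_snp(C.from_strings(pat), spread)
    assert rec.status == REJECTED_MAD and rec.mad_cm == pytest.approx(20.0)

    split = make_map([("m1", "chr1", 0.0, pat), ("m2", "chr2", 0.0, pat)])
    rec = place_snp(C.from_strings(pat), split, PlacementParams(min_chrom_frac=0.5))
    assert rec.status == REJECTED_CHROM  # chromosome ties reject deterministically


def _matrix_from_map(fmap: FrameworkMap, population_type="DH") -> GenotypeMatrix:
    return GenotypeMatrix(
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
        population_type=population_type,
    )


def test_self_placement_on_simulated_map(sim_small):
    """Every non-redundant framework marker placed against its own map lands
    on itself: PLACED, distance 0, MAD 0, own cM."""
    fmap = prune_redundant(sim_small.framework)
    placed = place_all(_matrix_from_map(fmap), fmap)
    assert len(placed) == fmap.n_markers
    for rec, row in zip(placed, fmap.markers.itertuples(index=False)):
        assert rec.status == PLACED
        assert rec.min_distance == 0
        assert rec.mad_cm == 0.0
        assert rec.chromosome == row.chromosome
        assert rec.cm == pytest.approx(row.cm, abs=1e-12)


def test_place_all_matches_per_site_and_exhaustive_scan(sim_small):
    """The batched one-hot search equals place_snp (exhaustive scan) site by site."""
    m = sim_small.matrix
    sub = m.subset_sites(np.arange(m.n_sites) < 300)
    fmap = sim_small.framework
    batch = place_all(sub, fmap)
    for i, rec in enumerate(batch):
        site = SiteRecord(
            marker_id=rec.marker_id, contig_id=rec.contig_id, position=rec.position,
            quality=0.0, calls=sub.calls[i],
        )
        single = place_snp(site, fmap)
        assert (rec.status, rec.chromosome, rec.n_neighbors, rec.min_distance) == (
            single.status, single.chromosome, single.n_neighbors, single.min_distance
        )
        assert rec.cm == single.cm or (np.isnan(rec.cm) and np.isnan(single.cm))


def test_placed_set_monotone_in_max_distance(sim_small):
    m = sim_small.matrix.subset_sites(np.arange(sim_small.matrix.n_sites) < 500)
    ids = lambda placed: {p.marker_id for p in placed if p.status == PLACED}
    d1 = ids(place_all(m, sim_small.framework, PlacementParams(max_distance=1)))
    d2 = ids(place_all(m, sim_small.framework, PlacementParams(max_distance=2)))
    assert d1 <= d2


def test_placement_invariant_under_joint_individual_permutation(sim_small):
    m = sim_small.matrix.subset_sites(np.arange(sim_small.matrix.n_sites) < 200)
    fmap = sim_small.framework
    rng = np.random.default_rng(3)
    perm = rng.permutation(m.n_individuals)
    m2 = GenotypeMatrix(
        sites=m.sites.copy(), calls=m.calls[:, perm],
        individuals=[m.individuals[j] for j in perm],
        population_type=m.population_type,
    )
    fmap2 = FrameworkMap(
        markers=fmap.markers.copy(), calls=fmap.calls[:, perm],
        individuals=[fmap.individuals[j] for j in perm],
    )
    a = place_all(m, fmap)
    b = place_all(m2, fmap2)
    assert [(p.status, p.chromosome, p.cm) for p in a] == [
        (p.status, p.chromosome, p.cm) for p in b
    ]


def test_place_all_rejects_individual_set_mismatch(sim_small):
    m = sim_small.matrix
    fmap = sim_small.framework
    bad = FrameworkMap(
        markers=fmap.markers.copy(), calls=fmap.calls,
        individuals=["x" + i for i in fmap.individuals],
    )
    with pytest.raises(ValueError, match="individual sets differ"):
        place_all(m, bad)


def test_params_validation():
    with pytest.raises(ValueError):
        PlacementParams(min_call_frac=0.0)
    with pytest.raises(ValueError):
        PlacementParams(min_chrom_frac=0.3)
    with pytest.raises(ValueError):
        PlacementParams(max_mad_cm=0.0)
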