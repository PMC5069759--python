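"""Identity clustering, reciprocal best hits, species-count estimation, and
lifestyle partitioning against planted truth."""

import numpy as np
import pytest

from strainscope.genesets import (
    GeneRecord,
    best_hit,
    cluster_identity,
    estimate_species_count,
    pairwise_identity,
    partition_gene_sets,
    reciprocal_best_hits,
)
from strainscope.synthetic import mutate_cds, random_cds


@pytest.mark.parametrize(
    "a,b,expected",
    [("ACGTACGT", "ACGTACGT", 1.0), ("AAAA", "AAAT", 0.75), ("AAAA", "AAA", 0.75)],
)
def test_pairwise_identity_examples(a, b, expected):
    assert pairwise_identity(a, b) == pytest.approx(expected)


def test_pairwise_identity_empty_raises():
    with pytest.raises(ValueError):
        pairwise_identity("", "ACGT")


def test_cluster_identity_all_identical():
    genes = [GeneRecord(f"g{i}", cds="ATGAAAGTTCTT" * 10) for i in range(4)]
    clusters = cluster_identity(genes)
    assert len(clusters) == 1
    assert sorted(clusters[0].members) == [f"g{i}" for i in range(4)]


def test_cluster_identity_below_threshold_splits():
    rng = np.random.default_rng(1)
    base = random_cds(100, rng=rng)
    variant = mutate_cds(base, 1.0, 40, rng)  # ~10% diverged
    assert pairwise_identity(base, variant) < 0.97
    clusters = cluster_identity(
        [GeneRecord("a", cds=base), GeneRecord("b", cds=variant)], 0.97
    )
    assert len(clusters) == 2


def test_cluster_identity_twelve_diverged_variants():
    """Twelve marker variants pairwise below 97% identity found as twelve
    clusters — the mechanism behind per-site species richness estimates."""
    rng = np.random.default_rng(2)
    base = random_cds(150, rng=rng)
    genes = [
        GeneRecord(f"v{i:02d}", cds=mutate_cds(base, 1.0, 80, rng))
        for i in range(12)
    ]
    for i in range(12):
        for j in range(i + 1, 12):
            assert pairwise_identity(genes[i].cds, genes[j].cds) < 0.97
    assert len(cluster_identity(genes, 0.97)) == 12


def test_cluster_identity_order_stable():
    rng = np.random.default_rng(3)
    base = random_cds(80, rng=rng)
    genes = [
        GeneRecord(f"g{i}", cds=mutate_cds(base, 1.0, 50, rng)) for i in range(6)
    ]
    n1 = len(cluster_identity(genes, 0.97))
    n2 = len(cluster_identity(genes[::-1], 0.97))
    assert n1 == n2


def test_estimate_species_count_basics():
    one = {"famA": [GeneRecord("g", cds="ATGAAA" * 30)]}
    assert estimate_species_count(one)[0] == 1

    rng = np.random.default_rng(4)

    def family(k):
        base = random_cds(120, rng=rng)
        return [
            GeneRecord(f"m{k}_{i}", cds=mutate_cds(base, 1.0, 60, rng))
            for i in range(k)
        ]

    fams = {"f1": family(3), "f2": family(3), "f3": family(5)}
    estimate, per_family = estimate_species_count(fams)
    assert sorted(per_family.values()) == [3, 3, 5]
    assert estimate == 3


def test_estimate_species_count_recovers_planted_strains(small_community):
    estimate, per_family = estimate_species_count(small_community.marker_families)
    assert estimate == small_community.config.n_strains


def test_best_hit_identity_and_none():
    q = GeneRecord("q", cds=random_cds(100, seed=5))
    same = GeneRecord("t1", cds=q.cds)
    far = GeneRecord("t2", cds=random_cds(100, seed=6))
    hit = best_hit(q, [far, same])
    assert hit is not None and hit[0].gene_id == "t1"
    assert best_hit(q, [GeneRecord("short", cds=random_cds(100, seed=7)[:30])]) is None


def test_best_hit_tie_breaks_lexically():
    q = GeneRecord("q", cds=random_cds(100, seed=8))
    t_b = GeneRecord("b", cds=q.cds)
    t_a = GeneRecord("a", cds=q.cds)
    hit = best_hit(q, [t_b, t_a])
    assert hit[0].gene_id == "a"


def test_rbh_basics_and_reciprocity():
    g = GeneRecord("a0", cds=random_cds(100, seed=9))
    pairs = reciprocal_best_hits([g], [GeneRecord("b0", cds=g.cds)])
    assert len(pairs) == 1 and pairs[0].identity == pytest.approx(1.0)

    # a1's best hit is b0, but b0's best is a0 -> only (a0, b0) pairs
    rng = np.random.default_rng(10)
    base = random_cds(120, rng=rng)
    a0 = GeneRecord("a0", cds=base)
    a1 = GeneRecord("a1", cds=mutate_cds(base, 1.0, 25, rng))
    b0 = GeneRecord("b0", cds=base)
    pairs = reciprocal_best_hits([a0, a1], [b0])
    assert [(p.gene_a, p.gene_b) for p in pairs] == [("a0", "b0")]


def test_rbh_symmetric_under_swap():
    rng = np.random.default_rng(11)
    set_a, set_b = [], []
    for i in range(4):
        base = random_cds(100, rng=rng)
        set_a.append(GeneRecord(f"a{i}", cds=mutate_cds(base, 0.5, 15, rng)))
        set_b.append(GeneRecord(f"b{i}", cds=mutate_cds(base, 0.5, 15, rng)))
    fwd = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(set_a, set_b)}
    rev = {(p.gene_b, p.gene_a) for p in reciprocal_best_hits(set_b, set_a)}
    assert fwd == rev and len(fwd) == 4


def test_rbh_planted_orthologs_no_decoys():
    """Planted 1:1 orthologs (high identity) are recovered; unrelated decoy
    sequences never pair."""
    rng = np.random.default_rng(12)
    set_a, set_b, planted = [], [], set()
    for i in range(5):
        base = random_cds(110, rng=rng)
        set_a.append(GeneRecord(f"a{i}", cds=mutate_cds(base, 0.5, 20, rng)))
        set_b.append(GeneRecord(f"b{i}", cds=mutate_cds(base, 0.5, 20, rng)))
        planted.add((f"a{i}", f"b{i}"))
    set_a.append(GeneRecord("decoy_a", cds=random_cds(110, rng=rng)))
    set_b.append(GeneRecord("decoy_b", cds=random_cds(110, rng=rng)))
    got = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(set_a, set_b)}
    assert planted <= got
    assert not any("decoy" in a and "decoy" in b for a, b in got - planted)


def test_partition_rules_direct():
    rng = np.random.default_rng(13)
    core_base = random_cds(100, rng=rng)
    endo_base = random_cds(100, rng=rng)
    orphan = random_cds(100, rng=rng)
    pop = [
        GeneRecord("core_gene", cds=mutate_cds(core_base, 0.5, 15, rng)),
        GeneRecord("endo_gene", cds=mutate_cds(endo_base, 0.5, 15, rng)),
        GeneRecord("orphan", cds=orphan),
    ]
    endo_ref = [
        GeneRecord("e_core", cds=mutate_cds(core_base, 0.5, 15, rng)),
        GeneRecord("e_endo", cds=mutate_cds(endo_base, 0.5, 15, rng)),
    ]
    free_ref = [GeneRecord("f_core", cds=mutate_cds(core_base, 0.5, 15, rng))]
    part = partition_gene_sets(pop, endo_ref, [free_ref])
    assert part.assignments["core_gene"] == "core"
    assert part.assignments["endo_gene"] == "endosymbiont"
    assert part.assignments["orphan"] == "unassigned"
    assert sum(part.counts.values()) == len(pop)


def test_partition_recovers_planted_counts(small_community):
    cfg = small_community.config
    part = partition_gene_sets(
        small_community.pop_genes,
        small_community.endo_ref,
        small_community.free_refs,
    )
    assert part.counts["core"] == cfg.n_core
    assert part.counts["free_living"] == cfg.n_free_living
    assert part.counts["endosymbiont"] == cfg.n_endosymbiont
    assert part.counts["unassigned"] == cfg.n_unassigned
    truth = dict(
        small_community.gene_truth[["gene_id", "category"]].itertuples(
            index=False, name=None
        )
    )
    assert part.assignments == truth


def test_partition_requires_references():
    pop = [GeneRecord("g", cds=random_cds(100, seed=14))]
    with pytest.raises(ValueError):
        partition_gene_sets(pop, [], [[GeneRecord("f", cds=random_cds(100, seed=15))]])
    with pytest.raises(ValueError):
        partition_gene_sets([], pop, [pop])
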