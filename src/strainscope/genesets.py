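"""Ortholog detection and lifestyle partitioning of population gene content.

Population genes are matched to reference proteomes by reciprocal best hits
(RBH) under a deterministic global protein aligner, then demarcated into
lifestyle repertoires: a gene with an RBH in the endosymbiont reference AND
in at least one free-living reference is *core*; an RBH only in the
endosymbiont reference is *endosymbiont*-specific; only in free-living
reference(s) is *free-living*-specific; no RBH leaves it *unassigned*.

Species richness per bin/site is estimated from single-copy marker genes:
each marker family is clustered at 97% nucleotide identity and the median
cluster count across families is reported (copy-number-variation logic —
a bin holding k diverged strains shows k clusters per single-copy family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median_low

from Bio import Align

from .genetics import translate
from .selection import alignment_score

CATEGORIES = ("core", "free_living", "endosymbiont", "unassigned")


@dataclass
class GeneRecord:
    gene_id: str
    cds: str = ""
    protein: str = ""
    bin_id: str | None = None

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        if self.cds and not self.protein:
            self.protein = translate(self.cds).rstrip("*")
        self.protein = self.protein.upper().rstrip("*")

    @property
    def length_bp(self) -> int:
        return len(self.cds)


@dataclass
class IdentityCluster:
    representative: str
    members: list[str]
    threshold: float


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    score: float
    identity: float


@dataclass
class GeneSetPartition:
    assignments: dict[str, str]  # gene_id -> category
    best_hits: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for cat in self.assignments.values():
            out[cat] += 1
        return out


# a simple unit-match aligner for nucleotide/protein identity computation
_IDENTITY_ALIGNER = Align.PairwiseAligner(
    mode="global", match_score=1.0, mismatch_score=-1.0,
    open_gap_score=-2.0, extend_gap_score=-0.5,
)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Gap columns count as mismatch, so "AAAA" vs "AAA" scores 0.75.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot compute identity of an empty sequence")
    aln = _IDENTITY_ALIGNER.align(seq_a.upper(), seq_b.upper())[0]
    a, b = aln[0], aln[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a)


def cluster_identity(
    genes: list[GeneRecord], threshold: float = 0.97
) -> list[IdentityCluster]:
    """Greedy incremental clustering at a nucleotide identity threshold.

    Genes are processed longest-first (ties broken by gene_id); each joins
    the first cluster whose representative it matches at identity ≥
    threshold, else founds a new cluster.
    """
    if not genes:
        raise ValueError("no genes to cluster")
    ordered = sorted(genes, key=lambda g: (-len(g.cds or g.protein), g.gene_id))
    clusters: list[IdentityCluster] = []
    for g in ordered:
        seq = g.cds or g.protein
        placed = False
        for cl in clusters:
            rep_seq = cl._rep_seq  # type: ignore[attr-defined]
            if pairwise_identity(seq, rep_seq) >= threshold:
                cl.members.append(g.gene_id)
                placed = True
                break
        if not placed:
            cl = IdentityCluster(representative=g.gene_id, members=[g.gene_id],
                                 threshold=threshold)
            cl._rep_seq = seq  # type: ignore[attr-defined]
            clusters.append(cl)
    return clusters


def estimate_species_count(
    marker_genes_by_family: dict[str, list[GeneRecord]],
    threshold: float = 0.97,
) -> tuple[int, dict[str, int]]:
    """Median 97%-identity cluster count across single-copy marker families.

    Returns (median count, per-family counts).  The low median is used so
    the summary is always one of the observed integer counts.
    """
    if not marker_genes_by_family:
        raise ValueError("no marker families supplied")
    per_family = {
        fam: len(cluster_identity(genes, threshold))
        for fam, genes in marker_genes_by_family.items()
        if genes
    }
    if not per_family:
        raise ValueError("every marker family is empty")
    return median_low(sorted(per_family.values())), per_family


def best_hit(
    query: GeneRecord,
    targets: list[GeneRecord],
    min_identity: float = 0.4,
    min_coverage: float = 0.5,
) -> tuple[GeneRecord, float] | None:
    """Highest-scoring global-protein-alignment target for a query gene.

    Candidates must reach `min_identity` over alignment columns and a
    mutual length coverage min(len)/max(len) ≥ `min_coverage`.  Score ties
    break by identity, then by lexically smaller gene_id.
    """
    best: tuple[float, float, GeneRecord] | None = None
    for t in targets:
        la, lb = len(query.protein), len(t.protein)
        if la == 0 or lb == 0:
            continue
        if min(la, lb) / max(la, lb) < min_coverage:
            continue
        ident = pairwise_identity(query.protein, t.protein)
        if ident < min_identity:
            continue
        score = alignment_score(query.protein, t.protein)
        if (
            best is None
            or score > best[0]
            or (score == best[0] and ident > best[1])
            or (score == best[0] and ident == best[1] and t.gene_id < best[2].gene_id)
        ):
            best = (score, ident, t)
    if best is None:
        return None
    return best[2], best[0]


def reciprocal_best_hits(
    set_a: list[GeneRecord],
    set_b: list[GeneRecord],
    min_identity: float = 0.4,
    min_coverage: float = 0.5,
) -> list[OrthologPair]:
    """Pairs (a, b) where each is the other's best hit across the two sets."""
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    fwd: dict[str, str] = {}
    for a in set_a:
        hit = best_hit(a, set_b, min_identity, min_coverage)
        if hit is not None:
            fwd[a.gene_id] = hit[0].gene_id
    rev: dict[str, str] = {}
    for b in set_b:
        hit = best_hit(b, set_a, min_identity, min_coverage)
        if hit is not None:
            rev[b.gene_id] = hit[0].gene_id
    by_id = {g.gene_id: g for g in set_a}
    pairs = []
    for a_id, b_id in sorted(fwd.items()):
        if rev.get(b_id) == a_id:
            a = by_id[a_id]
            b = next(g for g in set_b if g.gene_id == b_id)
            pairs.append(
                OrthologPair(
                    gene_a=a_id,
                    gene_b=b_id,
                    score=alignment_score(a.protein, b.protein),
                    identity=pairwise_identity(a.protein, b.protein),
                )
            )
    return pairs


def partition_gene_sets(
    pop_genes: list[GeneRecord],
    endo_ref: list[GeneRecord],
    free_refs: list[list[GeneRecord]],
    min_identity: float = 0.4,
    min_coverage: float = 0.5,
) -> GeneSetPartition:
    """Demarcate population genes into core / free-living / endosymbiont sets.

    RBH in the endosymbiont reference AND ≥1 free-living reference → core;
    only endosymbiont → endosymbiont; only free-living → free_living;
    no RBH anywhere → unassigned.
    """
    if not pop_genes:
        raise ValueError("no population genes to partition")
    if not endo_ref or not free_refs or any(not r for r in free_refs):
        raise ValueError("each lifestyle group needs at least one reference proteome")

    def rbh_ids(ref: list[GeneRecord]) -> dict[str, str]:
        pairs = reciprocal_best_hits(pop_genes, ref, min_identity, min_coverage)
        return {p.gene_a: p.gene_b for p in pairs}

    endo_hits = rbh_ids(endo_ref)
    free_hits: dict[str, str] = {}
    for ref in free_refs:
        for gid, hit in rbh_ids(ref).items():
            free_hits.setdefault(gid, hit)

    assignments: dict[str, str] = {}
    best_hits: dict[str, dict[str, str]] = {}
    for g in pop_genes:
        in_endo = g.gene_id in endo_hits
        in_free = g.gene_id in free_hits
        if in_endo and in_free:
            cat = "core"
        elif in_endo:
            cat = "endosymbiont"
        elif in_free:
            cat = "free_living"
        else:
            cat = "unassigned"
        assignments[g.gene_id] = cat
        best_hits[g.gene_id] = {
            k: v
            for k, v in (
                ("endosymbiont", endo_hits.get(g.gene_id)),
                ("free_living", free_hits.get(g.gene_id)),
            )
            if v is not None
        }
    return GeneSetPartition(assignments=assignments, best_hits=best_hits)
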