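"""Seeded synthetic communities with the statistical structure the analysis
pipeline assumes.

The generator emulates, at desk scale, the inputs of a population-genomics
study of a dominant freshwater bacterium:

* source genomes with distinct GC content and tetranucleotide spectra
  (order-k Markov chains whose per-context transition tables are seeded per
  genome, with stationary GC pinned to the target), fragmented into contigs;
* orthologous gene pairs evolved from a common ancestor at a specified
  dN/dS (ω) — synonymous proposals always accepted, nonsynonymous proposals
  accepted with probability min(ω, 1), stop-creating proposals re-drawn —
  with synonymous codon choice Boltzmann-weighted to a tunable codon usage
  bias strength;
* lifestyle-specific gene presence/absence against endosymbiont and
  free-living reference proteomes;
* biallelic SNP allele-count profiles whose per-population frequencies
  follow a Balding–Nichols spread around a shared ancestral frequency, so
  the divergence knob approximates the expected Fst;
* site coordinates (the packaged waterway monitoring stations) and
  per-site abundance vectors for distance-decay statistics.

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .binning import Contig
from .genesets import GeneRecord
from .genetics import (
    AA_TO_CODONS,
    AMINO_ACIDS,
    CODON_TO_AA,
    NUCLEOTIDES,
    is_stop,
    translate,
)
from .popgen import SnpMatrix, load_caws_sites

_NT_TO_I = {c: i for i, c in enumerate(NUCLEOTIDES)}
_ALTERNATIVES = {c: [x for x in NUCLEOTIDES if x != c] for c in NUCLEOTIDES}


# ---------------------------------------------------------------------------
# genomes and contigs


@dataclass
class GenomeTruth:
    genome_id: str
    sequence: str
    gc_target: float
    markov_order: int


def generate_genome(
    gc_target: float,
    length: int,
    markov_order: int = 2,
    seed: int = 0,
    genome_id: str | None = None,
) -> GenomeTruth:
    """Sample a genome from a seeded order-k Markov chain.

    Every context's transition distribution carries exactly `gc_target` GC
    mass, split between G/C (and A/T) by context-specific seeded weights, so
    the realised GC tracks the target while different seeds give genomes
    with distinct tetranucleotide spectra.
    """
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must lie strictly within (0, 1)")
    if length <= 0:
        raise ValueError("length must be positive")
    if markov_order < 0:
        raise ValueError("markov_order must be >= 0")
    rng = np.random.default_rng(seed)
    k = markov_order
    n_ctx = 4**k
    # per context: GC split gc*(u, 1-u) over G/C, AT split (1-gc)*(v, 1-v)
    u = rng.beta(1.0, 1.0, size=n_ctx)
    v = rng.beta(1.0, 1.0, size=n_ctx)
    probs = np.empty((n_ctx, 4))
    probs[:, 0] = (1.0 - gc_target) * v          # A
    probs[:, 1] = gc_target * (1.0 - u)          # C
    probs[:, 2] = gc_target * u                  # G
    probs[:, 3] = (1.0 - gc_target) * (1.0 - v)  # T
    cum = probs.cumsum(axis=1)
    cum[:, -1] = 1.0

    base = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    draws = rng.random(length)
    seq_idx = np.empty(length, dtype=np.intp)
    ctx = 0
    base_cum = base.cumsum()
    for i in range(min(k, length)):
        nt = int(np.searchsorted(base_cum, draws[i], side="right"))
        nt = min(nt, 3)
        seq_idx[i] = nt
        ctx = (ctx * 4 + nt) % n_ctx
    searchsorted = np.searchsorted
    for i in range(k, length):
        row = cum[ctx]
        nt = int(searchsorted(row, draws[i], side="right"))
        nt = min(nt, 3)
        seq_idx[i] = nt
        ctx = (ctx * 4 + nt) % n_ctx
    sequence = "".join(NUCLEOTIDES[i] for i in seq_idx)
    gid = genome_id if genome_id is not None else f"genome_s{seed}"
    return GenomeTruth(
        genome_id=gid, sequence=sequence, gc_target=gc_target, markov_order=k
    )


def fragment_contigs(
    genome: GenomeTruth,
    n: int,
    length_mean: int = 10_000,
    length_sd: int = 2_000,
    min_len: int = 300,
    seed: int = 0,
) -> list[Contig]:
    """Sample n contigs uniformly in position with truncated-normal lengths.

    Every contig carries the source genome id as its truth label; no length
    falls below `min_len`.
    """
    if min_len < 300:
        raise ValueError("min_len must be at least 300")
    if length_mean <= min_len:
        raise ValueError("length_mean must exceed min_len")
    glen = len(genome.sequence)
    if glen < min_len:
        raise ValueError("genome is shorter than the minimum contig length")
    rng = np.random.default_rng(seed)
    contigs = []
    for i in range(n):
        while True:
            length = int(round(rng.normal(length_mean, length_sd)))
            if min_len <= length <= glen:
                break
        start = int(rng.integers(0, glen - length + 1))
        contigs.append(
            Contig(
                contig_id=f"{genome.genome_id}_c{i:04d}",
                sequence=genome.sequence[start : start + length],
                truth_label=genome.genome_id,
            )
        )
    return contigs


# ---------------------------------------------------------------------------
# coding sequences and ortholog pairs


@dataclass
class EvolvedPair:
    cds_a: str
    cds_b: str
    omega_true: float
    n_attempted_mutations: int
    seed: int


def _preferred_codon_weights(cub_strength: float, rng) -> dict[str, np.ndarray]:
    """Per-amino-acid Boltzmann weights over synonymous codons.

    One preferred codon per amino acid is drawn from the rng; it receives
    weight exp(cub_strength), the rest weight 1 (cub_strength = 0 gives
    uniform synonymous usage).
    """
    weights = {}
    for aa in AMINO_ACIDS:
        codons = AA_TO_CODONS[aa]
        w = np.ones(len(codons))
        preferred = int(rng.integers(0, len(codons)))
        w[preferred] = math.exp(cub_strength)
        weights[aa] = w / w.sum()
    return weights


def random_cds(
    n_codons: int, cub_strength: float = 0.0, seed: int = 0, rng=None
) -> str:
    """A random in-frame CDS: uniform amino acids, Boltzmann-biased codons."""
    if rng is None:
        rng = np.random.default_rng(seed)
    weights = _preferred_codon_weights(cub_strength, rng)
    out = []
    aas = rng.integers(0, len(AMINO_ACIDS), size=n_codons)
    for ai in aas:
        aa = AMINO_ACIDS[ai]
        codons = AA_TO_CODONS[aa]
        ci = int(rng.choice(len(codons), p=weights[aa]))
        out.append(codons[ci])
    return "".join(out)


def mutate_cds(cds: str, omega: float, attempts: int, rng) -> str:
    """Propose `attempts` random single-nucleotide changes on a CDS.

    Stop-creating proposals are rejected and re-drawn without consuming an
    attempt; synonymous proposals are accepted with probability 1 and
    nonsynonymous proposals with probability min(omega, 1).
    """
    seq = list(cds)
    n = len(seq)
    done = 0
    while done < attempts:
        pos = int(rng.integers(0, n))
        current = seq[pos]
        alternatives = _ALTERNATIVES[current]
        nt = alternatives[int(rng.integers(0, 3))]
        cstart = (pos // 3) * 3
        old_codon = "".join(seq[cstart : cstart + 3])
        new_codon = (
            old_codon[: pos - cstart] + nt + old_codon[pos - cstart + 1 :]
        )
        if is_stop(new_codon):
            continue  # re-drawn, not counted
        done += 1
        if CODON_TO_AA[new_codon] == CODON_TO_AA[old_codon]:
            seq[pos] = nt
        elif rng.random() < min(omega, 1.0):
            seq[pos] = nt
    return "".join(seq)


def evolve_ortholog_pair(
    n_codons: int,
    omega_true: float,
    mutation_attempts: int,
    cub_strength: float = 0.0,
    seed: int = 0,
) -> EvolvedPair:
    """Evolve two descendants of a common ancestor at a known ω.

    The ancestor's synonymous codon choice follows the Boltzmann weighting
    of strength `cub_strength`; each descendant accumulates
    `mutation_attempts` proposed single-nucleotide changes independently.
    """
    if n_codons < 100:
        raise ValueError("n_codons must be >= 100 (NG86 unstable below)")
    if not 0.0 <= omega_true <= 1.5:
        raise ValueError("omega_true must lie in [0, 1.5]")
    if mutation_attempts < 0 or cub_strength < 0:
        raise ValueError("mutation_attempts and cub_strength must be non-negative")
    rng = np.random.default_rng(seed)
    ancestor = random_cds(n_codons, cub_strength=cub_strength, rng=rng)
    cds_a = mutate_cds(ancestor, omega_true, mutation_attempts, rng)
    cds_b = mutate_cds(ancestor, omega_true, mutation_attempts, rng)
    return EvolvedPair(
        cds_a=cds_a,
        cds_b=cds_b,
        omega_true=omega_true,
        n_attempted_mutations=mutation_attempts,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# SNP profiles


def generate_snp_profiles(
    n_snps: int,
    n_pops: int = 2,
    divergence: float = 0.3,
    depth: int = 100,
    seed: int = 0,
    populations: list[str] | None = None,
) -> SnpMatrix:
    """Biallelic allele counts with Balding–Nichols population spread.

    Per SNP, an ancestral frequency p0 ~ U(0.05, 0.95) is drawn and each
    population's frequency comes from Beta(p0(1-F)/F, (1-p0)(1-F)/F) with
    F = divergence, so the expected Fst tracks the divergence knob;
    divergence = 0 pins every population to p0 (differentiation only from
    binomial sampling at the given depth) and divergence = 1 fixes one or
    the other allele in each population.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if depth < 10:
        raise ValueError("depth must be >= 10")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    if n_pops < 2:
        raise ValueError("need at least 2 populations")
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.05, 0.95, size=n_snps)
    if divergence == 0.0:
        freqs = np.repeat(p0[:, None], n_pops, axis=1)
    elif divergence >= 1.0:
        freqs = rng.binomial(1, np.repeat(p0[:, None], n_pops, axis=1)).astype(float)
    else:
        f = divergence
        a = p0 * (1 - f) / f
        b = (1 - p0) * (1 - f) / f
        freqs = rng.beta(a[:, None], b[:, None], size=(n_snps, n_pops))
    allele1 = rng.binomial(depth, freqs)
    counts = np.stack([allele1, depth - allele1], axis=2)
    pops = populations or [f"pop_{i + 1}" for i in range(n_pops)]
    if len(pops) != n_pops:
        raise ValueError("populations list must have length n_pops")
    loci = [f"snp_{i + 1:05d}" for i in range(n_snps)]
    return SnpMatrix(counts=counts, populations=list(pops), loci=loci)


# ---------------------------------------------------------------------------
# whole community


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic community (all seeds derived from
    `seed`)."""

    seed: int = 0
    # genomes and contigs
    genomes: list[dict[str, Any]] = field(
        default_factory=lambda: [
            {"genome_id": "genome_lo", "gc_target": 0.35},
            {"genome_id": "genome_mid", "gc_target": 0.50},
            {"genome_id": "genome_hi", "gc_target": 0.65},
        ]
    )
    genome_length: int = 120_000
    markov_order: int = 2
    contigs_per_genome: int = 200
    contig_length_mean: int = 10_000
    contig_length_sd: int = 2_000
    min_contig_len: int = 300
    # lifestyle gene content
    n_core: int = 50
    n_free_living: int = 20
    n_endosymbiont: int = 10
    n_unassigned: int = 5
    n_free_refs: int = 2
    n_ref_decoys: int = 3
    gene_length_codons: int = 120
    ref_mutation_attempts: int = 25
    ref_omega: float = 0.5
    # single-copy markers (species richness truth)
    n_marker_families: int = 5
    n_strains: int = 3
    marker_length_codons: int = 150
    marker_mutation_attempts: int = 60
    # ortholog pairs for selection/CUB coupling
    n_ortholog_pairs: int = 60
    pair_codons: int = 300
    pair_mutation_attempts: int = 120
    omega_low: float = 0.05
    omega_high: float = 1.2
    cub_max: float = 3.0
    couple_cub_to_omega: bool = True
    # SNPs
    n_snps: int = 200
    snp_divergence: float = 0.3
    snp_depth: int = 100
    # sites and abundances
    n_taxa: int = 30

    def __post_init__(self) -> None:
        if len(self.genomes) < 2:
            raise ValueError("config must name at least 2 genomes")
        gcs = [g["gc_target"] for g in self.genomes]
        if len(set(gcs)) != len(gcs):
            raise ValueError("genomes must have distinct gc_target values")
        for c in (self.n_core, self.n_free_living, self.n_endosymbiont,
                  self.n_unassigned):
            if c < 0:
                raise ValueError("gene category counts must be non-negative")
        total_gene_bp = (
            (self.n_core + self.n_free_living + self.n_endosymbiont
             + self.n_unassigned) * self.gene_length_codons * 3
        )
        if total_gene_bp > len(self.genomes) * self.genome_length:
            raise ValueError("gene category counts exceed community gene capacity")

    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SyntheticCommunity:
    config: GeneratorConfig
    genomes: list[GenomeTruth]
    contigs: list[Contig]
    pop_genes: list[GeneRecord]
    endo_ref: list[GeneRecord]
    free_refs: list[list[GeneRecord]]
    gene_truth: pd.DataFrame  # gene_id, category
    marker_families: dict[str, list[GeneRecord]]
    pairs: dict[str, EvolvedPair]
    ortholog_truth: pd.DataFrame  # pair_id, omega_true, cub_strength, category
    snps: SnpMatrix
    sites: pd.DataFrame
    abundances: pd.DataFrame

    @property
    def truth_labels(self) -> dict[str, str]:
        return {c.contig_id: c.truth_label for c in self.contigs}


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def generate_community(config: GeneratorConfig | None = None) -> SyntheticCommunity:
    """Generate a fully labelled synthetic community from one config."""
    config = config or GeneratorConfig()
    seeds = iter(_child_seeds(config.seed, 10_000))

    genomes = [
        generate_genome(
            gc_target=g["gc_target"],
            length=config.genome_length,
            markov_order=config.markov_order,
            seed=next(seeds),
            genome_id=g["genome_id"],
        )
        for g in config.genomes
    ]
    contigs: list[Contig] = []
    for g in genomes:
        contigs.extend(
            fragment_contigs(
                g,
                n=config.contigs_per_genome,
                length_mean=config.contig_length_mean,
                length_sd=config.contig_length_sd,
                min_len=config.min_contig_len,
                seed=next(seeds),
            )
        )

    # lifestyle gene content: population gene + reference copies by category
    rng = np.random.default_rng(next(seeds))
    pop_genes: list[GeneRecord] = []
    endo_ref: list[GeneRecord] = []
    free_refs: list[list[GeneRecord]] = [[] for _ in range(config.n_free_refs)]
    truth_rows = []
    plan = (
        [("core", i) for i in range(config.n_core)]
        + [("free_living", i) for i in range(config.n_free_living)]
        + [("endosymbiont", i) for i in range(config.n_endosymbiont)]
        + [("unassigned", i) for i in range(config.n_unassigned)]
    )
    for category, i in plan:
        gid = f"{category}_{i:04d}"
        ancestor = random_cds(config.gene_length_codons, cub_strength=1.0, rng=rng)
        pop_cds = mutate_cds(
            ancestor, config.ref_omega, config.ref_mutation_attempts, rng
        )
        pop_genes.append(GeneRecord(gene_id=gid, cds=pop_cds))
        truth_rows.append({"gene_id": gid, "category": category})
        if category in ("core", "endosymbiont"):
            ref_cds = mutate_cds(
                ancestor, config.ref_omega, config.ref_mutation_attempts, rng
            )
            endo_ref.append(GeneRecord(gene_id=f"endo_{gid}", cds=ref_cds))
        if category in ("core", "free_living"):
            for r, ref in enumerate(free_refs):
                ref_cds = mutate_cds(
                    ancestor, config.ref_omega, config.ref_mutation_attempts, rng
                )
                ref.append(GeneRecord(gene_id=f"free{r}_{gid}", cds=ref_cds))
    # private reference decoys (present in a reference, absent from the
    # population) so unassigned genes face realistic negative targets
    for r, ref in enumerate([endo_ref] + free_refs):
        for i in range(config.n_ref_decoys):
            ref.append(
                GeneRecord(
                    gene_id=f"decoy_r{r}_{i:03d}",
                    cds=random_cds(config.gene_length_codons, rng=rng),
                )
            )
    gene_truth = pd.DataFrame(truth_rows)

    # single-copy marker families with n_strains diverged variants each
    marker_families: dict[str, list[GeneRecord]] = {}
    for f in range(config.n_marker_families):
        fam = f"marker_{f:02d}"
        ancestor = random_cds(config.marker_length_codons, rng=rng)
        variants = []
        for s in range(config.n_strains):
            cds = mutate_cds(ancestor, 1.0, config.marker_mutation_attempts, rng)
            variants.append(GeneRecord(gene_id=f"{fam}_strain{s}", cds=cds))
        marker_families[fam] = variants

    # ortholog pairs with known omega and codon-bias strength
    pairs: dict[str, EvolvedPair] = {}
    pair_rows = []
    pair_categories = ("core", "free_living", "endosymbiont")
    for i in range(config.n_ortholog_pairs):
        omega = float(rng.uniform(config.omega_low, config.omega_high))
        if config.couple_cub_to_omega:
            span = config.omega_high - config.omega_low
            cub = config.cub_max * (config.omega_high - omega) / span
        else:
            cub = float(rng.uniform(0.0, config.cub_max))
        pair_id = f"pair_{i:04d}"
        pair = evolve_ortholog_pair(
            n_codons=config.pair_codons,
            omega_true=omega,
            mutation_attempts=config.pair_mutation_attempts,
            cub_strength=cub,
            seed=next(seeds),
        )
        pairs[pair_id] = pair
        pair_rows.append(
            {
                "pair_id": pair_id,
                "omega_true": omega,
                "cub_strength": cub,
                "category": pair_categories[i % len(pair_categories)],
            }
        )
    ortholog_truth = pd.DataFrame(pair_rows)

    sites = load_caws_sites()
    snps = generate_snp_profiles(
        n_snps=config.n_snps,
        n_pops=len(sites),
        divergence=config.snp_divergence,
        depth=config.snp_depth,
        seed=next(seeds),
        populations=list(sites.index),
    )
    abund = np.random.default_rng(next(seeds)).dirichlet(
        np.full(config.n_taxa, 0.8), size=len(sites)
    )
    abundances = pd.DataFrame(
        abund,
        index=sites.index,
        columns=[f"taxon_{i:03d}" for i in range(config.n_taxa)],
    )
    return SyntheticCommunity(
        config=config,
        genomes=genomes,
        contigs=contigs,
        pop_genes=pop_genes,
        endo_ref=endo_ref,
        free_refs=free_refs,
        gene_truth=gene_truth,
        marker_families=marker_families,
        pairs=pairs,
        ortholog_truth=ortholog_truth,
        snps=snps,
        sites=sites,
        abundances=abundances,
    )
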