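# Methods

This note documents the models implemented in `strainscope`, the choices
made where several constructions were defensible, and what the synthetic
validation does and does not establish about real data.

## Composition-based genotype binning

Each contig is summarised by its tetranucleotide frequency (TNF) profile:
all 256 overlapping 4-mers counted with step 1 on the sequence **and** its
reverse complement, normalised to sum 1. Counting both strands makes the
profile strand-symmetric by construction — `profile(s) ==
profile(revcomp(s))` — without collapsing to the 136 canonical words.
Windows containing an ambiguous base (N) are skipped; GC content is
(G+C)/(A+C+G+T) with N excluded from both numerator and denominator.

Profiles are clustered by average-linkage hierarchical agglomeration on the
distance d = 1 − R², where R is the Pearson correlation between two
256-vectors, and the dendrogram is cut at d = 1 − r²_cutoff (default
R² = 0.9, i.e. contigs merge while their interprofile correlation stays
high). Average linkage was chosen because it compares group-mean profile
similarity, matching the "interprofile correlation" reading; the cutoff,
the ≥300 bp length filter (a 300 bp contig is kept; 299 bp is dropped), and
the linkage are all exposed in `BinningConfig`. GC is deliberately *not*
part of the clustering feature vector — it is used only by the chimera
filter — but a config switch (`cluster_on_gc`) records that the design was
open. A constant (zero-variance) profile has no defined correlation; such
contigs are placed in flagged singleton bins rather than crashing the run.

Bin refinement is a single pass: the bin's mean GC and sample SD (ddof = 1)
are computed once over the full membership, and members deviating by
strictly more than `multiplier`·SD (default 1.0) are removed; statistics
are not recomputed during the pass, and bins with fewer than 3 members are
left untouched because the sample SD is unstable there. Recovery is scored
as the adjusted Rand index (scikit-learn) between the bin partition and the
generator's truth labels. Taxonomic contaminant screening against a trained
classifier is out of scope; in synthetic mode the truth labels provide the
equivalent contamination report.

## Ortholog detection and lifestyle partitioning

Protein pairs are aligned globally (Needleman–Wunsch, BLOSUM62, gap open
−11 for the first gap position, −1 per extension, via Biopython's
`PairwiseAligner`; non-standard residues map to X and score 0 against
everything). A *best hit* is the highest-scoring target that also reaches
40 % identity over alignment columns (gaps count as mismatch — this
denominator makes the 97 % marker threshold reproducible) and a mutual
length coverage min(len)/max(len) ≥ 0.5; score ties break by identity, then
by lexically smaller gene id, so the search is deterministic. Score-only
alignments are computed first and tracebacks only for candidates, which
keeps reciprocal-best-hit (RBH) searches tractable at desk scale.

A population gene with an RBH in the endosymbiont reference **and** in at
least one free-living reference is *core*; only endosymbiont →
*endosymbiont*-specific; only free-living → *free-living*-specific; no RBH →
*unassigned*. "Core" requires presence in both lifestyles rather than in
every reference, which is the natural reading of a three-way demarcation
with two free-living references. Reports emit both raw counts and
fractions of assigned genes, since lifestyle fractions are
denominator-sensitive.

Species richness per site uses single-copy markers: each family is
clustered greedily at 97 % nucleotide identity (longest-first, join the
first representative at ≥ threshold) and the low median of the per-family
cluster counts is reported, so the summary is always an observed integer.

## NG86 dN/dS

Synonymous sites per codon: at each position, the site splits into the
synonymous fraction of its single-nucleotide neighbours, with mutations to
stop codons excluded from numerator *and* denominator — so S + N = 3 per
sense codon exactly. Differences between two codons differing at k
positions are averaged uniformly over all k! single-step orderings;
orderings whose intermediates hit a stop codon are discarded and the
average renormalised over the survivors (if none survive, all k differences
count as nonsynonymous). Both routines are table-driven (61 and 61×61
caches), and the test suite checks the full 61×61 sweep against an
independently written brute-force enumerator to 1e-9.

Codon alignments come from back-threading each CDS through the global
protein alignment; gap columns become gap triplets and are excluded, and
terminal stop codons are dropped before counting. Proportions pS = Sd/S and
pN = Nd/N are Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3). ω = dN/dS is
*undefined* (NaN, flagged `dS_zero`) when dS = 0 and flagged `saturated`
when p ≥ 3/4; undefined ω is excluded from medians and correlations rather
than propagating infinities. Classification: ω < 1 purifying, ω > 1
positive, undefined or exactly 1 neutral/undetermined. This is a
deterministic counting estimator, not a maximum-likelihood codon model; in
the mostly-purifying, low-divergence regime it targets, the two agree well,
and a cross-check against an independently maintained NG86 implementation
(which keeps slightly different stop-codon site bookkeeping) is part of the
suite at loose tolerance.

## Codon deviation coefficient

The null expectation for codon usage is factorised from the gene's own
positional composition: with gc_p and pur_p the GC and purine fractions at
codon position p, P(G) = gc·pur, P(A) = (1−gc)·pur, P(C) = gc·(1−pur),
P(T) = (1−gc)·(1−pur), codon probability = product over its three
positions, stop codons removed and the 61-vector renormalised. CDC = 1 −
cosine similarity between observed and expected usage, so a gene matching
its compositional expectation scores exactly 0 (any single-codon gene does)
and CDC ∈ [0, 1] always. Significance is a parametric bootstrap: same-length
genes resampled codon-by-codon from the expectation, scored against that
same expectation, add-one p = (1 + #{CDC* ≥ CDC})/(1 + n_boot). An optional
`expected` argument lets callers score against an external (e.g.
genome-wide) null. Genes under 30 codons are computed but flagged
low-confidence. ENC/CAI/RSCU are deliberately not implemented.

## Coupling and selection summaries

Per lifestyle category, the correlation between ω and the arithmetic mean
CDC of the two orthologs is computed with Spearman by default — ω
distributions are heavy-tailed, and rank correlation is invariant to
monotone transforms — with Pearson behind a flag. Categories with fewer
than 3 usable pairs or a constant variable yield an undefined (NaN) result
rather than an exception. Because three categories are tested, raw and
Bonferroni-adjusted p-values are reported side by side. Selection summaries
give the median over defined ω, the count of fast-evolving pairs (ω > 1),
and the count of undefined ω per group (site or category — both groupings
are supported, since per-gene medians could reasonably be keyed either way).

## Population genetics and biogeography

Per-locus Fst uses the heterozygosity form for pooled allele counts:
Hw = mean within-population 1 − Σp², Ht = 1 − Σp̄² on the unweighted mean
frequency; Fst = (Ht − Hw)/Ht, undefined (and skipped) when Ht = 0, and the
population-pair value is the unweighted mean over informative loci.
Geographic distances are haversine with Earth radius fixed at 6371.0 km.
Bray–Curtis is Σ|x−y|/Σ(x+y) (scipy). Shannon H uses natural logarithms so
Pielou J = H/ln S (J undefined at S = 1); the log base is recorded in the
output header. The Mantel statistic is the Pearson correlation of
upper-triangle entries; the null jointly permutes rows and columns of the
second matrix, and p is two-sided add-one over n_perm ≥ 99 permutations.
Distance decay fits an OLS slope (dissimilarity per km) over site pairs and
attaches the Mantel test.

## The synthetic generator

The generator defines the study conditions for all validation:

* **Genomes** are order-k Markov chains (default k = 2). Every context's
  transition distribution carries exactly the target GC mass, split
  between G/C (and A/T) by context-specific weights drawn uniformly on
  (0, 1) per genome seed. The uniform draw gives each genome strong,
  distinct word preferences — the realised GC stays on target (within
  ±0.03 at ≥50 kb) while tetranucleotide spectra differ genome to genome,
  which is the property the binner consumes. The default community is
  three genomes at GC 0.35/0.50/0.65, 120 kb each, fragmented into 200
  contigs of ~10 kb (truncated normal, floor 300 bp).
* **Ortholog pairs** descend from a common ancestor whose synonymous codon
  choice is Boltzmann-weighted (one seeded preferred codon per amino acid,
  weight e^strength; strength 0 ⇒ uniform). Each descendant receives a
  fixed budget of proposed single-nucleotide changes: stop-creating
  proposals are re-drawn without consuming the budget, synonymous
  proposals are always accepted, nonsynonymous ones with probability
  min(ω, 1). Because proposals are uniform over positions and nucleotides —
  exactly the neighbourhood NG86 sites count — the NG86 estimate converges
  near the simulated ω at low divergence, which the recovery tests
  quantify (median ω̂ within [0.05, 0.20] / [0.35, 0.65] / [0.8, 1.2] for
  ω = 0.1 / 0.5 / 1.0 at 500 codons, 150 attempts, 200 replicates).
* **SNP profiles** follow Balding–Nichols: ancestral frequency
  p0 ~ U(0.05, 0.95) per locus, population frequencies from
  Beta(p0(1−F)/F, (1−p0)(1−F)/F) with F the divergence knob, binomially
  sampled at the configured depth — so expected Fst tracks F, F = 0 leaves
  only sampling noise, and F = 1 fixes alleles.
* **Lifestyle gene content** plants each population gene's orthologs in
  the reference proteomes its category dictates (plus private decoys in
  every reference), so partition recovery has exact truth.
* **Sites** are the seven packaged waterway monitoring stations
  (coordinates, physicochemistry, diversity); per-site abundance vectors
  are Dirichlet draws for distance-decay exercises.

Everything is a pure function of (config, seed); whole-community runs are
byte-identical for a fixed seed.

What the generator does **not** emulate: sequencing error and read-level
artefacts (the pipeline starts from contigs), assembly chimerism beyond the
GC-outlier model, repeat content, horizontal transfer, within-population
ω heterogeneity along a gene, and realistic genome sizes (the defaults are
deliberately desk-scale: ~120 kb genomes, hundreds of contigs, tens to
hundreds of gene pairs — chosen so a full run finishes in seconds while
leaving enough statistical power for the recovery windows). Passing tests
therefore establish the *estimators and their couplings* are correct and
calibrated, not that any particular field system behaves this way. The
in-situ strain divergence of real populations is unknown; demo configs
expose `snp_divergence` as a free parameter rather than asserting a
field value.

## Numerical and degenerate-input conventions

* Cosine distances are clipped to [0, 1]; values within 1e-12 of 0 snap to
  0 so the "matches own expectation" identity is exact.
* The condensed distance matrix for clustering is symmetrised and clipped
  at 0 before linkage to absorb floating-point asymmetry.
* Jukes–Cantor saturation (p ≥ 3/4) yields NaN plus a flag, never an
  exception; empty comparable-column sets raise.
* Identity tie-breaks everywhere are deterministic (lexical ids,
  longest-first orderings), so shuffled inputs reproduce the same results.
* All permutation p-values are add-one, bounded below by 1/(n_perm + 1).

## Known limitations

* NG86 with JC correction underestimates ω when transition/transversion
  bias or codon-frequency asymmetry is strong; no ML codon models are
  provided.
* The CDC expectation assumes positional independence of nucleotide
  composition; genes with strong dinucleotide constraints (e.g. CpG-like
  avoidance) will show nonzero CDC under the null.
* Average-linkage TNF clustering has no coverage signal, so strains with
  near-identical composition cannot be separated — by design, matching the
  composition-only binning it implements.
* The Fst estimator ignores unequal pool depths beyond binomial sampling
  and applies no small-sample bias correction.
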