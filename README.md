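# strainscope

Strain-level population genomics from metagenome contigs: who is this for,
and what does it compute?

Dominant freshwater bacteria such as *Polynucleobacter* often show
strain-level endemism — near-identical 16S sequences, yet site-specific
population genomes. Testing whether *local functional constraints* (rather
than dispersal limitation) maintain that endemism requires a chain of
population-genomic analyses that are usually scattered across ad-hoc
scripts. `strainscope` packages that chain as a tested, seedable pipeline
for microbial ecologists working from assembled contigs:

1. **Genotype binning** — contigs are summarised by strand-symmetric
   tetranucleotide frequency (TNF) profiles and clustered by average-linkage
   agglomeration on d = 1 − R² (R = Pearson correlation of 256-mers),
   cut at R² = 0.9; bins are refined by removing chimeric contigs whose GC
   deviates from the bin mean by more than 1 sample SD.
2. **Gene-set partitioning** — reciprocal best hits (RBH) against
   endosymbiont and free-living reference proteomes demarcate population
   genes into core / free-living / endosymbiont repertoires; single-copy
   marker genes clustered at 97 % identity estimate species richness.
3. **Selection** — pairwise dN/dS by Nei–Gojobori (1986) counting:
   per-codon synonymous site fractions, pathway-averaged difference counts
   (stop-crossing paths excluded), Jukes–Cantor correction
   d = −(3/4)·ln(1 − 4p/3), ω = dN/dS.
4. **Codon usage bias** — the codon deviation coefficient (CDC):
   cosine distance between a gene's observed sense-codon usage and the
   expectation factorised from its positional GC and purine content.
5. **Coupling** — the headline statistic: per lifestyle category, the
   Spearman correlation between ω and pair-mean CDC. Strong in-situ
   functional constraints predict a negative correlation (codon-optimised
   genes sit under stronger purifying selection).
6. **Biogeography** — pooled-SNP pairwise Fst ((Ht − Hw)/Ht per locus),
   haversine geographic distances, Bray–Curtis dissimilarity, Shannon H and
   Pielou J, and Mantel distance-decay tests.

Because real deep metagenomes are impractical for testing, the package
includes a first-class synthetic-community generator (`strainscope.synthetic`)
that plants known genome signatures, gene categories, ω values, codon-bias
strengths, and SNP divergences, so every stage can be validated against
ground truth. See `docs/methods.md` for the models and their assumptions.

## Worked example

```python
from strainscope import evolve_ortholog_pair, dnds_from_cds, pair_mean_cdc

pair = evolve_ortholog_pair(n_codons=300, omega_true=0.1,
                            mutation_attempts=120, cub_strength=2.0, seed=42)
res = dnds_from_cds(pair.cds_a, pair.cds_b, pair_id="demo")
print(f"dN = {res.dN:.4f}  dS = {res.dS:.4f}  omega = {res.omega:.3f}")
print(f"pair-mean CDC = {pair_mean_cdc(pair.cds_a, pair.cds_b):.3f}")
```

prints

```
dN = 0.0274  dS = 0.3010  omega = 0.091
pair-mean CDC = 0.244
```

The pair was simulated under strong purifying selection (ω = 0.1) with a
strong codon preference; the NG86 estimate (0.091) recovers the simulated ω,
and the CDC (0.244) reflects the injected bias.

The full pipeline runs from one command:

```bash
strainscope demo --outdir demo_out --seed 1
```

which simulates a 3-genome community (GC 0.35 / 0.50 / 0.65, 200 contigs of
~10 kb each), bins it, partitions genes, estimates selection and codon bias,
and correlates them. Key outputs from that run:

* `bin_recovery.tsv` — adjusted Rand index 1.0 (perfect genotype recovery);
* `species_counts.tsv` — median marker-based species estimate 3 (the number
  of planted strains);
* `coupling.tsv` — Spearman ρ = −0.92 (core), −0.84 (free-living), both
  p < 1e-5: the simulated coupling of high codon bias to low ω is recovered
  as a significant negative correlation;
* `selection_summary.tsv` — per-category median ω and fast-evolving
  (ω > 1) counts.

Each stage is also available as its own subcommand (`simulate`, `bin`,
`genesets`, `select`, `cub`, `popgen`, `couple`) over a shared output
directory, with `--config` taking a YAML file of all parameters.

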