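"""End-to-end pipeline orchestration.

Stages run in dependency order over a shared output directory:

    simulate  → contigs, CDS sets, reference proteomes, truth tables
    bin       → TNF clustering, chimera filtering, bin QC
    genesets  → lifestyle partition, species-count estimate
    evolution → per-pair dN/dS (NG86) and codon deviation coefficients
    popgen    → Fst matrix, geographic/Bray-Curtis distances, Mantel decay
    coupling  → per-category ω–CDC correlation and selection summaries

Every stage is a pure function of (files on disk, config), all randomness is
seeded from the run config, and the manifest records a SHA-256 checksum per
output so a re-run with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__, binning, coupling, popgen, selection
from .codonbias import CodonBiasResult, cdc, pair_mean_cdc
from .genesets import GeneRecord, estimate_species_count, partition_gene_sets
from .io import read_fasta, read_table, write_fasta, write_table
from .synthetic import GeneratorConfig, generate_community

STAGES = ("simulate", "bin", "genesets", "evolution", "popgen", "coupling")


@dataclass
class PipelineConfig:
    outdir: str = "strainscope_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    binning: binning.BinningConfig = field(default_factory=binning.BinningConfig)
    min_identity: float = 0.4
    min_coverage: float = 0.5
    marker_identity: float = 0.97
    min_pair_bp: int = 300
    coupling_method: str = "spearman"
    n_perm: int = 999
    make_plots: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # every stage's inputs must come from an enabled earlier stage or disk
        self.generator.seed = self.seed

    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            d["generator"] = GeneratorConfig(**d["generator"])
        if "binning" in d and isinstance(d["binning"], dict):
            d["binning"] = binning.BinningConfig(**d["binning"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunManifest:
    config: dict[str, Any]
    stages: list[dict[str, Any]]
    version: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"version": self.version, "config": self.config, "stages": self.stages},
                fh,
                indent=2,
                default=str,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(out: Path, cfg: PipelineConfig) -> list[Path]:
    community = generate_community(cfg.generator)
    paths = []

    contigs = {c.contig_id: c.sequence for c in community.contigs}
    p = out / "contigs.fasta"
    write_fasta(contigs, p)
    paths.append(p)

    truth = pd.DataFrame(
        {
            "contig_id": [c.contig_id for c in community.contigs],
            "genome_id": [c.truth_label for c in community.contigs],
        }
    )
    p = out / "contig_truth.tsv"
    write_table(truth, p, "simulate", {"seed": cfg.seed})
    paths.append(p)

    p = out / "population_genes.fasta"
    write_fasta({g.gene_id: g.cds for g in community.pop_genes}, p)
    paths.append(p)
    p = out / "ref_endosymbiont.fasta"
    write_fasta({g.gene_id: g.cds for g in community.endo_ref}, p)
    paths.append(p)
    for i, ref in enumerate(community.free_refs):
        p = out / f"ref_free_living_{i}.fasta"
        write_fasta({g.gene_id: g.cds for g in ref}, p)
        paths.append(p)

    p = out / "gene_truth.tsv"
    write_table(community.gene_truth, p, "simulate", {"seed": cfg.seed})
    paths.append(p)

    markers = {
        g.gene_id: g.cds
        for fam in community.marker_families.values()
        for g in fam
    }
    p = out / "markers.fasta"
    write_fasta(markers, p)
    paths.append(p)
    marker_table = pd.DataFrame(
        [
            {"gene_id": g.gene_id, "family": fam}
            for fam, genes in community.marker_families.items()
            for g in genes
        ]
    )
    p = out / "marker_families.tsv"
    write_table(marker_table, p, "simulate", {"seed": cfg.seed})
    paths.append(p)

    pair_seqs = {}
    for pid, pair in community.pairs.items():
        pair_seqs[f"{pid}_a"] = pair.cds_a
        pair_seqs[f"{pid}_b"] = pair.cds_b
    p = out / "ortholog_pairs.fasta"
    write_fasta(pair_seqs, p)
    paths.append(p)
    p = out / "ortholog_truth.tsv"
    write_table(community.ortholog_truth, p, "simulate", {"seed": cfg.seed})
    paths.append(p)

    snp_rows = []
    for i, locus in enumerate(community.snps.loci):
        for j, pop in enumerate(community.snps.populations):
            snp_rows.append(
                {
                    "locus": locus,
                    "population": pop,
                    "allele1_count": int(community.snps.counts[i, j, 0]),
                    "allele2_count": int(community.snps.counts[i, j, 1]),
                }
            )
    p = out / "snps.tsv"
    write_table(pd.DataFrame(snp_rows), p, "simulate", {"seed": cfg.seed})
    paths.append(p)

    p = out / "sites.tsv"
    write_table(community.sites.reset_index(), p, "simulate", {})
    paths.append(p)
    p = out / "abundances.tsv"
    write_table(community.abundances.reset_index(), p, "simulate", {"seed": cfg.seed})
    paths.append(p)
    return paths


def stage_bin(out: Path, cfg: PipelineConfig) -> list[Path]:
    contigs_path = out / "contigs.fasta"
    if not contigs_path.exists():
        raise FileNotFoundError(
            "stage 'bin' needs contigs.fasta (enable 'simulate' or provide input)"
        )
    seqs = read_fasta(contigs_path)
    contigs = [binning.Contig(contig_id=k, sequence=v) for k, v in seqs.items()]
    contigs = binning.filter_contigs(contigs, cfg.binning.min_contig_len)
    profiles = [binning.tnf_profile(c) for c in contigs]
    lengths = {c.contig_id: c.length for c in contigs}
    by_id = {c.contig_id: c for c in contigs}
    bins = binning.cluster_contigs(profiles, cfg.binning, contig_lengths=lengths)

    refined = []
    removed_all: dict[str, str] = {}
    for b in bins:
        rb, removed = binning.remove_chimeric(
            b, by_id, multiplier=cfg.binning.gc_sd_multiplier
        )
        refined.append(rb)
        for cid in removed:
            removed_all[cid] = b.bin_id

    member_rows = []
    for b in refined:
        for cid in b.contig_ids:
            member_rows.append(
                {
                    "contig_id": cid,
                    "bin_id": b.bin_id,
                    "gc": round(by_id[cid].gc, 6),
                    "length": by_id[cid].length,
                }
            )
    for cid, bid in removed_all.items():
        member_rows.append(
            {
                "contig_id": cid,
                "bin_id": "removed_chimeric",
                "gc": round(by_id[cid].gc, 6),
                "length": by_id[cid].length,
            }
        )
    paths = []
    p = out / "bin_membership.tsv"
    write_table(
        pd.DataFrame(member_rows), p, "bin",
        {"r2_cutoff": cfg.binning.r2_cutoff, "linkage": cfg.binning.linkage},
    )
    paths.append(p)

    qc_rows = [
        {
            "bin_id": b.bin_id,
            "n_contigs": len(b.contig_ids),
            "total_bp": b.total_bp,
            "n50": b.n50,
            "mean_gc": round(b.mean_gc, 6),
            "sd_gc": round(b.sd_gc, 6),
            "removed_chimeras": sum(
                1 for bid in removed_all.values() if bid == b.bin_id
            ),
        }
        for b in refined
    ]
    p = out / "bin_qc.tsv"
    write_table(pd.DataFrame(qc_rows), p, "bin", {"gc_sd_multiplier": cfg.binning.gc_sd_multiplier})
    paths.append(p)

    for b in refined:
        p = out / "bins" / f"{b.bin_id}.fasta"
        write_fasta({cid: seqs[cid] for cid in b.contig_ids}, p)
        paths.append(p)

    truth_path = out / "contig_truth.tsv"
    if truth_path.exists():
        truth = dict(
            read_table(truth_path)[["contig_id", "genome_id"]].itertuples(
                index=False, name=None
            )
        )
        ari = binning.bin_recovery_score(refined, truth)
        p = out / "bin_recovery.tsv"
        write_table(
            pd.DataFrame([{"metric": "adjusted_rand_index", "value": ari}]),
            p, "bin", {},
        )
        paths.append(p)
    return paths


def stage_genesets(out: Path, cfg: PipelineConfig) -> list[Path]:
    pop_path = out / "population_genes.fasta"
    endo_path = out / "ref_endosymbiont.fasta"
    if not pop_path.exists() or not endo_path.exists():
        raise FileNotFoundError(
            "stage 'genesets' needs population_genes.fasta and reference "
            "proteome FASTAs (enable 'simulate' or provide inputs)"
        )
    pop = [GeneRecord(gene_id=k, cds=v) for k, v in read_fasta(pop_path).items()]
    endo = [GeneRecord(gene_id=k, cds=v) for k, v in read_fasta(endo_path).items()]
    free_refs = []
    for p in sorted(out.glob("ref_free_living_*.fasta")):
        free_refs.append(
            [GeneRecord(gene_id=k, cds=v) for k, v in read_fasta(p).items()]
        )
    part = partition_gene_sets(
        pop, endo, free_refs,
        min_identity=cfg.min_identity, min_coverage=cfg.min_coverage,
    )
    rows = []
    for g in pop:
        hits = part.best_hits.get(g.gene_id, {})
        rows.append(
            {
                "gene_id": g.gene_id,
                "category": part.assignments[g.gene_id],
                "endo_hit": hits.get("endosymbiont", ""),
                "free_hit": hits.get("free_living", ""),
            }
        )
    paths = []
    p = out / "gene_partition.tsv"
    write_table(
        pd.DataFrame(rows), p, "genesets",
        {"min_identity": cfg.min_identity, "min_coverage": cfg.min_coverage},
    )
    paths.append(p)

    counts = part.counts
    total_assigned = sum(v for k, v in counts.items() if k != "unassigned")
    count_rows = [
        {
            "category": k,
            "n_genes": v,
            "fraction_of_assigned": (
                round(v / total_assigned, 4)
                if total_assigned and k != "unassigned"
                else ""
            ),
        }
        for k, v in counts.items()
    ]
    p = out / "gene_partition_counts.tsv"
    write_table(pd.DataFrame(count_rows), p, "genesets", {})
    paths.append(p)

    markers_path = out / "markers.fasta"
    fam_path = out / "marker_families.tsv"
    if markers_path.exists() and fam_path.exists():
        seqs = read_fasta(markers_path)
        fams = read_table(fam_path)
        families: dict[str, list[GeneRecord]] = {}
        for gid, fam in fams[["gene_id", "family"]].itertuples(index=False, name=None):
            families.setdefault(fam, []).append(GeneRecord(gene_id=gid, cds=seqs[gid]))
        estimate, per_family = estimate_species_count(
            families, threshold=cfg.marker_identity
        )
        rows = [{"family": f, "n_clusters": c} for f, c in sorted(per_family.items())]
        rows.append({"family": "median_estimate", "n_clusters": estimate})
        p = out / "species_counts.tsv"
        write_table(
            pd.DataFrame(rows), p, "genesets", {"identity": cfg.marker_identity}
        )
        paths.append(p)
    return paths


def stage_evolution(out: Path, cfg: PipelineConfig) -> list[Path]:
    pairs_path = out / "ortholog_pairs.fasta"
    if not pairs_path.exists():
        raise FileNotFoundError(
            "stage 'evolution' needs ortholog_pairs.fasta "
            "(enable 'simulate' or provide input)"
        )
    seqs = read_fasta(pairs_path)
    pair_ids = sorted({k[:-2] for k in seqs if k.endswith("_a")})
    sel_rows = []
    cub_rows = []
    for pid in pair_ids:
        cds_a, cds_b = seqs[f"{pid}_a"], seqs[f"{pid}_b"]
        if min(len(cds_a), len(cds_b)) <= cfg.min_pair_bp:
            continue
        res = selection.dnds_from_cds(cds_a, cds_b, pair_id=pid)
        sel_rows.append(
            {
                "pair_id": pid,
                "S": round(res.S, 4),
                "N": round(res.N, 4),
                "Sd": round(res.Sd, 4),
                "Nd": round(res.Nd, 4),
                "pS": round(res.pS, 6),
                "pN": round(res.pN, 6),
                "dS": round(res.dS, 6),
                "dN": round(res.dN, 6),
                "omega": round(res.omega, 6) if res.omega_defined else "",
                "flags": ";".join(res.flags),
                "selection_class": selection.classify_selection(res),
            }
        )
        ca, cb = cdc(cds_a), cdc(cds_b)
        cub_rows.append(
            {
                "pair_id": pid,
                "cdc_a": round(ca.cdc, 6),
                "cdc_b": round(cb.cdc, 6),
                "pair_mean_cdc": round(pair_mean_cdc(cds_a, cds_b), 6),
            }
        )
    paths = []
    p = out / "selection.tsv"
    write_table(
        pd.DataFrame(sel_rows), p, "evolution",
        {"estimator": "NG86+JC69", "aligner": "BLOSUM62/-11/-1",
         "min_pair_bp": cfg.min_pair_bp},
    )
    paths.append(p)
    p = out / "codon_bias.tsv"
    write_table(pd.DataFrame(cub_rows), p, "evolution", {"measure": "CDC"})
    paths.append(p)
    return paths


def stage_popgen(out: Path, cfg: PipelineConfig) -> list[Path]:
    snp_path = out / "snps.tsv"
    sites_path = out / "sites.tsv"
    if not snp_path.exists() or not sites_path.exists():
        raise FileNotFoundError(
            "stage 'popgen' needs snps.tsv and sites.tsv "
            "(enable 'simulate' or provide inputs)"
        )
    snp_df = read_table(snp_path)
    pops = sorted(snp_df["population"].unique())
    loci = list(dict.fromkeys(snp_df["locus"]))
    counts = np.zeros((len(loci), len(pops), 2))
    li = {l: i for i, l in enumerate(loci)}
    pi = {p: i for i, p in enumerate(pops)}
    for row in snp_df.itertuples(index=False):
        counts[li[row.locus], pi[row.population]] = (
            row.allele1_count,
            row.allele2_count,
        )
    snps = popgen.SnpMatrix(counts=counts, populations=pops, loci=loci)
    fst = popgen.fst_matrix(snps)

    sites = read_table(sites_path).set_index("site_id")
    sites = sites.loc[[p for p in pops if p in sites.index]]
    geo = popgen.geographic_distance_matrix(sites)

    paths = []

    def write_matrix(dm: popgen.DistanceMatrix, name: str, stage: str) -> None:
        df = pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels)
        p = out / name
        write_table(df.reset_index(names="site_id"), p, stage, {})
        paths.append(p)

    write_matrix(fst, "fst_matrix.tsv", "popgen")
    write_matrix(geo, "geo_distance_km.tsv", "popgen")

    abund_path = out / "abundances.tsv"
    decay_rows = []
    if abund_path.exists():
        abund = read_table(abund_path).set_index("site_id").loc[geo.labels]
        bc = popgen.bray_curtis_matrix(abund)
        write_matrix(bc, "bray_curtis.tsv", "popgen")
        div_rows = []
        for site in abund.index:
            h, j = popgen.diversity(abund.loc[site].to_numpy())
            div_rows.append(
                {"site_id": site, "shannon_h": round(h, 5),
                 "pielou_j": round(j, 5) if not np.isnan(j) else ""}
            )
        p = out / "diversity.tsv"
        write_table(pd.DataFrame(div_rows), p, "popgen", {"log_base": "e"})
        paths.append(p)
        targets = [("bray_curtis", bc)]
    else:
        targets = []
    if fst.labels == geo.labels:
        targets.append(("fst", fst))
    for name, dm in targets:
        dd = popgen.distance_decay(geo, dm, n_perm=cfg.n_perm, seed=cfg.seed)
        decay_rows.append(
            {
                "community_matrix": name,
                "slope_per_km": round(dd.slope, 8),
                "intercept": round(dd.intercept, 6),
                "r2": round(dd.r2, 6),
                "mantel_r": round(dd.mantel.r, 6),
                "mantel_p": round(dd.mantel.p, 6),
                "n_perm": dd.mantel.n_perm,
            }
        )
    p = out / "distance_decay.tsv"
    write_table(pd.DataFrame(decay_rows), p, "popgen", {"n_perm": cfg.n_perm})
    paths.append(p)
    return paths


def stage_coupling(out: Path, cfg: PipelineConfig) -> list[Path]:
    sel_path = out / "selection.tsv"
    cub_path = out / "codon_bias.tsv"
    truth_path = out / "ortholog_truth.tsv"
    if not sel_path.exists() or not cub_path.exists():
        raise FileNotFoundError(
            "stage 'coupling' needs selection.tsv and codon_bias.tsv "
            "(enable 'evolution' first)"
        )
    sel_df = read_table(sel_path)
    cub_df = read_table(cub_path)
    categories: dict[str, str] = {}
    if truth_path.exists():
        tr = read_table(truth_path)
        categories = dict(tr[["pair_id", "category"]].itertuples(index=False, name=None))
    else:
        categories = {pid: "core" for pid in sel_df["pair_id"]}

    sel_results = [
        selection.SelectionResult(
            S=r.S, N=r.N, Sd=r.Sd, Nd=r.Nd, pS=r.pS, pN=r.pN,
            dS=r.dS, dN=r.dN,
            omega=float(r.omega) if str(r.omega) not in ("", "nan") else float("nan"),
            n_codons=0, pair_id=r.pair_id,
        )
        for r in sel_df.itertuples(index=False)
    ]
    bias_results = [
        CodonBiasResult(
            gene_id=r.pair_id, cdc=r.pair_mean_cdc, n_codons=0,
            pair_mean_cdc=r.pair_mean_cdc,
        )
        for r in cub_df.itertuples(index=False)
    ]
    results = coupling.coupling_analysis(
        sel_results, bias_results, categories, method=cfg.coupling_method
    )
    paths = []
    p = out / "coupling.tsv"
    write_table(
        coupling.coupling_results_frame(results), p, "coupling",
        {"method": cfg.coupling_method},
    )
    paths.append(p)

    summaries = coupling.summarize_selection(sel_results, categories)
    p = out / "selection_summary.tsv"
    write_table(
        pd.DataFrame(
            [
                {
                    "group": s.group,
                    "median_omega": round(s.median_omega, 6)
                    if not np.isnan(s.median_omega) else "",
                    "n_fast": s.n_fast,
                    "n_total": s.n_total,
                    "n_undefined": s.n_undefined,
                }
                for s in summaries
            ]
        ),
        p, "coupling", {},
    )
    paths.append(p)

    scatter = coupling.coupling_table(sel_results, bias_results, categories)
    p = out / "coupling_scatter.tsv"
    write_table(scatter, p, "coupling", {})
    paths.append(p)

    if cfg.make_plots and len(scatter):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for cat, sub in scatter.groupby("category"):
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.scatter(sub["pair_mean_cdc"], sub["omega"], s=12, alpha=0.7)
            ax.set_xlabel("pair-mean CDC")
            ax.set_ylabel("dN/dS")
            ax.set_title(str(cat))
            fig.tight_layout()
            fig.savefig(out / f"coupling_{cat}.png", dpi=120)
            plt.close(fig)
    return paths


_STAGE_FUNCS: dict[str, Callable[[Path, PipelineConfig], list[Path]]] = {
    "simulate": stage_simulate,
    "bin": stage_bin,
    "genesets": stage_genesets,
    "evolution": stage_evolution,
    "popgen": stage_popgen,
    "coupling": stage_coupling,
}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in dependency order and write a manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_records = []
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](out, config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        stage_records.append(
            {
                "stage": stage,
                "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
                "wall_seconds": round(time.perf_counter() - t0, 3),
            }
        )
    manifest = RunManifest(
        config=config.to_dict(), stages=stage_records, version=__version__
    )
    manifest.to_json(out / "manifest.json")
    return manifest
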