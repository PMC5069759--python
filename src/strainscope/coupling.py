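"""Coupling between natural selection (dN/dS) and codon usage bias.

The central statistic: per lifestyle category (core, free-living,
endosymbiont), the rank correlation between each ortholog pair's ω = dN/dS
and its pair-mean codon deviation coefficient.  Under strong in-situ
functional constraints, highly codon-optimised genes are expected to sit
under stronger purifying selection, producing a negative correlation.

Spearman is the default (ω distributions are heavy-tailed); Pearson is
available by flag.  Pairs with undefined ω (dS = 0 or saturation) are
excluded.  Raw and Bonferroni-adjusted p-values are both reported because
three categories are tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .codonbias import CodonBiasResult
from .selection import SelectionResult


@dataclass
class CouplingResult:
    category: str
    n_pairs: int
    rho: float  # NaN when undefined (< 3 pairs or constant input)
    p: float
    p_adjusted: float
    method: str

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


@dataclass
class SelectionSummary:
    group: str
    median_omega: float  # NaN when no defined omegas
    n_fast: int  # pairs with omega > 1
    n_total: int
    n_undefined: int


def coupling_table(
    selection: list[SelectionResult],
    bias: list[CodonBiasResult],
    categories: dict[str, str],
) -> pd.DataFrame:
    """Join selection and codon-bias results on pair id.

    `bias` entries carry pair_mean_cdc in `pair_mean_cdc` (preferred) or
    `cdc`; `categories` maps pair id to lifestyle category.  Pairs with
    undefined omega are dropped.
    """
    sel = pd.DataFrame(
        {
            "pair_id": [s.pair_id for s in selection],
            "omega": [s.omega for s in selection],
        }
    )
    cub = pd.DataFrame(
        {
            "pair_id": [b.gene_id for b in bias],
            "pair_mean_cdc": [
                b.pair_mean_cdc if b.pair_mean_cdc is not None else b.cdc
                for b in bias
            ],
        }
    )
    df = sel.merge(cub, on="pair_id", how="inner")
    df["category"] = df["pair_id"].map(categories)
    df = df.dropna(subset=["category"])
    return df[~df["omega"].isna()].reset_index(drop=True)


def coupling_analysis(
    selection: list[SelectionResult],
    bias: list[CodonBiasResult],
    categories: dict[str, str],
    method: str = "spearman",
) -> list[CouplingResult]:
    """Per-category correlation between ω and pair-mean CDC.

    Categories with < 3 usable pairs, or a constant variable, yield an
    undefined (NaN) correlation rather than an exception.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    df = coupling_table(selection, bias, categories)
    cats = sorted(set(categories.values()))
    n_tests = max(1, len(cats))
    out = []
    for cat in cats:
        sub = df[df["category"] == cat]
        n = len(sub)
        if n < 3 or sub["omega"].nunique() < 2 or sub["pair_mean_cdc"].nunique() < 2:
            out.append(
                CouplingResult(cat, n, math.nan, math.nan, math.nan, method)
            )
            continue
        if method == "spearman":
            rho, p = spearmanr(sub["pair_mean_cdc"], sub["omega"])
        else:
            rho, p = pearsonr(sub["pair_mean_cdc"], sub["omega"])
        out.append(
            CouplingResult(
                category=cat,
                n_pairs=n,
                rho=float(rho),
                p=float(p),
                p_adjusted=float(min(1.0, p * n_tests)),
                method=method,
            )
        )
    return out


def summarize_selection(
    selection: list[SelectionResult],
    group_key: dict[str, str] | None = None,
) -> list[SelectionSummary]:
    """Median ω, fast-evolving (ω > 1) counts, and undefined counts per group.

    `group_key` maps pair id to a grouping label (site or category); when
    omitted, a single overall summary is returned.
    """
    if not selection:
        raise ValueError("no selection results to summarise")
    groups: dict[str, list[SelectionResult]] = {}
    for s in selection:
        g = group_key.get(s.pair_id, "ungrouped") if group_key else "all"
        groups.setdefault(g, []).append(s)
    out = []
    for g in sorted(groups):
        members = groups[g]
        defined = [s.omega for s in members if s.omega_defined]
        out.append(
            SelectionSummary(
                group=g,
                median_omega=float(np.median(defined)) if defined else math.nan,
                n_fast=sum(1 for w in defined if w > 1.0),
                n_total=len(members),
                n_undefined=len(members) - len(defined),
            )
        )
    return out


def coupling_results_frame(results: list[CouplingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [r.category for r in results],
            "n_pairs": [r.n_pairs for r in results],
            "rho": [r.rho for r in results],
            "p": [r.p for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "method": [r.method for r in results],
        }
    )
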