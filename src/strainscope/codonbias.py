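"""Codon deviation coefficient (CDC): codon usage bias against a null
expectation built from positional GC and purine content.

The null model factorises nucleotide probabilities independently per codon
position from the gene's own composition: with gc_p and pur_p the GC and
purine (A+G) fractions at codon position p,

    P(G)_p = gc_p·pur_p        P(A)_p = (1-gc_p)·pur_p
    P(C)_p = gc_p·(1-pur_p)    P(T)_p = (1-gc_p)·(1-pur_p)

and the expected probability of a codon is the product over its three
positions, with stop codons removed and the 61-vector renormalised.  CDC is
the cosine distance between the observed and expected sense-codon usage, so
a gene whose usage matches its compositional expectation scores 0 and a
maximally deviant gene approaches 1.  Significance comes from a parametric
bootstrap that resamples same-length genes codon-by-codon from the expected
usage and scores them against the same expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genetics import SENSE_CODONS, codons_of, is_stop

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# per sense codon, the nucleotide index at each of the three positions
_CODON_NT = np.array(
    [[_NT_INDEX[c[p]] for p in range(3)] for c in SENSE_CODONS], dtype=np.intp
)

MIN_CONFIDENT_CODONS = 30


@dataclass
class PositionalComposition:
    """GC and purine fractions at codon positions 1..3."""

    gc: tuple[float, float, float]
    purine: tuple[float, float, float]

    def __post_init__(self) -> None:
        for v in (*self.gc, *self.purine):
            if not 0.0 <= v <= 1.0:
                raise ValueError("composition fractions must lie in [0, 1]")


@dataclass
class CodonBiasResult:
    gene_id: str | None
    cdc: float
    n_codons: int
    p_value: float | None = None
    pair_mean_cdc: float | None = None
    flags: tuple[str, ...] = ()


def _sense_codons(cds: str) -> list[str]:
    cods = codons_of(cds.upper())
    if cods and is_stop(cods[-1]):
        cods = cods[:-1]
    if any(is_stop(c) for c in cods):
        raise ValueError("internal stop codon in CDS")
    if not cods:
        raise ValueError("CDS contains no sense codons")
    return cods


def positional_composition(cds: str) -> PositionalComposition:
    """Per-codon-position GC and purine fractions of an in-frame CDS."""
    cods = _sense_codons(cds)
    gc = []
    pur = []
    for p in range(3):
        col = [c[p] for c in cods]
        n = len(col)
        gc.append(sum(1 for x in col if x in "GC") / n)
        pur.append(sum(1 for x in col if x in "AG") / n)
    return PositionalComposition(gc=tuple(gc), purine=tuple(pur))


def expected_codon_usage(comp: PositionalComposition) -> np.ndarray:
    """Expected sense-codon probabilities (61-vector, lexicographic order).

    Independence factorisation of positional GC × purine content; stop-codon
    mass is removed and the vector renormalised.  Raises ValueError when the
    composition puts zero mass on every sense codon.
    """
    # per position, probabilities over A,C,G,T
    pos_probs = np.empty((3, 4))
    for p in range(3):
        gc, pur = comp.gc[p], comp.purine[p]
        pos_probs[p] = [
            (1.0 - gc) * pur,        # A
            gc * (1.0 - pur),        # C
            gc * pur,                # G
            (1.0 - gc) * (1.0 - pur),  # T
        ]
    probs = (
        pos_probs[0, _CODON_NT[:, 0]]
        * pos_probs[1, _CODON_NT[:, 1]]
        * pos_probs[2, _CODON_NT[:, 2]]
    )
    total = probs.sum()
    if total <= 0.0:
        raise ValueError("composition assigns zero mass to all sense codons")
    return probs / total


def observed_codon_usage(cds: str) -> np.ndarray:
    """Observed sense-codon frequency vector (sums to 1)."""
    counts = _codon_counts(cds)
    return counts / counts.sum()


def _codon_counts(cds: str) -> np.ndarray:
    counts = np.zeros(len(SENSE_CODONS))
    for c in _sense_codons(cds):
        counts[_CODON_INDEX[c]] += 1
    return counts


def _cosine_distance(obs: np.ndarray, exp: np.ndarray) -> float:
    num = float(obs @ exp)
    den = float(np.linalg.norm(obs) * np.linalg.norm(exp))
    if den == 0.0:
        raise ValueError("zero-norm usage vector")
    # clip fp noise so identical vectors give exactly 0
    return min(1.0, max(0.0, 1.0 - num / den))


def cdc(cds: str, gene_id: str | None = None) -> CodonBiasResult:
    """Codon deviation coefficient of one CDS.

    cdc = 1 − cosine similarity between observed and expected usage; 0 when
    the gene matches its compositional expectation, bounded above by 1.
    Genes shorter than 30 codons are computed but flagged low-confidence.
    """
    cods = _sense_codons(cds)
    obs = observed_codon_usage(cds)
    exp = expected_codon_usage(positional_composition(cds))
    value = _cosine_distance(obs, exp)
    if math.isclose(value, 0.0, abs_tol=1e-12):
        value = 0.0
    flags = ("low_confidence",) if len(cods) < MIN_CONFIDENT_CODONS else ()
    return CodonBiasResult(gene_id=gene_id, cdc=value, n_codons=len(cods), flags=flags)


def cdc_significance(
    cds: str, n_boot: int = 999, seed: int = 0, expected: np.ndarray | None = None
) -> float:
    """Add-one bootstrap p-value for the CDC of one gene.

    Null genes of the same codon length are resampled from the expected
    usage and scored against that same expectation;
    p = (1 + #{CDC* ≥ CDC_obs}) / (1 + n_boot).  `expected` overrides the
    gene's own compositional expectation (e.g. a genome-wide null).
    """
    if n_boot < 99:
        raise ValueError("n_boot must be at least 99")
    cods = _sense_codons(cds)
    n = len(cods)
    exp = (
        np.asarray(expected, dtype=float)
        if expected is not None
        else expected_codon_usage(positional_composition(cds))
    )
    obs_cdc = _cosine_distance(observed_codon_usage(cds), exp)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        counts = rng.multinomial(n, exp).astype(float)
        boot = _cosine_distance(counts / n, exp)
        if boot >= obs_cdc:
            exceed += 1
    return (1 + exceed) / (1 + n_boot)


def pair_mean_cdc(cds_a: str, cds_b: str) -> float:
    """Arithmetic mean CDC of two orthologous genes (the coupling x-axis)."""
    return 0.5 * (cdc(cds_a).cdc + cdc(cds_b).cdc)
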