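"""Pairwise dN/dS estimation for orthologous coding genes.

The estimator is Nei–Gojobori (1986) counting with Jukes–Cantor correction:
synonymous and nonsynonymous *sites* are counted per codon from the fraction
of single-nucleotide neighbours that preserve the encoded amino acid, and
observed *differences* between a codon pair are classified by averaging over
every ordering of the single-step mutational pathways connecting the two
codons.  Mutational paths passing through a stop codon are excluded and the
average is renormalised over the remaining paths; mutations *to* stop codons
are excluded from both the numerator and the denominator of the site counts.

Proteins are aligned globally (BLOSUM62, gap open -11, extend -1) and the
codon alignment is obtained by threading each CDS back through its aligned
protein, so the per-column codon correspondence is exact.  ω = dN/dS is
reported as undefined (NaN) when dS = 0, which keeps infinite ratios out of
medians and correlations downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

from Bio.Align import PairwiseAligner, substitution_matrices

from .genetics import CODON_TO_AA, NUCLEOTIDES, codons_of, is_stop, translate

GAP_CODON = "---"

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# protein alignment


@dataclass
class ProteinAlignment:
    """A global pairwise protein alignment (equal-length gapped strings)."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    @property
    def identity(self) -> float:
        """Matches over all alignment columns (gap columns count as mismatch)."""
        n = len(self.aligned_a)
        if n == 0:
            return 0.0
        matches = sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )
        return matches / n


def _make_aligner() -> PairwiseAligner:
    matrix = substitution_matrices.load("BLOSUM62")
    matrix = matrix.copy()
    # non-standard residues are mapped to X and scored 0 against anything
    xi = matrix.alphabet.index("X")
    matrix[xi, :] = 0.0
    matrix[:, xi] = 0.0
    aligner = PairwiseAligner(mode="global")
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def _sanitize_protein(seq: str) -> str:
    seq = seq.upper()
    return "".join(c if c in _STANDARD_AA else "X" for c in seq)


def align_proteins_global(a: str, b: str) -> ProteinAlignment:
    """Needleman–Wunsch global alignment of two protein sequences.

    BLOSUM62 substitution scores, gap open -11 (first gap position), gap
    extend -1.  Non-standard residues are mapped to X and scored 0 against
    everything.  The aligner's first optimal alignment is returned, which is
    deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValueError("cannot align empty protein sequences")
    aln = _ALIGNER.align(_sanitize_protein(a), _sanitize_protein(b))[0]
    return ProteinAlignment(aligned_a=aln[0], aligned_b=aln[1], score=aln.score)


def alignment_score(a: str, b: str) -> float:
    """Score of the global protein alignment of `a` and `b` (no traceback)."""
    if not a or not b:
        raise ValueError("cannot align empty protein sequences")
    return _ALIGNER.score(_sanitize_protein(a), _sanitize_protein(b))


# ---------------------------------------------------------------------------
# codon alignment


@dataclass
class CodonAlignment:
    """Aligned codon columns; gap columns carry the gap triplet '---'."""

    codons_a: list[str]
    codons_b: list[str]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon columns must align one-to-one")

    def comparable_columns(self) -> list[tuple[str, str]]:
        """Columns where both sides carry a sense codon (no gaps, no stops)."""
        return [
            (ca, cb)
            for ca, cb in zip(self.codons_a, self.codons_b)
            if ca != GAP_CODON
            and cb != GAP_CODON
            and not is_stop(ca)
            and not is_stop(cb)
        ]


def _strip_terminal_stop(cds: str, protein: str) -> tuple[str, str]:
    if protein.endswith("*"):
        protein = protein[:-1]
        cds = cds[:-3]
    return cds, protein


def backthread_codons(aln: ProteinAlignment, cds_a: str, cds_b: str) -> CodonAlignment:
    """Thread two CDSs through their protein alignment, column by column.

    Each amino-acid column maps to its source codon; protein gaps become gap
    triplets.  Terminal stop codons are dropped.  Raises ValueError when a
    CDS does not translate to its aligned protein.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    prot_a = aln.aligned_a.replace("-", "")
    prot_b = aln.aligned_b.replace("-", "")
    tr_a = translate(cds_a)
    tr_b = translate(cds_b)
    cds_a, tr_a = _strip_terminal_stop(cds_a, tr_a)
    cds_b, tr_b = _strip_terminal_stop(cds_b, tr_b)
    if _sanitize_protein(tr_a) != _sanitize_protein(prot_a):
        raise ValueError("cds_a does not translate to the aligned protein a")
    if _sanitize_protein(tr_b) != _sanitize_protein(prot_b):
        raise ValueError("cds_b does not translate to the aligned protein b")
    cods_a = codons_of(cds_a)
    cods_b = codons_of(cds_b)
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for col_a, col_b in zip(aln.aligned_a, aln.aligned_b):
        if col_a == "-":
            out_a.append(GAP_CODON)
        else:
            out_a.append(cods_a[ia])
            ia += 1
        if col_b == "-":
            out_b.append(GAP_CODON)
        else:
            out_b.append(cods_b[ib])
            ib += 1
    return CodonAlignment(codons_a=out_a, codons_b=out_b)


def codon_alignment_from_cds(cds_a: str, cds_b: str) -> CodonAlignment:
    """Align two CDSs at the protein level and back-thread the codons."""
    prot_a = translate(cds_a.upper()).rstrip("*")
    prot_b = translate(cds_b.upper()).rstrip("*")
    aln = align_proteins_global(prot_a, prot_b)
    return backthread_codons(aln, cds_a, cds_b)


# ---------------------------------------------------------------------------
# NG86 counting


@lru_cache(maxsize=None)
def count_sites_ng86(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    At each of the 3 positions the site is split between the synonymous and
    nonsynonymous fractions of its single-nucleotide neighbours; mutations to
    stop codons are removed from both the numerator and the denominator, so
    s + n = 3 for every sense codon.
    """
    codon = codon.upper()
    if is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no NG86 site counts")
    if codon not in CODON_TO_AA:
        raise ValueError(f"invalid codon {codon!r}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            neighbour = codon[:pos] + nt + codon[pos + 1 :]
            if is_stop(neighbour):
                continue
            valid += 1
            if CODON_TO_AA[neighbour] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def count_differences_ng86(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Observed synonymous/nonsynonymous differences between two sense codons.

    With k differing positions, every one of the k! orderings of single-step
    changes is enumerated; orderings whose intermediate codons include a stop
    are discarded and the per-step classification is averaged uniformly over
    the remaining orderings.  If every ordering crosses a stop codon, all k
    differences are counted as nonsynonymous.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c not in CODON_TO_AA:
            raise ValueError(f"invalid codon {c!r}")
        if is_stop(c):
            raise ValueError(f"stop codon {c!r} not allowed in NG86 differences")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    totals_sd = 0.0
    totals_nd = 0.0
    n_valid = 0
    for order in permutations(diff_pos):
        current = codon_a
        sd = nd = 0.0
        valid = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if is_stop(nxt):
                valid = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if valid:
            totals_sd += sd
            totals_nd += nd
            n_valid += 1
    if n_valid == 0:
        return 0.0, float(k)
    return totals_sd / n_valid, totals_nd / n_valid


# ---------------------------------------------------------------------------
# dN/dS


@dataclass
class SelectionResult:
    """NG86 counts, Jukes–Cantor distances, and ω for one codon alignment."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float  # NaN when undefined (dS == 0 or saturation)
    n_codons: int
    flags: list[str] = field(default_factory=list)
    pair_id: str | None = None

    @property
    def omega_defined(self) -> bool:
        return not math.isnan(self.omega)


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4)·ln(1 - 4p/3); NaN at saturation (p ≥ 3/4)."""
    if p < 0:
        raise ValueError("proportion of differences cannot be negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def dnds(caln: CodonAlignment, pair_id: str | None = None) -> SelectionResult:
    """NG86 dN/dS over the comparable (gap-free, stop-free) codon columns."""
    columns = caln.comparable_columns()
    if not columns:
        raise ValueError("codon alignment has no comparable columns")
    S = N = Sd = Nd = 0.0
    for ca, cb in columns:
        sa, na = count_sites_ng86(ca)
        sb, nb = count_sites_ng86(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = count_differences_ng86(ca, cb)
        Sd += sd
        Nd += nd
    flags: list[str] = []
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    if math.isnan(dS) or math.isnan(dN):
        flags.append("saturated")
        omega = math.nan
    elif dS == 0.0:
        flags.append("dS_zero")
        omega = math.nan
    else:
        omega = dN / dS
    if len(columns) < 100:
        flags.append("short_alignment")
    return SelectionResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN,
        omega=omega, n_codons=len(columns), flags=flags, pair_id=pair_id,
    )


def dnds_from_cds(cds_a: str, cds_b: str, pair_id: str | None = None) -> SelectionResult:
    """Convenience wrapper: protein-align, back-thread, and run NG86."""
    return dnds(codon_alignment_from_cds(cds_a, cds_b), pair_id=pair_id)


PURIFYING = "purifying"
POSITIVE = "positive"
NEUTRAL_OR_UNDETERMINED = "neutral_or_undetermined"


def classify_selection(result: SelectionResult) -> str:
    """ω < 1 → purifying, ω > 1 → positive, undefined or = 1 → neutral."""
    if not result.omega_defined or result.omega == 1.0:
        return NEUTRAL_OR_UNDETERMINED
    return PURIFYING if result.omega < 1.0 else POSITIVE
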