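"""Standard genetic code (NCBI translation table 1) and codon utilities.

The code table is taken from Biopython so the package never hand-maintains
the 64-codon map; everything downstream (NG86 counting, CDC expectations,
the ortholog simulator) reads from these constants.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDES = "ACGT"

_table = unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for the three stop codons
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
CODON_TO_AA.update({c: "*" for c in _table.stop_codons})

#: the 61 sense codons in lexicographic order (canonical vector axis)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
)

STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)

#: amino acid -> tuple of synonymous sense codons (lexicographic)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_c], tuple())
    AA_TO_CODONS[CODON_TO_AA[_c]] += (_c,)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate(cds: str) -> str:
    """Translate an in-frame CDS; stop codons render as '*'.

    Raises ValueError on frame violations or non-ACGT characters.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        try:
            aas.append(CODON_TO_AA[codon])
        except KeyError:
            raise ValueError(f"invalid codon {codon!r} at position {i}") from None
    return "".join(aas)


def codons_of(cds: str) -> list[str]:
    """Split an in-frame CDS into its codons."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def has_internal_stop(cds: str) -> bool:
    """True if any codon before the last is a stop codon."""
    cods = codons_of(cds.upper())
    return any(is_stop(c) for c in cods[:-1])
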