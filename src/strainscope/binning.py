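"""Composition-based genotype binning of metagenome contigs.

Contigs are summarised by their strand-symmetric tetranucleotide frequency
(TNF) profile — every overlapping 4-mer counted on the sequence and its
reverse complement, normalised to sum 1 — and clustered by average-linkage
hierarchical agglomeration on the distance d = 1 − R², where R is the
Pearson correlation between two 256-component profiles.  The dendrogram is
cut at d = 1 − r²_cutoff (default R² = 0.9).  Bins are then refined by a
single-pass chimera filter that removes members whose GC content deviates
from the bin mean by more than one sample standard deviation.

GC is computed on A/C/G/T only (ambiguous N bases are excluded from both
numerator and denominator) and 4-mer windows containing N are skipped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
TETRAMERS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=4)
)
_TETRAMER_INDEX = {t: i for i, t in enumerate(TETRAMERS)}


@dataclass
class Contig:
    contig_id: str
    sequence: str
    truth_label: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)


@dataclass
class TnfProfile:
    contig_id: str
    freqs: np.ndarray  # 256 components, sums to 1
    gc: float


@dataclass
class Bin:
    bin_id: str
    contig_ids: list[str]
    mean_gc: float
    sd_gc: float
    total_bp: int
    n50: int
    flags: tuple[str, ...] = ()


@dataclass
class BinningConfig:
    r2_cutoff: float = 0.9
    min_contig_len: int = 300
    linkage: str = "average"
    gc_sd_multiplier: float = 1.0
    cluster_on_gc: bool = False  # TNF-only clustering by default

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_cutoff <= 1.0:
            raise ValueError("r2_cutoff must lie in (0, 1]")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_content(sequence: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); N bases excluded entirely."""
    if not sequence:
        raise ValueError("empty sequence has no GC content")
    sequence = sequence.upper()
    gc = sum(1 for c in sequence if c in "GC")
    acgt = sum(1 for c in sequence if c in "ACGT")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / acgt


def _count_tetramers(sequence: str, counts: np.ndarray) -> int:
    n_valid = 0
    for i in range(len(sequence) - 3):
        word = sequence[i : i + 4]
        idx = _TETRAMER_INDEX.get(word)
        if idx is not None:  # windows containing N are skipped
            counts[idx] += 1
            n_valid += 1
    return n_valid


def tnf_profile(contig: Contig) -> TnfProfile:
    """Strand-symmetric tetranucleotide frequency profile of one contig.

    All 256 words are counted with step 1 on the sequence and on its reverse
    complement, then normalised to sum 1, so profile(s) == profile(revcomp(s)).
    """
    seq = contig.sequence
    counts = np.zeros(256)
    n = _count_tetramers(seq, counts)
    n += _count_tetramers(reverse_complement(seq), counts)
    if n == 0:
        raise ValueError(f"contig {contig.contig_id} has no valid 4-mer window")
    return TnfProfile(contig_id=contig.contig_id, freqs=counts / n, gc=contig.gc)


def filter_contigs(contigs: list[Contig], min_len: int = 300) -> list[Contig]:
    """Keep contigs with length ≥ min_len (the boundary length is kept)."""
    if min_len < 0:
        raise ValueError("min_len must be non-negative")
    return [c for c in contigs if c.length >= min_len]


def n50(lengths: list[int]) -> int:
    """Smallest length L whose ≥L contigs hold at least half the total bp."""
    if not lengths:
        raise ValueError("N50 of an empty length list is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for x in ordered:
        acc += x
        if acc >= half:
            return x
    return ordered[-1]  # unreachable


def _make_bin(bin_id: str, members: list[TnfProfile], lengths: dict[str, int],
              flags: tuple[str, ...] = ()) -> Bin:
    gcs = np.array([m.gc for m in members])
    member_lengths = [lengths[m.contig_id] for m in members]
    return Bin(
        bin_id=bin_id,
        contig_ids=[m.contig_id for m in members],
        mean_gc=float(gcs.mean()),
        sd_gc=float(gcs.std(ddof=1)) if len(gcs) > 1 else 0.0,
        total_bp=int(sum(member_lengths)),
        n50=n50(member_lengths),
        flags=flags,
    )


def cluster_contigs(
    profiles: list[TnfProfile],
    config: BinningConfig | None = None,
    contig_lengths: dict[str, int] | None = None,
) -> list[Bin]:
    """Average-linkage clustering of TNF profiles at d = 1 − R².

    R² is the squared Pearson correlation between two 256-vectors; the
    dendrogram is cut at 1 − r2_cutoff so contigs merge while R² ≥ cutoff.
    Zero-variance (constant) profiles have no defined correlation and are
    placed in flagged singleton bins.  Bin ids are ordered by total bp
    descending so bin_001 is always the largest bin.
    """
    if not profiles:
        raise ValueError("no profiles to cluster")
    config = config or BinningConfig()
    if contig_lengths is None:
        contig_lengths = {p.contig_id: 0 for p in profiles}
        approx = True
    else:
        approx = False

    matrix = np.vstack([p.freqs for p in profiles])
    variances = matrix.var(axis=1)
    degenerate = variances <= 0.0
    usable_idx = np.flatnonzero(~degenerate)

    assignments: dict[int, int] = {}
    next_label = 0
    if usable_idx.size == 1:
        assignments[int(usable_idx[0])] = next_label
        next_label += 1
    elif usable_idx.size > 1:
        sub = matrix[usable_idx]
        r = np.corrcoef(sub)
        d = 1.0 - r * r
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        z = linkage(squareform(d, checks=False), method=config.linkage)
        cut = 1.0 - config.r2_cutoff
        labels = fcluster(z, t=cut, criterion="distance")
        for i, lab in zip(usable_idx, labels):
            assignments[int(i)] = int(lab)
        next_label = int(labels.max()) + 1

    groups: dict[int, list[TnfProfile]] = {}
    flagged: set[int] = set()
    for i, p in enumerate(profiles):
        if degenerate[i]:
            lab = next_label
            next_label += 1
            flagged.add(lab)
        else:
            lab = assignments[i]
        groups.setdefault(lab, []).append(p)

    if approx:
        # fall back to ordering by member count when lengths are unknown
        ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    else:
        ordered = sorted(
            groups.items(),
            key=lambda kv: (-sum(contig_lengths[m.contig_id] for m in kv[1]), kv[0]),
        )
    bins = []
    for rank, (lab, members) in enumerate(ordered, start=1):
        flags = ("degenerate_profile",) if lab in flagged else ()
        lengths = (
            contig_lengths
            if not approx
            else {m.contig_id: 1 for m in members}
        )
        bins.append(_make_bin(f"bin_{rank:03d}", members, lengths, flags))
    return bins


def remove_chimeric(
    bin_: Bin,
    contigs: dict[str, "Contig | float"],
    multiplier: float = 1.0,
) -> tuple[Bin, list[str]]:
    """Single-pass GC chimera filter.

    Members whose GC deviates from the bin mean by strictly more than
    `multiplier` sample standard deviations are removed; the mean and SD are
    computed once on the full membership and not updated during the pass.
    Bins with fewer than 3 members are returned unchanged (SD unstable).
    `contigs` maps contig_id to either a Contig or a bare GC fraction.
    """
    if not bin_.contig_ids:
        raise ValueError("cannot filter an empty bin")
    if len(bin_.contig_ids) < 3:
        return bin_, []

    def _gc(cid: str) -> float:
        v = contigs[cid]
        return v.gc if isinstance(v, Contig) else float(v)

    def _len(cid: str) -> int | None:
        v = contigs[cid]
        return v.length if isinstance(v, Contig) else None

    gcs = np.array([_gc(c) for c in bin_.contig_ids])
    mean = gcs.mean()
    sd = gcs.std(ddof=1)
    removed = [
        cid
        for cid, gc in zip(bin_.contig_ids, gcs)
        if abs(gc - mean) > multiplier * sd
    ]
    kept = [c for c in bin_.contig_ids if c not in set(removed)]
    kept_gc = np.array([_gc(c) for c in kept])
    kept_len = [_len(c) for c in kept]
    have_lengths = all(x is not None for x in kept_len) and kept_len
    refined = Bin(
        bin_id=bin_.bin_id,
        contig_ids=kept,
        mean_gc=float(kept_gc.mean()),
        sd_gc=float(kept_gc.std(ddof=1)) if len(kept_gc) > 1 else 0.0,
        total_bp=int(sum(kept_len)) if have_lengths else bin_.total_bp,
        n50=n50(list(kept_len)) if have_lengths else bin_.n50,
        flags=bin_.flags,
    )
    return refined, removed


def bin_recovery_score(bins: list[Bin], truth_labels: dict[str, str]) -> float:
    """Adjusted Rand Index between the bin partition and the truth labels."""
    pred = []
    true = []
    for i, b in enumerate(bins):
        for cid in b.contig_ids:
            if cid not in truth_labels:
                raise ValueError(f"contig {cid} has no truth label")
            pred.append(i)
            true.append(truth_labels[cid])
    return float(adjusted_rand_score(true, pred))
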