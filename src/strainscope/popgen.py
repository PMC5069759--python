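"""Population differentiation and biogeography statistics.

Pairwise Fst is the classic heterozygosity form used for pooled SNP data:
per biallelic locus, Fst = (Ht − Hw)/Ht, where Hw is the mean within-
population expected heterozygosity 1 − Σp² and Ht is computed on the
unweighted mean allele frequency of the two populations; a locus with
Ht = 0 is uninformative and excluded.  Population-pair Fst is the
unweighted mean over informative loci.

Distance decay couples a geographic great-circle distance matrix
(haversine, Earth radius 6371.0 km) to a community dissimilarity matrix
(Bray–Curtis) through ordinary least squares on the upper-triangle pairs
and a Mantel permutation test (Pearson r on upper triangles, two-sided
add-one permutation p, rows and columns of the second matrix permuted
jointly).  Shannon diversity uses natural logarithms so Pielou's evenness
is J = H / ln S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis
from scipy.stats import linregress, pearsonr

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# containers


@dataclass
class SnpMatrix:
    """Biallelic allele counts: array (n_snps, n_pops, 2) plus labels."""

    counts: np.ndarray
    populations: list[str]
    loci: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != 2:
            raise ValueError("counts must have shape (n_snps, n_pops, 2)")
        if self.counts.shape[1] < 2:
            raise ValueError("need at least 2 populations")
        if (self.counts < 0).any():
            raise ValueError("allele counts must be non-negative")

    def pop_index(self, label: str) -> int:
        return self.populations.index(label)


@dataclass
class DistanceMatrix:
    """Symmetric, hollow, non-negative distance matrix with site labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match the number of labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int


def load_caws_sites() -> pd.DataFrame:
    """Published monitoring-station metadata for the seven Chicago Area
    Waterway System sites (coordinates, physicochemistry, diversity),
    indexed by site id."""
    with resources.files("strainscope.data").joinpath("caws_sites.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return df.set_index("site_id")


# ---------------------------------------------------------------------------
# Fst


def fst_per_snp(counts_a, counts_b) -> float:
    """Per-locus Fst from two populations' biallelic allele counts.

    Returns NaN when the locus is monomorphic across both populations
    (Ht = 0).  Raises on zero total depth in either population.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("each population needs total allele count >= 1")
    p1 = a[0] / a.sum()
    p2 = b[0] / b.sum()
    hw = 0.5 * ((2 * p1 * (1 - p1)) + (2 * p2 * (1 - p2)))
    pbar = 0.5 * (p1 + p2)
    ht = 2 * pbar * (1 - pbar)
    if ht == 0.0:
        return math.nan
    return (ht - hw) / ht


def pairwise_fst(matrix: SnpMatrix, pop_a: str, pop_b: str) -> float:
    """Unweighted mean of per-SNP Fst over loci where it is defined."""
    ia, ib = matrix.pop_index(pop_a), matrix.pop_index(pop_b)
    values = []
    for snp in matrix.counts:
        if snp[ia].sum() <= 0 or snp[ib].sum() <= 0:
            continue
        v = fst_per_snp(snp[ia], snp[ib])
        if not math.isnan(v):
            values.append(v)
    if not values:
        raise ValueError(f"no informative SNPs between {pop_a} and {pop_b}")
    return float(np.mean(values))


def fst_matrix(matrix: SnpMatrix) -> DistanceMatrix:
    """All population pairs; Fst clipped at 0 to keep the matrix a distance."""
    n = len(matrix.populations)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = pairwise_fst(matrix, matrix.populations[i], matrix.populations[j])
            out[i, j] = out[j, i] = max(v, 0.0)
    return DistanceMatrix(labels=list(matrix.populations), values=out)


# ---------------------------------------------------------------------------
# distances and diversity


def haversine_km(a, b) -> float:
    """Great-circle distance in km between two (lat, lon) records.

    Accepts (lat, lon) tuples or mappings/Series with 'latitude'/'longitude'.
    """

    def coords(x):
        if hasattr(x, "__getitem__") and not isinstance(x, (tuple, list)):
            return float(x["latitude"]), float(x["longitude"])
        return float(x[0]), float(x[1])

    lat1, lon1 = coords(a)
    lat2, lon2 = coords(b)
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"invalid coordinates ({lat}, {lon})")
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def geographic_distance_matrix(sites: pd.DataFrame) -> DistanceMatrix:
    """Haversine distances (km) between every pair of site rows."""
    labels = list(sites.index)
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(sites.iloc[i], sites.iloc[j])
            out[i, j] = out[j, i] = d
    return DistanceMatrix(labels=labels, values=out)


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("abundance vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_braycurtis(x, y))


def bray_curtis_matrix(abundances: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray–Curtis over the rows (sites) of an abundance table."""
    labels = list(abundances.index)
    arr = abundances.to_numpy(dtype=float)
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(arr[i], arr[j])
    return DistanceMatrix(labels=labels, values=out)


def diversity(abund) -> tuple[float, float]:
    """Shannon diversity H (natural log) and Pielou evenness J = H / ln S.

    Zero entries are excluded; J is NaN when only one taxon is present.
    """
    a = np.asarray(abund, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("diversity of an all-zero vector is undefined")
    p = a / a.sum()
    h = float(-(p * np.log(p)).sum())
    s = a.size
    j = h / math.log(s) if s > 1 else math.nan
    return h, j


# ---------------------------------------------------------------------------
# Mantel and distance decay


def mantel(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999, seed: int = 0
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r is the Pearson correlation of the upper-triangle entries; the null
    distribution jointly permutes rows and columns of `d2`;
    p = (1 + #{|r*| ≥ |r|}) / (1 + n_perm), two-sided.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels and order")
    n = len(d1.labels)
    if n < 3:
        raise ValueError("Mantel test needs at least 3 sites")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    m2 = d2.values
    r = float(pearsonr(x, m2[iu])[0])
    rng = np.random.default_rng(seed)
    exceed = 0
    # precentre x for a fast correlation in the permutation loop
    xc = x - x.mean()
    xs = math.sqrt(float(xc @ xc))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = m2[np.ix_(perm, perm)][iu]
        yc = yp - yp.mean()
        ys = math.sqrt(float(yc @ yc))
        r_star = float(xc @ yc) / (xs * ys) if xs > 0 and ys > 0 else 0.0
        if abs(r_star) >= abs(r):
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return MantelResult(r=r, p=p, n_perm=n_perm, seed=seed)


@dataclass
class DistanceDecayResult:
    slope: float
    intercept: float
    r2: float
    mantel: MantelResult


def distance_decay(
    geo: DistanceMatrix,
    comm: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> DistanceDecayResult:
    """OLS of community dissimilarity on geographic distance (per-km slope),
    plus the Mantel test between the two matrices."""
    if geo.labels != comm.labels:
        raise ValueError("matrices must share labels and order")
    x = geo.condensed()
    y = comm.condensed()
    if np.allclose(x, x[0]):
        raise ValueError("geographic distances are constant; slope undefined")
    fit = linregress(x, y)
    mr = mantel(geo, comm, n_perm=n_perm, seed=seed)
    return DistanceDecayResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        mantel=mr,
    )
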