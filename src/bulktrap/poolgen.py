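"""Population genomics on per-site base counts.

A pooled bulk sample mixes reads from an unknown number of conspecific
individuals. The per-site alternative-allele frequency spectrum of its
mitochondrial genome carries a signature of that number: k equally weighted
haplotypes put most variant sites near multiples of 1/k, so comparing the
observed spectrum against spectra simulated from known pool sizes gives a
best-fit contributor count. The nuclear stages are windowed heterozygosity
(sites with more than one allele among mapped reads, in 10-kb windows),
mean coverage with a 0.1X inclusion gate, pseudo-haploid allele sampling at
shared variant sites, and a MAF-filtered PCA of the resulting calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

_BASES = np.array(["A", "C", "G", "T"])
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# site counts
# ---------------------------------------------------------------------------


@dataclass
class SiteCounts:
    """Per-site A/C/G/T depths for one reference sequence in one sample."""

    ref_id: str
    pos: np.ndarray  # 1-based positions, int
    counts: np.ndarray  # (n_sites, 4) base counts in A,C,G,T order
    ref_base: np.ndarray  # per-site reference base, '<U1'

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size == 0:
            self.counts = self.counts.reshape(0, 4)
        self.ref_base = np.asarray(self.ref_base, dtype="<U1")
        if self.counts.shape != (self.pos.size, 4):
            raise ValueError("counts must be (n_sites, 4)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.ref_base.size != self.pos.size:
            raise ValueError("one reference base per position required")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(
            {
                "ref_id": self.ref_id,
                "pos": self.pos,
                "count_A": self.counts[:, 0],
                "count_C": self.counts[:, 1],
                "count_G": self.counts[:, 2],
                "count_T": self.counts[:, 3],
                "ref_base": self.ref_base,
            }
        )
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SiteCounts":
        frame = pd.read_csv(path, sep="\t")
        ref_ids = frame["ref_id"].unique()
        if len(ref_ids) != 1:
            raise ValueError("a SiteCounts table holds exactly one reference")
        return cls(
            ref_id=str(ref_ids[0]),
            pos=frame["pos"].to_numpy(),
            counts=frame[["count_A", "count_C", "count_G", "count_T"]].to_numpy(),
            ref_base=frame["ref_base"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# allele-frequency spectra
# ---------------------------------------------------------------------------


@dataclass
class AFSpectrum:
    """Alternative-allele frequencies strictly inside (0, 1), with histogram."""

    frequencies: np.ndarray
    n_bins: int = 20
    bin_edges: np.ndarray = field(init=False)
    histogram: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.size and not (
            (self.frequencies > 0) & (self.frequencies < 1)
        ).all():
            raise ValueError("spectrum frequencies must lie strictly in (0, 1)")
        self.bin_edges = np.linspace(0.0, 1.0, self.n_bins + 1)
        if self.frequencies.size:
            hist, _ = np.histogram(self.frequencies, bins=self.bin_edges)
            self.histogram = hist / hist.sum()
        else:
            self.histogram = np.zeros(self.n_bins)

    @property
    def n_sites(self) -> int:
        return int(self.frequencies.size)

    def is_empty(self) -> bool:
        return self.frequencies.size == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"alt_freq": self.frequencies})


def allele_frequencies(counts: SiteCounts, min_depth: int = 5) -> AFSpectrum:
    """Per-site alternative-allele frequencies from base counts.

    At each site with depth >= ``min_depth`` the alternative allele is the
    most frequent non-reference base and its frequency is alt/depth. Fixed
    sites (frequency 0, or 1 when no reference base remains) are excluded,
    so a single error-free haplotype yields an empty spectrum.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if counts.pos.size == 0:
        warnings.warn("empty site-count input; returning an empty spectrum")
        return AFSpectrum(np.empty(0))
    depth = counts.depth
    keep = depth >= min_depth
    if not keep.any():
        return AFSpectrum(np.empty(0))
    sub = counts.counts[keep]
    depths = depth[keep]
    ref_idx = np.array([_BASE_INDEX[b] for b in counts.ref_base[keep]])
    nonref = sub.copy()
    nonref[np.arange(sub.shape[0]), ref_idx] = -1
    alt = nonref.max(axis=1)
    af = alt / depths
    inside = (af > 0) & (af < 1)
    return AFSpectrum(af[inside])


@dataclass(frozen=True)
class PoolComparison:
    """Distances from an observed spectrum to candidate pool-size spectra."""

    distances: Dict[int, float]
    best_k: int
    tied_ks: Tuple[int, ...]
    margin: float  # gap between the best and second-best distance

    @property
    def is_tie(self) -> bool:
        return len(self.tied_ks) > 1


def compare_pool_spectra(
    observed: AFSpectrum,
    pools: Mapping[int, AFSpectrum],
    metric: str = "l1",
    tie_tol: float = 1e-12,
) -> PoolComparison:
    """Match an observed spectrum against simulated known-size pools.

    The default distance is the L1 difference between normalized 20-bin
    histograms; ``metric="wasserstein"`` uses the 1-Wasserstein distance on
    the raw frequencies. Real spectra rarely match any simulated profile
    exactly, so the best k is returned together with its margin over the
    runner-up, and exact ties are reported rather than silently broken.
    """
    if observed.is_empty():
        raise ValueError("observed spectrum is empty; nothing to compare")
    if len(pools) < 2:
        raise ValueError("need at least two candidate pool sizes")
    for k, spec in pools.items():
        if spec.is_empty():
            raise ValueError(f"candidate spectrum for k={k} is empty")
    distances: Dict[int, float] = {}
    for k, spec in pools.items():
        if metric == "l1":
            distances[k] = float(np.abs(observed.histogram - spec.histogram).sum())
        elif metric == "wasserstein":
            from scipy.stats import wasserstein_distance

            distances[k] = float(
                wasserstein_distance(observed.frequencies, spec.frequencies)
            )
        else:
            raise ValueError(f"unknown metric {metric!r}")
    ordered = sorted(distances.items(), key=lambda kv: (kv[1], kv[0]))
    best_dist = ordered[0][1]
    tied = tuple(k for k, d in ordered if d - best_dist <= tie_tol)
    margin = (ordered[1][1] - best_dist) if len(ordered) > 1 else float("inf")
    return PoolComparison(
        distances=distances, best_k=ordered[0][0], tied_ks=tied, margin=margin
    )


# ---------------------------------------------------------------------------
# heterozygosity and coverage
# ---------------------------------------------------------------------------


def windowed_heterozygosity(
    counts: SiteCounts,
    ref_length: Optional[int] = None,
    window: int = 10_000,
    min_minor: int = 2,
    min_depth: int = 5,
) -> pd.DataFrame:
    """Heterozygous-site counts in fixed windows along the reference.

    Windows tile [1, ref_length] as 1-based inclusive spans ([1, w],
    [w+1, 2w], ...; the last window may be shorter). A site is heterozygous
    when at least two distinct bases each reach ``min_minor`` observations
    and total depth reaches ``min_depth``; ``min_minor=1`` reproduces the
    literal more-than-one-allele rule. The rate denominator is the number
    of covered (depth >= min_depth) sites in the window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    length = ref_length if ref_length is not None else (
        int(counts.pos.max()) if counts.pos.size else 0
    )
    if counts.pos.size and counts.pos.max() > length:
        raise ValueError("positions exceed the stated reference length")
    depth = counts.depth
    covered = depth >= min_depth
    het = covered & ((counts.counts >= min_minor).sum(axis=1) >= 2)
    rows = []
    start = 1
    while start <= length:
        end = min(start + window - 1, length)
        in_win = (counts.pos >= start) & (counts.pos <= end)
        n_cov = int(covered[in_win].sum())
        n_het = int(het[in_win].sum())
        rows.append(
            {
                "ref_id": counts.ref_id,
                "start": start - 1,  # BED-like 0-based start
                "end": end,
                "het_sites": n_het,
                "covered_sites": n_cov,
                "rate": (n_het / n_cov) if n_cov else np.nan,
            }
        )
        start = end + 1
    return pd.DataFrame(
        rows, columns=["ref_id", "start", "end", "het_sites", "covered_sites", "rate"]
    )


def mean_coverage(counts: SiteCounts, ref_length: int) -> float:
    """Mean depth over the whole reference; absent sites count as depth 0."""
    if counts.pos.size and counts.pos.max() > ref_length:
        raise ValueError("positions exceed the stated reference length")
    if ref_length < 1:
        raise ValueError("ref_length must be >= 1")
    return float(counts.depth.sum() / ref_length)


def coverage_gate(coverages: Mapping[str, float], min_cov: float = 0.1) -> List[str]:
    """Samples retained for structure analysis: coverage strictly over the gate."""
    for sid, cov in coverages.items():
        if cov < 0:
            raise ValueError(f"negative coverage for {sid!r}")
    return [sid for sid, cov in coverages.items() if cov > min_cov]


# ---------------------------------------------------------------------------
# pseudo-haploid calls and PCA
# ---------------------------------------------------------------------------

MISSING = -1


@dataclass(frozen=True)
class VariantSite:
    """A shared biallelic site: 1-based position, reference and alternative base."""

    pos: int
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Samples x variant sites of pseudo-haploid calls (0 ref, 1 alt, -1 missing)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if not np.isin(values, [0, 1, MISSING]).all():
            raise ValueError("genotype codes must be 0, 1 or -1 (missing)")

    def site_maf(self) -> pd.Series:
        """Minor-allele frequency per site over non-missing calls."""
        values = self.data.to_numpy().astype(float)
        masked = np.where(values == MISSING, np.nan, values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(masked, axis=0)
        return pd.Series(np.minimum(freq, 1 - freq), index=self.data.columns)


def pseudo_haploid_calls(
    counts: SiteCounts,
    sites: Sequence[VariantSite],
    seed: int = 0,
) -> np.ndarray:
    """Sample one allele per covered site, in proportion to its base counts.

    Low-coverage samples cannot be genotyped diploid; drawing a single
    observed base per site gives an unbiased haploid representation. The
    draw is coded 0 when it equals the site's reference base, 1 for the
    alternative, and missing when the site is uncovered or the drawn base
    is neither allele.
    """
    rng = np.random.default_rng(seed)
    by_pos = {int(p): i for i, p in enumerate(counts.pos)}
    calls = np.full(len(sites), MISSING, dtype=np.int8)
    for j, site in enumerate(sites):
        i = by_pos.get(site.pos)
        if i is None:
            continue
        row = counts.counts[i]
        total = row.sum()
        if total == 0:
            continue
        base = _BASES[rng.choice(4, p=row / total)]
        if base == site.ref:
            calls[j] = 0
        elif base == site.alt:
            calls[j] = 1
    return calls


def shared_variant_sites(
    counts_by_sample: Mapping[str, SiteCounts],
    min_depth: int = 2,
    min_minor: int = 1,
) -> List[VariantSite]:
    """Biallelic candidate sites visible across a set of samples.

    Pools the per-sample counts; a position is kept when, besides the
    recorded reference base, its most common non-reference base reaches
    ``min_minor`` observations at pooled depth >= ``min_depth``. Ref is the
    site's reference base, alt the pooled most-common non-reference base.
    """
    pooled: Dict[int, np.ndarray] = {}
    ref_of: Dict[int, str] = {}
    for counts in counts_by_sample.values():
        for i, p in enumerate(counts.pos):
            acc = pooled.setdefault(int(p), np.zeros(4, dtype=np.int64))
            acc += counts.counts[i]
            ref_of.setdefault(int(p), str(counts.ref_base[i]))
    sites = []
    for pos in sorted(pooled):
        row = pooled[pos]
        if row.sum() < min_depth:
            continue
        ref = ref_of[pos]
        nonref = row.copy()
        nonref[_BASE_INDEX[ref]] = -1
        alt_idx = int(nonref.argmax())
        if row[alt_idx] >= min_minor:
            sites.append(VariantSite(pos=pos, ref=ref, alt=str(_BASES[alt_idx])))
    return sites


@dataclass
class PCAResult:
    """Sample coordinates on the top principal components."""

    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    kept_sites: List  # site labels surviving the MAF filter
    loadings: np.ndarray  # components x kept_sites


def pca_structure(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    n_components: int = 10,
) -> PCAResult:
    """PCA of pseudo-haploid calls after a minor-allele-frequency filter.

    Sites with MAF < ``maf_min`` (over non-missing calls) are dropped,
    missing calls are mean-imputed per site, columns are centred and the
    centred matrix is decomposed by SVD. Components are sign-fixed so the
    first nonzero loading of each is positive.
    """
    if gm.data.shape[0] < 2:
        raise ValueError("need at least two samples")
    maf = gm.site_maf()
    keep = maf.index[(maf >= maf_min) & maf.notna()]
    if len(keep) < 2:
        raise ValueError(
            f"only {len(keep)} sites survive the MAF >= {maf_min} filter; need >= 2"
        )
    values = gm.data[keep].to_numpy().astype(float)
    masked = np.where(values == MISSING, np.nan, values)
    col_means = np.nanmean(masked, axis=0)
    filled = np.where(np.isnan(masked), col_means, masked)
    centred = filled - filled.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    # sign convention: first nonzero loading of each component positive
    for c in range(vt.shape[0]):
        nz = np.nonzero(np.abs(vt[c]) > 1e-12)[0]
        if nz.size and vt[c, nz[0]] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    n_comp = min(n_components, s.size)
    coords = u[:, :n_comp] * s[:n_comp]
    var = s**2
    ratio = var[:n_comp] / var.sum() if var.sum() > 0 else np.zeros(n_comp)
    frame = pd.DataFrame(
        coords,
        index=gm.data.index,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    return PCAResult(
        coordinates=frame,
        explained_variance_ratio=ratio,
        kept_sites=list(keep),
        loadings=vt[:n_comp],
    )
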