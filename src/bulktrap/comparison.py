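"""Concordance between metagenomic and metabarcoding detections.

Comparisons are restricted to genera present in both reference databases.
The headline statistic is the overlap fraction: of the genus-sample cells
the metabarcoding method detected, the share also detected by metagenomics.
A threshold sweep re-binarizes the metagenomic reports at decreasing global
minimiser thresholds to show how the conservative spike-calibrated floor
trades sensitivity for specificity, and a Welch t-test asks whether the
genera metagenomics misses are the ones with fewer barcode reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import DetectionMatrix, binarize_metagenomics_samples


@dataclass(frozen=True)
class OverlapResult:
    """Genus-sample detection overlap at one metagenomic threshold."""

    threshold: str
    n_both: int
    n_metabarcoding_only: int
    n_metagenomics_only: int

    @property
    def overlap_fraction(self) -> Optional[float]:
        denom = self.n_both + self.n_metabarcoding_only
        return self.n_both / denom if denom else None


@dataclass(frozen=True)
class AbundanceTestResult:
    """Welch t-test of barcode reads, metagenomics-detected vs non-detected."""

    statistic: float
    pvalue: float
    mean_detected: float
    mean_nondetected: float
    n_detected: int
    n_nondetected: int
    degenerate: bool = False  # both groups had zero variance


def shared_genera(dbA_genera: Iterable[str], dbB_genera: Iterable[str]) -> List[str]:
    """Sorted intersection of two reference-database genus lists."""
    common = sorted(set(dbA_genera) & set(dbB_genera))
    if not common:
        warnings.warn("reference databases share no genera; comparison is empty")
    return common


def overlap_fraction(mg: DetectionMatrix, mb: DetectionMatrix, threshold: str = "spike") -> OverlapResult:
    """Count genus-sample cells detected by both, one, or the other method."""
    if list(mg.data.index) != list(mb.data.index) or list(mg.data.columns) != list(
        mb.data.columns
    ):
        raise ValueError("matrices must share sample and genus axes; project first")
    a = mg.data.to_numpy().astype(bool)
    b = mb.data.to_numpy().astype(bool)
    return OverlapResult(
        threshold=str(threshold),
        n_both=int((a & b).sum()),
        n_metabarcoding_only=int((~a & b).sum()),
        n_metagenomics_only=int((a & ~b).sum()),
    )


def threshold_sweep(
    reports: Mapping[str, object],
    mb: DetectionMatrix,
    thresholds: Sequence[int],
    genera: Sequence[str],
    spike_genera: Sequence[str] = (),
    excluded: Iterable[str] = (),
    include_spike_mode: bool = False,
) -> List[OverlapResult]:
    """Overlap at each fixed global minimiser threshold (descending).

    With ``include_spike_mode`` the per-sample spike-calibrated thresholds
    are evaluated first, reproducing the mixed sweep in which the sample
    specific floor sits alongside the fixed ones.
    """
    mb_proj = mb.restrict(genera)
    results: List[OverlapResult] = []
    if include_spike_mode:
        mg = binarize_metagenomics_samples(reports, spike_genera, excluded).restrict(genera)
        mg = DetectionMatrix(mg.data.loc[mb_proj.data.index], mg.method, mg.thresholds, mg.excluded)
        results.append(overlap_fraction(mg, mb_proj, threshold="spike"))
    for thr in thresholds:
        if thr < 0:
            raise ValueError("thresholds must be >= 0")
        mg = binarize_metagenomics_samples(
            reports, spike_genera, excluded, global_threshold=int(thr)
        ).restrict(genera)
        mg = DetectionMatrix(mg.data.loc[mb_proj.data.index], mg.method, mg.thresholds, mg.excluded)
        results.append(overlap_fraction(mg, mb_proj, threshold=str(int(thr))))
    return results


def sweep_table(results: Sequence[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "threshold": r.threshold,
                "n_both": r.n_both,
                "n_metabarcoding_only": r.n_metabarcoding_only,
                "n_metagenomics_only": r.n_metagenomics_only,
                "overlap_fraction": r.overlap_fraction,
            }
            for r in results
        ]
    )


def heatmap_frame(
    reports: Mapping[str, object],
    mg: DetectionMatrix,
    mb: DetectionMatrix,
    mb_counts: Optional[pd.DataFrame] = None,
    genera: Optional[Sequence[str]] = None,
    near_miss_minimisers: int = 100_000,
    near_miss_reads: tuple = (25, 99),
) -> pd.DataFrame:
    """Long-format detection states per genus-sample cell, with near-miss flags.

    A metagenomic near-miss is a non-detected genus whose distinct-minimiser
    count still exceeds ``near_miss_minimisers``; a metabarcoding near-miss
    is a non-detected genus with a barcode count inside ``near_miss_reads``
    (inclusive). Both mark signal that the conservative filters discarded.
    """
    cols = list(genera) if genera is not None else list(mg.data.columns)
    mg_proj, mb_proj = mg.restrict(cols), mb.restrict(cols)
    rows = []
    for sample in mg_proj.data.index:
        minim = (
            reports[sample].distinct_minimisers_by_rank("genus")
            if sample in reports
            else pd.Series(dtype=int)
        )
        for genus in cols:
            mg_state = float(mg_proj.data.at[sample, genus])
            mb_state = (
                float(mb_proj.data.at[sample, genus])
                if sample in mb_proj.data.index
                else 0.0
            )
            n_min = int(minim.get(genus, 0))
            n_reads = (
                int(mb_counts.at[genus, sample])
                if mb_counts is not None
                and genus in mb_counts.index
                and sample in mb_counts.columns
                else 0
            )
            rows.append(
                {
                    "sample": sample,
                    "genus": genus,
                    "mg_state": mg_state,
                    "mb_state": mb_state,
                    "mg_near_miss": mg_state == 0.0 and n_min > near_miss_minimisers,
                    "mb_near_miss": mb_state == 0.0
                    and near_miss_reads[0] <= n_reads <= near_miss_reads[1],
                }
            )
    return pd.DataFrame(rows)


def abundance_difference_test(
    mb_counts: pd.DataFrame,
    mg_detection: DetectionMatrix,
    log_transform: bool = False,
) -> AbundanceTestResult:
    """Welch two-sample t-test of barcode read counts by metagenomic state.

    Each genus-sample cell contributes its barcode read count to the
    "detected" or "non-detected" group according to the metagenomic matrix.
    ``mb_counts`` is genus x sample. When both groups are constant the test
    statistic is degenerate: equal means give t=0 / p=1, unequal means give
    an infinite statistic with p=0, both flagged.
    """
    counts = mb_counts.T  # samples x genera
    shared_samples = [s for s in counts.index if s in mg_detection.data.index]
    shared_cols = [g for g in counts.columns if g in mg_detection.data.columns]
    if not shared_samples or not shared_cols:
        raise ValueError("no shared sample/genus cells between counts and detections")
    counts = counts.loc[shared_samples, shared_cols]
    states = mg_detection.data.loc[shared_samples, shared_cols]
    values = counts.to_numpy(dtype=float).ravel()
    detected_mask = states.to_numpy().astype(bool).ravel()
    if log_transform:
        values = np.log1p(values)
    detected = values[detected_mask]
    nondetected = values[~detected_mask]
    if detected.size == 0 or nondetected.size == 0:
        raise ValueError(
            f"both groups must be non-empty (detected={detected.size}, "
            f"non-detected={nondetected.size})"
        )
    var_d = detected.var(ddof=1) if detected.size > 1 else 0.0
    var_n = nondetected.var(ddof=1) if nondetected.size > 1 else 0.0
    if var_d == 0.0 and var_n == 0.0:
        equal = detected.mean() == nondetected.mean()
        stat = 0.0 if equal else np.inf * np.sign(detected.mean() - nondetected.mean())
        return AbundanceTestResult(
            statistic=float(stat),
            pvalue=1.0 if equal else 0.0,
            mean_detected=float(detected.mean()),
            mean_nondetected=float(nondetected.mean()),
            n_detected=int(detected.size),
            n_nondetected=int(nondetected.size),
            degenerate=True,
        )
    stat, pvalue = stats.ttest_ind(detected, nondetected, equal_var=False)
    return AbundanceTestResult(
        statistic=float(stat),
        pvalue=float(pvalue),
        mean_detected=float(detected.mean()),
        mean_nondetected=float(nondetected.mean()),
        n_detected=int(detected.size),
        n_nondetected=int(nondetected.size),
    )
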