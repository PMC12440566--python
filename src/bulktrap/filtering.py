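"""Binary detection matrices from classification reports and barcode tables.

Two binarization routes mirror the two survey methods:

* metagenomics — a genus counts as present in a sample when its clade
  distinct-minimiser count reaches the sample-specific threshold set by the
  weakest biological spike-in (the minimum distinct-minimiser count over the
  spike genera), is not a spike itself, and is not on the contaminant
  exclusion list;
* metabarcoding — a genus counts as present when its barcode read count
  reaches a fixed floor (default 100 reads, inclusive).

Supporting filters drop placeholder taxa ("unclassified", names suffixed
with _X/_XX/... marking unresolved ranks), taxa prevalent in negative
controls, and barcode clusters with fewer than three reads overall.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set

import pandas as pd

_PLACEHOLDER_SUFFIX = re.compile(r"_X+$")


class SpikeFailureError(RuntimeError):
    """All spike genera have zero distinct minimisers; no threshold exists."""


@dataclass
class DetectionMatrix:
    """Sample x genus presence (1.0) / non-detection (0.0) for one method.

    ``thresholds`` records the per-sample detection floor actually applied
    (distinct minimisers or barcode reads), ``excluded`` the taxa removed
    before binarization.
    """

    data: pd.DataFrame
    method: str
    thresholds: Dict[str, float] = field(default_factory=dict)
    excluded: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if not ((values == 0.0) | (values == 1.0)).all():
            raise ValueError("detection values must be 0.0 or 1.0")
        if self.data.columns.duplicated().any():
            raise ValueError("genera must be unique")

    @property
    def samples(self) -> List[str]:
        return list(self.data.index)

    @property
    def genera(self) -> List[str]:
        return list(self.data.columns)

    def restrict(self, genera: Sequence[str]) -> "DetectionMatrix":
        """Project onto a genus list (missing genera become non-detections)."""
        projected = self.data.reindex(columns=list(genera), fill_value=0.0)
        return DetectionMatrix(projected, self.method, dict(self.thresholds), set(self.excluded))

    def n_detections(self) -> int:
        return int(self.data.to_numpy().sum())

    def to_tsv(self, path, provenance_path=None) -> None:
        """Write the matrix; optionally a sidecar of per-sample thresholds
        and excluded taxa."""
        self.data.rename_axis("sample").to_csv(path, sep="\t")
        if provenance_path is not None:
            frame = pd.DataFrame(
                {
                    "sample": list(self.thresholds),
                    "threshold": list(self.thresholds.values()),
                    "method": self.method,
                    "excluded_taxa": ",".join(sorted(self.excluded)),
                }
            )
            frame.to_csv(provenance_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, method: str) -> "DetectionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="sample").rename_axis(None)
        return cls(frame.astype(float), method)


@dataclass(frozen=True)
class BlankProfile:
    """Occurrence counts of taxa across negative controls."""

    n_blanks: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.n_blanks <= 0:
            raise ValueError("n_blanks must be positive")
        bad = [t for t, c in self.counts.items() if c < 0 or c > self.n_blanks]
        if bad:
            raise ValueError(f"blank counts out of range for {bad!r}")


def spike_threshold(report, spike_genera: Sequence[str]) -> int:
    """Sample-specific detection floor: min distinct minimisers over spikes.

    The weakest spike genus defines the least signal a taxon known to be in
    the sample can produce; anything below it is unreliable. Raises
    :class:`SpikeFailureError` when every spike genus has zero distinct
    minimisers (the sample cannot be thresholded).
    """
    if not spike_genera:
        raise ValueError("need at least one spike genus")
    counts = report.distinct_minimisers_by_rank("genus")
    missing = [g for g in spike_genera if g not in counts.index]
    if missing:
        raise ValueError(f"spike genera absent from the report taxonomy: {missing!r}")
    spike_counts = counts.loc[list(spike_genera)]
    if (spike_counts == 0).all():
        raise SpikeFailureError(
            f"all spike genera have zero distinct minimisers: {list(spike_genera)!r}"
        )
    return int(spike_counts.min())


def binarize_metagenomics(
    report,
    threshold: int,
    excluded: Iterable[str] = (),
    spike_genera: Iterable[str] = (),
) -> pd.Series:
    """One sample's presence row: distinct minimisers >= threshold (inclusive).

    Spike genera and excluded taxa are forced to non-detection regardless of
    signal.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    counts = report.distinct_minimisers_by_rank("genus")
    drop = set(excluded) | set(spike_genera)
    present = (counts >= threshold).astype(float)
    present[present.index.isin(drop)] = 0.0
    return present


def binarize_metagenomics_samples(
    reports: Mapping[str, object],
    spike_genera: Sequence[str],
    excluded: Iterable[str] = (),
    global_threshold: int | None = None,
) -> DetectionMatrix:
    """Assemble the metagenomic DetectionMatrix over samples.

    With ``global_threshold`` unset each sample uses its spike-derived
    threshold; otherwise the fixed threshold is applied everywhere (used by
    the threshold sweep).
    """
    rows = {}
    thresholds: Dict[str, float] = {}
    for sample, report in reports.items():
        thr = global_threshold if global_threshold is not None else spike_threshold(
            report, spike_genera
        )
        thresholds[sample] = float(thr)
        rows[sample] = binarize_metagenomics(report, thr, excluded, spike_genera)
    data = pd.DataFrame(rows).T.sort_index()
    return DetectionMatrix(
        data, method="metagenomics", thresholds=thresholds, excluded=set(excluded)
    )


def binarize_metabarcoding(
    counts: pd.DataFrame,
    min_reads: int = 100,
) -> DetectionMatrix:
    """Binarize a genus x sample barcode count table at a read floor.

    Presence requires ``count >= min_reads`` (inclusive, consistent with the
    minimiser rule).
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("barcode counts must be non-negative")
    data = (counts.T >= min_reads).astype(float)  # samples x genera
    thresholds = {sample: float(min_reads) for sample in data.index}
    return DetectionMatrix(data, method="metabarcoding", thresholds=thresholds)


def placeholder_filter(genus_names: Iterable[str]) -> List[str]:
    """Drop unresolved-taxonomy placeholders.

    Removes names equal to "unclassified" (case-insensitive) and names
    carrying an underscore-X suffix (Hominidae_X, Hominidae_XX, ...) that
    marks a missing genus-level assignment.
    """
    return [
        name
        for name in genus_names
        if name.lower() != "unclassified" and not _PLACEHOLDER_SUFFIX.search(name)
    ]


def blank_filter(blanks: BlankProfile, max_fraction: float = 0.05) -> Set[str]:
    """Taxa to exclude as likely contaminants from negative controls.

    A taxon is excluded when its blank-occurrence count reaches
    ``floor(max_fraction * n_blanks)`` — at 281 blanks and 5% that is 14
    blanks or more.
    """
    cutoff = math.floor(max_fraction * blanks.n_blanks)
    return {taxon for taxon, count in blanks.counts.items() if count >= cutoff}


def min_read_cluster_filter(
    cluster_totals: Mapping[str, int],
    min_total: int = 3,
) -> List[str]:
    """Retain clusters with at least ``min_total`` reads across all datasets."""
    bad = [c for c, t in cluster_totals.items() if t < 0]
    if bad:
        raise ValueError(f"negative cluster totals for {bad!r}")
    return [c for c, t in cluster_totals.items() if t >= min_total]
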