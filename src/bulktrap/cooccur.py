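"""Plant-arthropod co-occurrence from joint detections.

Plant species are detected from the plant-database classification reports
(distinct-minimiser floor, default 5000); arthropod genera come from the
filtered metagenomic detection matrix. A co-occurrence is a sample in which
both pass their filters, so each plant-genus pair's count is bounded by the
smaller of the two prevalences. Pairs are annotated against a local table
of known plant-pollinator interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .filtering import DetectionMatrix


@dataclass
class CooccurrenceMatrix:
    """Plant species x arthropod genus joint-detection counts.

    ``confirmed`` flags pairs with a known interaction record;
    ``plant_in_database`` flags plants that appear anywhere in the
    interaction table (so an unflagged pair under a covered plant is a
    candidate novel interaction, while one under an uncovered plant is
    simply unassessed).
    """

    counts: pd.DataFrame  # plants x genera
    plant_prevalence: pd.Series
    genus_prevalence: pd.Series
    n_samples: int
    confirmed: pd.DataFrame = field(default_factory=pd.DataFrame)
    plant_in_database: pd.Series = field(default_factory=pd.Series)

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if (values < 0).any() or (values > self.n_samples).any():
            raise ValueError("pair counts must lie in [0, n_samples]")
        upper = np.minimum.outer(
            self.plant_prevalence.loc[self.counts.index].to_numpy(),
            self.genus_prevalence.loc[self.counts.columns].to_numpy(),
        )
        if (values > upper).any():
            raise ValueError("pair count exceeds min of the two prevalences")

    def to_long_frame(self) -> pd.DataFrame:
        long = (
            self.counts.rename_axis("plant")
            .reset_index()
            .melt(id_vars="plant", var_name="genus", value_name="count")
        )
        if not self.confirmed.empty:
            conf = (
                self.confirmed.rename_axis("plant")
                .reset_index()
                .melt(id_vars="plant", var_name="genus", value_name="confirmed")
            )
            long = long.merge(conf, on=["plant", "genus"], how="left")
        else:
            long["confirmed"] = False
        return long


def filter_plants(
    reports: Mapping[str, object],
    min_minimisers: int = 5000,
) -> pd.DataFrame:
    """Sample x plant-species presence at a distinct-minimiser floor."""
    rows = {}
    for sample, report in reports.items():
        counts = report.distinct_minimisers_by_rank("species")
        rows[sample] = (counts >= min_minimisers).astype(float)
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows).T.sort_index().fillna(0.0)


def top_taxa(abundance: pd.Series, n: int) -> List[str]:
    """The n most abundant taxa (summed distinct minimisers across samples).

    Ties are broken alphabetically so the selection is deterministic; asking
    for more taxa than exist returns all of them with a warning.
    """
    if n > len(abundance):
        warnings.warn(
            f"requested {n} taxa but only {len(abundance)} available; returning all"
        )
        n = len(abundance)
    ordered = abundance.sort_index().sort_values(ascending=False, kind="stable")
    return list(ordered.index[:n])


def build_matrix(
    plants: pd.DataFrame,
    arthropods: DetectionMatrix,
) -> CooccurrenceMatrix:
    """Count, per plant-genus pair, the samples where both are detected."""
    shared = [s for s in plants.index if s in arthropods.data.index]
    if not shared:
        raise ValueError("plant and arthropod tables share no samples")
    p = plants.loc[shared].astype(bool)
    a = arthropods.data.loc[shared].astype(bool)
    counts = pd.DataFrame(
        p.to_numpy().T.astype(int) @ a.to_numpy().astype(int),
        index=p.columns,
        columns=a.columns,
    )
    return CooccurrenceMatrix(
        counts=counts,
        plant_prevalence=p.sum().astype(int),
        genus_prevalence=a.sum().astype(int),
        n_samples=len(shared),
    )


def annotate_interactions(
    matrix: CooccurrenceMatrix,
    interactions: pd.DataFrame,
) -> CooccurrenceMatrix:
    """Flag known interactions from a local plant x genus interaction table.

    ``interactions`` needs columns ``plant`` (species name) and ``genus``.
    A pair is confirmed when it appears in the table; a plant is covered by
    the database when it appears in any row.
    """
    for col in ("plant", "genus"):
        if col not in interactions.columns:
            raise ValueError(f"interaction table lacks a {col!r} column")
    known_pairs: Set[Tuple[str, str]] = {
        (str(r.plant), str(r.genus)) for r in interactions.itertuples(index=False)
    }
    known_plants = {p for p, _ in known_pairs}
    confirmed = pd.DataFrame(
        [
            [(plant, genus) in known_pairs for genus in matrix.counts.columns]
            for plant in matrix.counts.index
        ],
        index=matrix.counts.index,
        columns=matrix.counts.columns,
    )
    covered = pd.Series(
        [plant in known_plants for plant in matrix.counts.index],
        index=matrix.counts.index,
    )
    return CooccurrenceMatrix(
        counts=matrix.counts,
        plant_prevalence=matrix.plant_prevalence,
        genus_prevalence=matrix.genus_prevalence,
        n_samples=matrix.n_samples,
        confirmed=confirmed,
        plant_in_database=covered,
    )
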