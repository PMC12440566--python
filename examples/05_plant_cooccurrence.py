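"""Plant-arthropod co-occurrence from joint post-filter detections.

Plant species detected from the plant-database reports (distinct-minimiser
floor) are crossed with the filtered arthropod genus detections: a
co-occurrence is a sample containing both. Pairs are annotated against a
local table of known plant-pollinator interactions, so a starred cell is a
confirmed interaction candidate and an unstarred cell under a covered
plant is a potential novel one.
"""

import numpy as np
import pandas as pd

import bulktrap as bt

rng = np.random.default_rng(21)
samples = [f"s{i:02d}" for i in range(10)]
plants = ["Vaccinium myrtillus", "Ranunculus repens", "Melampyrum pratense"]
genera = ["Bombus", "Formica", "Pollenia", "Sphaerophoria"]


# plant reports with random distinct-minimiser counts per species
class _Report:
    def __init__(self, counts):
        self._counts = pd.Series(counts)

    def distinct_minimisers_by_rank(self, rank):
        return self._counts.sort_index()


reports = {
    s: _Report({p: int(c) for p, c in zip(plants, rng.integers(0, 12_000, 3))})
    for s in samples
}
presence = bt.filter_plants(reports, min_minimisers=5000)

arthro = bt.DetectionMatrix(
    pd.DataFrame(rng.integers(0, 2, (10, 4)).astype(float),
                 index=samples, columns=genera),
    method="metagenomics",
)

matrix = bt.build_matrix(presence, arthro)
interactions = pd.DataFrame(
    {"plant": ["Vaccinium myrtillus", "Melampyrum pratense"],
     "genus": ["Bombus", "Sphaerophoria"]}
)
annotated = bt.annotate_interactions(matrix, interactions)

print(annotated.counts)
print()
print("genus prevalence (samples detected):")
print(annotated.genus_prevalence.to_string())
print()
for plant in annotated.counts.index:
    covered = "in interaction DB" if annotated.plant_in_database[plant] else "not in DB"
    stars = [g for g in annotated.counts.columns if annotated.confirmed.loc[plant, g]]
    print(f"  {plant}: {covered}; confirmed pairs: {stars or 'none'}")
print()
print("Each cell counts samples where plant and genus were both detected "
      "after filtering; counts are bounded by the smaller prevalence.")
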