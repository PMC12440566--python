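"""Spike-in-calibrated detection filtering of classification reports.

Two cockroach/cricket-like spike genera are added to every sample at a
fixed read allocation. The weakest spike's distinct-minimiser count sets
each sample's detection floor; genera at or above it (and not themselves
spikes or known blank contaminants) are scored present. The companion
barcode table is binarized at the 100-read floor.
"""

import bulktrap as bt

tree = bt.make_taxonomy(n_genera=6, species_per_genus=2)
genomes = bt.make_genomes(tree, length=2000, divergence=0.05, seed=4)
community = bt.make_community(tree, n_samples=3, seed=5,
                              spike_species=("g5s1", "g6s1"), spike_reads=60)
spike_genera = ("Genus05", "Genus06")
reads = bt.make_reads(genomes, community, n_reads=2000, read_length=90,
                      error_rate=0.005, seed=6)

index = bt.build_index(genomes, tree, k=31)
reports = {s: bt.classify_sample(r, index, sample=s)[0] for s, r in reads.items()}

for sample, report in reports.items():
    print(f"{sample}: spike threshold = "
          f"{bt.spike_threshold(report, spike_genera)} distinct minimisers")

blanks = bt.BlankProfile(n_blanks=281, counts={"Genus01": 20, "Genus02": 3})
excluded = bt.blank_filter(blanks)  # taxa in >=14 of 281 blanks are contaminants
print(f"excluded as blank contaminants: {sorted(excluded)}")

mg = bt.binarize_metagenomics_samples(reports, spike_genera, excluded=excluded)
print()
print(mg.data)
print("1.0 = present, 0.0 = non-detection; spike genera and blank "
      "contaminants are always 0.0.")

barcode = bt.make_barcode_counts(community, tree, total_reads=30_000, seed=7)
mb = bt.binarize_metabarcoding(barcode, min_reads=100)
print()
print(mb.data)
print("Metabarcoding presence needs >= 100 barcode reads.")
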