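"""Miniature k-mer/LCA taxonomic classifier.

The index maps every canonical k-mer (lexicographic minimum of a k-mer and
its reverse complement, default k=31) occurring in a set of reference
genomes to the lowest common ancestor of all species whose genomes contain
it. A read is classified by counting k-mer hits per taxon, scoring every
root-to-leaf path of the taxonomy by the summed hits on its nodes, and
assigning the deepest node of the maximal path; exact ties are broken by
taking the LCA of the tied leaves, which is how multi-species matches
collapse to genus or family level. Databases can be applied sequentially:
reads a database cannot classify are passed forward to the next one.

Reports mirror the classifier-report convention of clade read counts plus
per-clade total and distinct minimiser counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .synthetic import GenomeSet, Read
from .taxonomy import RANK_CODES, TaxonomyTree

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

REPORT_COLUMNS = [
    "percent",
    "clade_reads",
    "direct_reads",
    "total_minimisers",
    "distinct_minimisers",
    "rank_code",
    "taxon_id",
    "name",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def iter_canonical_kmers(seq: str, k: int):
    """Canonical k-mers of a sequence; windows containing non-ACGT are skipped.

    Yields ``(kmer, valid)`` pairs where invalid windows yield
    ``(None, False)`` so callers can count skips.
    """
    valid = set("ACGT")
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if set(window) <= valid:
            yield canonical_kmer(window), True
        else:
            yield None, False


class IndexError_(ValueError):
    """Invalid index construction arguments."""


@dataclass
class MinimiserIndex:
    """Canonical k-mer -> LCA taxon map over one reference database."""

    k: int
    kmer_to_taxon: Dict[str, str]
    tree: TaxonomyTree
    name: str = "db"
    skipped_kmers: int = 0

    def __len__(self) -> int:
        return len(self.kmer_to_taxon)


def build_index(
    genomes: GenomeSet,
    tree: TaxonomyTree,
    k: int = 31,
    name: str = "db",
) -> MinimiserIndex:
    """Index a genome set: each canonical k-mer maps to the LCA of its sources.

    A k-mer present in the genomes of several species is stored at the
    lowest common ancestor of those species, so genus-shared sequence is
    reported at genus level. Windows containing non-ACGT characters are
    skipped and counted.
    """
    if not genomes.sequences:
        raise IndexError_("empty genome set")
    shortest = min(len(s) for s in genomes.sequences.values())
    if k > shortest:
        raise IndexError_(f"k={k} exceeds the shortest genome ({shortest} bp)")
    for sid in genomes.sequences:
        if sid not in tree:
            raise IndexError_(f"genome {sid!r} has no taxon in the tree")

    kmer_species: Dict[str, Set[str]] = {}
    skipped = 0
    for sid, seq in genomes.sequences.items():
        for kmer, ok in iter_canonical_kmers(seq.upper(), k):
            if not ok:
                skipped += 1
                continue
            kmer_species.setdefault(kmer, set()).add(sid)
    mapping = {
        kmer: species.pop() if len(species) == 1 else tree.lca(species)
        for kmer, species in kmer_species.items()
    }
    return MinimiserIndex(k=k, kmer_to_taxon=mapping, tree=tree, name=name, skipped_kmers=skipped)


def classify_read(read_seq: str, index: MinimiserIndex) -> Optional[str]:
    """Assign one read to a taxon id, or None if no k-mer hits.

    Hits per taxon are accumulated over the read's canonical k-mers; every
    root-to-leaf path is scored by the sum of hits on its nodes; the read is
    assigned the deepest node of the maximal path, with exact ties resolved
    to the LCA of the tied leaves. Reads shorter than k are unclassifiable.
    """
    if len(read_seq) < index.k:
        return None
    hits: Counter = Counter()
    for kmer, ok in iter_canonical_kmers(read_seq.upper(), index.k):
        if not ok:
            continue
        taxon = index.kmer_to_taxon.get(kmer)
        if taxon is not None:
            hits[taxon] += 1
    return resolve_hits(hits, index.tree)


def resolve_hits(hits: Mapping[str, int], tree: TaxonomyTree) -> Optional[str]:
    """Path-scoring resolution of per-taxon hit counts (shared with reports)."""
    if not hits:
        return None
    leaf_scores: Counter = Counter()
    for taxon, count in hits.items():
        for leaf in tree.subtree_species(taxon):
            leaf_scores[leaf] += count
    best = max(leaf_scores.values())
    tied = [leaf for leaf, score in leaf_scores.items() if score == best]
    return tied[0] if len(tied) == 1 else tree.lca(tied)


@dataclass
class ClassificationReport:
    """Per-sample, per-database classification summary.

    ``direct_reads`` counts reads assigned exactly to a node;
    ``minimiser_hits`` and ``minimiser_sets`` accumulate, per node, the hit
    count and distinct canonical k-mers whose index entry points at that
    node. Clade-level quantities aggregate over each node's subtree.
    """

    tree: TaxonomyTree
    sample: str = "sample"
    database: str = "db"
    n_reads: int = 0
    unclassified: int = 0
    direct_reads: Counter = field(default_factory=Counter)
    minimiser_hits: Counter = field(default_factory=Counter)
    minimiser_sets: Dict[str, Set[str]] = field(default_factory=dict)

    # -- aggregation -------------------------------------------------------

    def _subtree_nodes(self, taxon_id: str) -> List[str]:
        out = [taxon_id]
        for child in self.tree.children(taxon_id):
            out.extend(self._subtree_nodes(child))
        return out

    def clade_reads(self, taxon_id: str) -> int:
        return sum(self.direct_reads.get(n, 0) for n in self._subtree_nodes(taxon_id))

    def clade_total_minimisers(self, taxon_id: str) -> int:
        return sum(self.minimiser_hits.get(n, 0) for n in self._subtree_nodes(taxon_id))

    def clade_distinct_minimisers(self, taxon_id: str) -> int:
        distinct: Set[str] = set()
        for n in self._subtree_nodes(taxon_id):
            distinct |= self.minimiser_sets.get(n, set())
        return len(distinct)

    def classified(self) -> int:
        return self.n_reads - self.unclassified

    # -- named accessors used by the detection filters ---------------------

    def distinct_minimisers_by_rank(self, rank: str) -> pd.Series:
        """Clade distinct-minimiser counts keyed by taxon name at a rank."""
        data = {
            self.tree.name(nid): self.clade_distinct_minimisers(nid)
            for nid in self.tree.ids_at_rank(rank)
        }
        return pd.Series(data, dtype=int).sort_index()

    def clade_reads_by_rank(self, rank: str) -> pd.Series:
        data = {
            self.tree.name(nid): self.clade_reads(nid)
            for nid in self.tree.ids_at_rank(rank)
        }
        return pd.Series(data, dtype=int).sort_index()

    # -- tabular form ------------------------------------------------------

    def to_table(self) -> pd.DataFrame:
        """Report rows: unclassified first, then nonzero clades in DFS order."""
        total = self.n_reads
        # an empty report is written as a single all-unclassified row
        rows = [
            {
                "percent": 100.0 if total == 0 else round(100.0 * self.unclassified / total, 2),
                "clade_reads": self.unclassified,
                "direct_reads": self.unclassified,
                "total_minimisers": 0,
                "distinct_minimisers": 0,
                "rank_code": "U",
                "taxon_id": "unclassified",
                "name": "unclassified",
            }
        ]
        for nid in self.tree.depth_first():
            clade = self.clade_reads(nid)
            if clade == 0:
                continue
            rows.append(
                {
                    "percent": round(100.0 * clade / total, 2),
                    "clade_reads": clade,
                    "direct_reads": self.direct_reads.get(nid, 0),
                    "total_minimisers": self.clade_total_minimisers(nid),
                    "distinct_minimisers": self.clade_distinct_minimisers(nid),
                    "rank_code": RANK_CODES[self.tree.rank(nid)],
                    "taxon_id": nid,
                    "name": "  " * self.tree.depth(nid) + self.tree.name(nid),
                }
            )
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def classify_sample(
    reads: Sequence[Read],
    index: MinimiserIndex,
    sample: str = "sample",
) -> Tuple[ClassificationReport, List[Read]]:
    """Classify one sample against one database.

    Returns the report plus the reads the database could not classify
    (which sequential classification feeds to the next database). Minimiser
    statistics accumulate only over classified reads, so an unclassifiable
    read never contributes hits.
    """
    report = ClassificationReport(
        tree=index.tree, sample=sample, database=index.name, n_reads=len(reads)
    )
    unclassified: List[Read] = []
    for read in reads:
        hits: Counter = Counter()
        kmer_by_taxon: Dict[str, Set[str]] = {}
        if len(read.sequence) >= index.k:
            for kmer, ok in iter_canonical_kmers(read.sequence.upper(), index.k):
                if not ok:
                    continue
                taxon = index.kmer_to_taxon.get(kmer)
                if taxon is not None:
                    hits[taxon] += 1
                    kmer_by_taxon.setdefault(taxon, set()).add(kmer)
        assigned = resolve_hits(hits, index.tree)
        if assigned is None:
            unclassified.append(read)
            continue
        report.direct_reads[assigned] += 1
        for taxon, count in hits.items():
            report.minimiser_hits[taxon] += count
            report.minimiser_sets.setdefault(taxon, set()).update(kmer_by_taxon[taxon])
    report.unclassified = len(unclassified)
    return report, unclassified


def classify_sample_sequential(
    reads: Sequence[Read],
    indexes: Sequence[MinimiserIndex],
    sample: str = "sample",
) -> Tuple[List[ClassificationReport], List[Read]]:
    """Run databases in order; only still-unclassified reads move forward.

    Each read therefore lands in exactly one report (or the final
    unclassified set): the sum of classified reads over all reports plus the
    final unclassified count equals the input read count.
    """
    if not indexes:
        raise ValueError("need at least one index")
    reports: List[ClassificationReport] = []
    pending = list(reads)
    for index in indexes:
        report, pending = classify_sample(pending, index, sample=sample)
        reports.append(report)
    return reports, pending


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------


def write_report(report: ClassificationReport, path) -> None:
    """Write the report table as TSV (columns as in REPORT_COLUMNS)."""
    report.to_table().to_csv(path, sep="\t", index=False)


@dataclass
class ParsedReport:
    """A report read back from disk; exposes the accessors the filters need."""

    table: pd.DataFrame

    def distinct_minimisers_by_rank(self, rank: str) -> pd.Series:
        code = RANK_CODES[rank]
        sub = self.table[self.table["rank_code"] == code]
        return pd.Series(
            sub["distinct_minimisers"].to_numpy(),
            index=sub["name"].str.strip().to_numpy(),
            dtype=int,
        ).sort_index()

    def clade_reads_by_rank(self, rank: str) -> pd.Series:
        code = RANK_CODES[rank]
        sub = self.table[self.table["rank_code"] == code]
        return pd.Series(
            sub["clade_reads"].to_numpy(),
            index=sub["name"].str.strip().to_numpy(),
            dtype=int,
        ).sort_index()


def read_report(path) -> ParsedReport:
    table = pd.read_csv(path, sep="\t", keep_default_na=False)
    return ParsedReport(table[REPORT_COLUMNS])
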