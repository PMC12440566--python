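"""Synthetic inputs with known ground truth.

Everything the downstream pipeline consumes can be generated here: a small
ranked taxonomy, toy genomes diverged along its branches, log-normal
community compositions with biological spike-ins, error-bearing shotgun
reads whose names carry their true species, genus-level barcode count
tables with capture bias, and per-site base counts from pooled
mitochondrial haplotypes. Each operation takes a single integer seed and is
byte-stable for a fixed seed.

The generator emulates merged (single-end) shotgun reads with independent
per-site substitutions and no indels, which keeps exact k-mer identity
analysable; spike-ins are injected as fixed read counts per sample so the
spike-calibrated detection floor is controllable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .taxonomy import RANKS, TaxonNode, TaxonomyTree

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSet:
    """Nucleotide sequences per species id, with optional mitochondrial flags.

    ``mito_ids`` marks which entries are designated mitochondrial sequences
    (used by the pooled-haplotype workflow); it must be a subset of the
    sequence keys.
    """

    sequences: Dict[str, str]
    mito_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        for sid, seq in self.sequences.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"genome {sid!r} contains non-ACGT characters")
        if not self.mito_ids <= set(self.sequences):
            raise ValueError("mito_ids must reference existing sequences")

    def __len__(self) -> int:
        return len(self.sequences)

    def write_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=sid, description="")
            for sid, seq in self.sequences.items()
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path) -> "GenomeSet":
        return cls({r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")})


@dataclass
class CommunityTable:
    """True community composition: samples x species relative abundances.

    ``abundances`` rows sum to one; ``spikes`` gives, per sample, the fixed
    number of reads allocated to each spike-in species. Spike species must
    have zero wild abundance within the same sample.
    """

    abundances: pd.DataFrame
    spikes: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.abundances.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        sums = self.abundances.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-sample abundances must sum to 1 (+/- 1e-9)")
        for sample, alloc in self.spikes.items():
            if sample not in self.abundances.index:
                raise ValueError(f"spike sample {sample!r} not in abundance table")
            for sp in alloc:
                if sp in self.abundances.columns and self.abundances.at[sample, sp] > 0:
                    raise ValueError(
                        f"spike species {sp!r} has nonzero wild abundance in {sample!r}"
                    )

    @property
    def samples(self) -> List[str]:
        return list(self.abundances.index)

    def to_tsv(self, path) -> None:
        self.abundances.rename_axis("sample").to_csv(path, sep="\t")


@dataclass(frozen=True)
class PoolConfig:
    """A simulated pool of k mitochondrial haplotypes.

    ``weights`` are the fraction of reads contributed by each individual;
    ``depth`` is the mean per-site coverage of the whole pool; errors are
    independent per-base substitutions to a uniformly chosen other base.
    """

    haplotypes: Tuple[str, ...]
    weights: Tuple[float, ...]
    depth: float
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.haplotypes) == 0:
            raise ValueError("need at least one haplotype")
        lengths = {len(h) for h in self.haplotypes}
        if len(lengths) != 1:
            raise ValueError("haplotypes must all have equal length")
        if len(self.weights) != len(self.haplotypes):
            raise ValueError("one weight per haplotype required")
        if not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")

    @property
    def k_individuals(self) -> int:
        return len(self.haplotypes)


@dataclass(frozen=True)
class Read:
    """A simulated read; ``species`` is the truth label encoded in its name."""

    name: str
    sequence: str
    species: str


# ---------------------------------------------------------------------------
# taxonomy / genomes
# ---------------------------------------------------------------------------


def make_taxonomy(
    n_genera: int,
    species_per_genus: int,
    seed: int = 0,
    prefix: str = "Genus",
) -> TaxonomyTree:
    """Build a full eight-rank tree with ``n_genera * species_per_genus`` species.

    Genera are grouped into families of up to three; ranks above family form
    a single lineage. Construction is deterministic; ``seed`` is accepted for
    interface uniformity with the other generators.
    """
    del seed
    if n_genera < 1 or species_per_genus < 1:
        raise ValueError("n_genera and species_per_genus must be >= 1")
    nodes: List[TaxonNode] = []
    upper_names = {
        "root": "root",
        "domain": "Eukaryota",
        "phylum": "Arthropoda",
        "class": "Insecta",
        "order": "Simuliformes",
    }
    parent: Optional[str] = None
    for rank in RANKS[:5]:
        nid = f"{rank[:1]}1"
        nodes.append(TaxonNode(nid, upper_names[rank], rank, parent))
        parent = nid
    order_id = parent
    n_families = (n_genera + 2) // 3
    for f in range(n_families):
        fid = f"f{f + 1}"
        nodes.append(TaxonNode(fid, f"{prefix}idae{f + 1:02d}", "family", order_id))
    for g in range(n_genera):
        gid = f"g{g + 1}"
        fid = f"f{g // 3 + 1}"
        gname = f"{prefix}{g + 1:02d}"
        nodes.append(TaxonNode(gid, gname, "genus", fid))
        for s in range(species_per_genus):
            sid = f"{gid}s{s + 1}"
            nodes.append(TaxonNode(sid, f"{gname}_sp{s + 1}", "species", gid))
    return TaxonomyTree(nodes)


def _mutate(seq_codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position independently with probability ``rate``."""
    if rate == 0.0:
        return seq_codes.copy()
    out = seq_codes.copy()
    hit = rng.random(out.size) < rate
    n = int(hit.sum())
    if n:
        # uniform choice among the three other bases
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[codes])


def str_to_codes(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int64, count=len(seq))


def make_genomes(
    tree: TaxonomyTree,
    length: int,
    divergence: float,
    seed: int = 0,
    k: int = 31,
) -> GenomeSet:
    """Evolve one genome per species down the taxonomy.

    A random ancestral sequence is placed at the root and mutated
    independently along every branch at per-site substitution rate
    ``divergence``, so congeners share more exact k-mers than cross-genus
    pairs in expectation. ``length`` must be at least ``2k - 1`` so every
    genome contributes at least ``k`` k-mers.
    """
    if length < 2 * k - 1:
        raise ValueError(f"length must be >= {2 * k - 1} (2k-1 for k={k})")
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    ancestral = rng.integers(0, 4, size=length)
    node_seq: Dict[str, np.ndarray] = {tree.root: ancestral}
    sequences: Dict[str, str] = {}
    # deterministic walk: depth_first visits parents before children
    for nid in tree.depth_first():
        if nid == tree.root:
            continue
        parent_codes = node_seq[tree.node(nid).parent]
        node_seq[nid] = _mutate(parent_codes, divergence, rng)
        if tree.rank(nid) == "species":
            sequences[nid] = _codes_to_str(node_seq[nid])
    return GenomeSet(sequences)


def make_mito_haplotypes(
    length: int,
    k_individuals: int,
    divergence: float,
    seed: int = 0,
) -> Tuple[str, ...]:
    """Independent haplotypes mutated from one ancestral mitochondrial sequence.

    With per-site rate ``divergence`` per haplotype, most variant sites are
    private to a single individual, which gives pooled allele-frequency
    spectra their characteristic 1/k peaks.
    """
    rng = np.random.default_rng(seed)
    ancestral = rng.integers(0, 4, size=length)
    return tuple(
        _codes_to_str(_mutate(ancestral, divergence, rng))
        for _ in range(k_individuals)
    )


# ---------------------------------------------------------------------------
# communities and reads
# ---------------------------------------------------------------------------


def make_community(
    tree: TaxonomyTree,
    n_samples: int,
    seed: int = 0,
    sigma: float = 1.5,
    spike_species: Sequence[str] = (),
    spike_reads: int = 200,
) -> CommunityTable:
    """Log-normal relative abundances per sample with fixed spike-in reads.

    Wild abundances are drawn log-normally (scale ``sigma``) over all
    non-spike species and normalised per sample; every sample receives each
    spike species at a fixed ``spike_reads`` read allocation.
    """
    rng = np.random.default_rng(seed)
    species = tree.ids_at_rank("species")
    wild = [s for s in species if s not in set(spike_species)]
    if not wild:
        raise ValueError("no wild species left after removing spikes")
    samples = [f"sample{i + 1:02d}" for i in range(n_samples)]
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=(n_samples, len(wild)))
    abund = raw / raw.sum(axis=1, keepdims=True)
    frame = pd.DataFrame(abund, index=samples, columns=wild)
    spikes = {
        s: {sp: spike_reads for sp in spike_species} for s in samples
    }
    return CommunityTable(frame, spikes)


def make_reads(
    genomes: GenomeSet,
    community: CommunityTable,
    n_reads: int,
    read_length: int = 120,
    error_rate: float = 0.005,
    seed: int = 0,
) -> Dict[str, List[Read]]:
    """Simulate merged shotgun reads per sample.

    ``n_reads`` wild reads are drawn per sample from species in proportion
    to abundance, with uniform start positions and independent per-base
    substitution errors; spike-in species then contribute their fixed read
    allocations on top. Read names encode the true species id.
    """
    if community.abundances.shape[1] == 0:
        raise ValueError("community has no species")
    min_len = min(len(s) for s in genomes.sequences.values())
    if read_length > min_len:
        raise ValueError("read_length exceeds the shortest genome")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    rng = np.random.default_rng(seed)
    out: Dict[str, List[Read]] = {}
    for sample in community.samples:
        probs = community.abundances.loc[sample]
        species = list(probs.index)
        counts = rng.multinomial(n_reads, probs.to_numpy()) if n_reads else np.zeros(
            len(species), dtype=int
        )
        alloc: List[Tuple[str, int]] = list(zip(species, counts))
        alloc += list(community.spikes.get(sample, {}).items())
        reads: List[Read] = []
        idx = 0
        for sp, count in alloc:
            if count == 0:
                continue
            if sp not in genomes.sequences:
                raise ValueError(f"no genome for species {sp!r}")
            codes = str_to_codes(genomes.sequences[sp])
            starts = rng.integers(0, len(codes) - read_length + 1, size=count)
            for start in starts:
                frag = _mutate(codes[start : start + read_length], error_rate, rng)
                reads.append(
                    Read(
                        name=f"{sample}_r{idx:06d}|species={sp}",
                        sequence=_codes_to_str(frag),
                        species=sp,
                    )
                )
                idx += 1
        out[sample] = reads
    return out


def write_fastq(reads: Sequence[Read], path, quality: int = 40) -> None:
    """Write reads as FASTQ with constant Phred-33 quality."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.name, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_fastq(path) -> List[Read]:
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        species = ""
        if "|species=" in rec.id:
            species = rec.id.split("|species=", 1)[1]
        reads.append(Read(rec.id, str(rec.seq).upper(), species))
    return reads


# ---------------------------------------------------------------------------
# barcode counts
# ---------------------------------------------------------------------------


def make_barcode_counts(
    community: CommunityTable,
    tree: TaxonomyTree,
    total_reads: int,
    capture_bias: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Genus x sample barcode read counts with per-species capture bias.

    Reads are a multinomial draw over wild species with probabilities
    proportional to abundance times bias, aggregated to genus; a strong
    downward bias emulates amplification dropout.
    """
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    bias = dict(capture_bias or {})
    for mult in bias.values():
        if mult <= 0:
            raise ValueError("capture bias multipliers must be > 0")
    rng = np.random.default_rng(seed)
    species = list(community.abundances.columns)
    genus_names = []
    for sp in species:
        gid = tree.genus_of(sp)
        if gid is None:
            raise ValueError(f"species {sp!r} has no genus in the tree")
        genus_names.append(tree.name(gid))
    rows = {}
    for sample in community.samples:
        weights = community.abundances.loc[sample].to_numpy() * np.array(
            [bias.get(sp, 1.0) for sp in species]
        )
        total_w = weights.sum()
        if total_w == 0 or total_reads == 0:
            counts = np.zeros(len(species), dtype=int)
        else:
            counts = rng.multinomial(total_reads, weights / total_w)
        rows[sample] = counts
    per_species = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    per_genus = per_species.T.groupby(genus_names).sum().T
    return per_genus.T  # genus x sample, matching the barcode-table convention


# ---------------------------------------------------------------------------
# pooled mitochondrial base counts
# ---------------------------------------------------------------------------


def make_pool_counts(
    cfg: PoolConfig,
    reference: Optional[str] = None,
    ref_id: str = "mito",
):
    """Per-site base counts from a pool of haplotypes, plus truth frequencies.

    Each individual contributes ``Poisson(depth * weight)`` observations per
    site of its haplotype base, substituted with probability ``error_rate``.
    Returns ``(SiteCounts, truth)`` where ``truth`` is a DataFrame (pos,
    true_alt_freq) over sites at which any haplotype differs from the
    reference; the true frequency is the summed weight of haplotypes
    carrying the most common non-reference base.
    """
    from .poolgen import SiteCounts  # local import to avoid a cycle

    ref = reference if reference is not None else cfg.haplotypes[0]
    length = len(cfg.haplotypes[0])
    if len(ref) != length:
        raise ValueError("reference length must match haplotype length")
    rng = np.random.default_rng(cfg.seed)
    hap_codes = np.stack([str_to_codes(h) for h in cfg.haplotypes])  # (k, L)
    ref_codes = str_to_codes(ref)
    counts = np.zeros((length, 4), dtype=np.int64)
    for i, w in enumerate(cfg.weights):
        cov = rng.poisson(cfg.depth * w, size=length)
        if cfg.error_rate > 0:
            errs = rng.binomial(cov, cfg.error_rate)
        else:
            errs = np.zeros(length, dtype=np.int64)
        correct = cov - errs
        np.add.at(counts, (np.arange(length), hap_codes[i]), correct)
        total_err = int(errs.sum())
        if total_err:
            # each error lands uniformly on one of the three other bases
            offsets = rng.integers(1, 4, size=total_err)
            sites = np.repeat(np.arange(length), errs)
            err_base = (hap_codes[i][sites] + offsets) % 4
            np.add.at(counts, (sites, err_base), 1)

    weights = np.asarray(cfg.weights)
    truth_rows = []
    for pos in np.nonzero((hap_codes != ref_codes).any(axis=0))[0]:
        alt_weight = np.zeros(4)
        for b in range(4):
            if b == ref_codes[pos]:
                continue
            alt_weight[b] = weights[hap_codes[:, pos] == b].sum()
        truth_rows.append({"pos": int(pos) + 1, "true_alt_freq": float(alt_weight.max())})
    truth = pd.DataFrame(truth_rows, columns=["pos", "true_alt_freq"])
    site_counts = SiteCounts(
        ref_id=ref_id,
        pos=np.arange(1, length + 1),
        counts=counts,
        ref_base=np.array([BASES[c] for c in ref_codes]),
    )
    return site_counts, truth
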