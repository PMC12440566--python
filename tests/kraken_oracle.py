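"""Brute-force reference classifier used as an independent oracle.

Enumerates every k-mer/species set explicitly, computes LCAs as the deepest
common node of root paths, and scores every root-to-leaf path by summing
hits along it. Deliberately naive: no shared code with the package's
classifier beyond the taxonomy container it checks against.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def canon(kmer):
    r = rc(kmer)
    return kmer if kmer < r else r


def oracle_kmer_species(genomes, k):
    """Map canonical k-mer -> set of species whose genome contains it."""
    table = {}
    for sid, seq in genomes.items():
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if set(window) <= set("ACGT"):
                table.setdefault(canon(window), set()).add(sid)
    return table


def paths_from_tree(tree):
    """species id -> root..species path, plus the full node->path map."""
    node_paths = {nid: tree.ancestors(nid) for nid in tree.depth_first()}
    return node_paths


def common_ancestor(paths):
    """Deepest node shared by all given root paths."""
    first = paths[0]
    n = min(len(p) for p in paths)
    deepest = first[0]
    for i in range(n):
        if all(p[i] == first[i] for p in paths):
            deepest = first[i]
        else:
            break
    return deepest


def oracle_classify(read, kmer_species, node_paths, tree, k):
    """Classify one read by exhaustive path scoring; None if no hits."""
    if len(read) < k:
        return None
    hits = {}
    for i in range(len(read) - k + 1):
        window = read[i : i + k]
        if not set(window) <= set("ACGT"):
            continue
        species = kmer_species.get(canon(window))
        if not species:
            continue
        taxon = (
            next(iter(species))
            if len(species) == 1
            else common_ancestor([node_paths[s] for s in species])
        )
        hits[taxon] = hits.get(taxon, 0) + 1
    if not hits:
        return None
    leaves = tree.ids_at_rank("species")
    scores = {}
    for leaf in leaves:
        scores[leaf] = sum(hits.get(node, 0) for node in node_paths[leaf])
    best = max(scores.values())
    if best == 0:
        return None
    tied = sorted(leaf for leaf, s in scores.items() if s == best)
    if len(tied) == 1:
        return tied[0]
    return common_ancestor([node_paths[leaf] for leaf in tied])
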