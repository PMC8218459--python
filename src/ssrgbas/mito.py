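"""Mitochondrial (COI) haplotype analyses.

Given a pre-aligned set of equal-length mitochondrial sequences with a
population map, this module collapses identical sequences into haplotypes,
computes raw p-distances with pairwise deletion of gap/ambiguous columns,
builds a statistical-parsimony haplotype network at the 95% connection limit
(single-mutation edges, inferred intermediate nodes, disconnected components
beyond the limit), reconstructs a bootstrap-supported UPGMA tree, and
estimates haplotype-frequency FST between populations with permutation tests.

The parsimony connection limit is the largest number of mutational steps j
for which the probability that j observed differences reflect exactly j
substitutions (no multiple hits anywhere in the alignment) is at least the
confidence level.  The probability model is a Jukes-Cantor finite-sites one:
the per-site substitution count is Poisson with mean d, the JC-corrected
divergence for j differences over L sites; a differing site is parsimonious
when it was hit exactly once and an identical site when it was not hit at
all, giving

    P(j, L) = [d e^{-d} / p]^j * [e^{-d} / (1 - p)]^(L-j),   p = j / L,
    d = -(3/4) ln(1 - 4 p / 3).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Alignment",
    "HaplotypeSet",
    "collapse_haplotypes",
    "p_distance_matrix",
    "parsimony_probability",
    "parsimony_connection_limit",
    "build_parsimony_network",
    "upgma_tree",
    "UpgmaNode",
    "upgma_with_bootstrap",
    "haplotype_pairwise_fst",
    "read_alignment_fasta",
]

_MISSING = {"N", "-", "?"}


@dataclass
class Alignment:
    ids: list
    sequences: list
    pop_map: dict

    def __post_init__(self):
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("alignment sequences must share one length")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


def read_alignment_fasta(fasta_path, pop_map: Mapping[str, str]) -> Alignment:
    from Bio import SeqIO

    ids, seqs = [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return Alignment(ids, seqs, dict(pop_map))


@dataclass
class HaplotypeSet:
    """Unique sequences H1..Hk with frequencies and population counts."""

    ids: list                  # haplotype ids in first-occurrence order
    sequences: dict            # haplotype id -> sequence
    frequencies: dict          # haplotype id -> total count
    pop_counts: dict           # haplotype id -> {population: count}
    members: dict              # haplotype id -> list of sequence ids
    seq_pops: dict = field(default_factory=dict)  # sequence id -> population

    @property
    def n_haplotypes(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        pops = sorted({p for d in self.pop_counts.values() for p in d})
        rows = []
        for h in self.ids:
            row = {"haplotype": h, "frequency": self.frequencies[h]}
            for p in pops:
                row[p] = self.pop_counts[h].get(p, 0)
            rows.append(row)
        return pd.DataFrame(rows)


def collapse_haplotypes(alignment: Alignment,
                        wildcard_missing: bool = False) -> HaplotypeSet:
    """Collapse identical sequences into haplotypes (ids in input order).

    By default identity is strict character equality (an N differs from an A),
    the conservative behaviour needed to keep distinct haplotypes apart;
    ``wildcard_missing=True`` lets N/- match any base, greedily merging each
    sequence into the first compatible haplotype.
    """
    if not alignment.sequences:
        raise ValueError("empty alignment")
    seq_of = {}
    order = []
    members = defaultdict(list)
    for sid, seq in zip(alignment.ids, alignment.sequences):
        key = None
        if wildcard_missing:
            for h, hseq in seq_of.items():
                if _compatible(seq, hseq):
                    key = h
                    break
        else:
            for h, hseq in seq_of.items():
                if seq == hseq:
                    key = h
                    break
        if key is None:
            key = f"H{len(order) + 1}"
            order.append(key)
            seq_of[key] = seq
        members[key].append(sid)
    freqs = {h: len(members[h]) for h in order}
    pop_counts = {h: dict(Counter(alignment.pop_map[s] for s in members[h]))
                  for h in order}
    return HaplotypeSet(ids=order, sequences=seq_of, frequencies=freqs,
                        pop_counts=pop_counts, members=dict(members),
                        seq_pops=dict(alignment.pop_map))


def _compatible(a: str, b: str) -> bool:
    return all(x == y or x in _MISSING or y in _MISSING for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# distances


def p_distance_matrix(sequences, ids=None, percent: bool = True):
    """Raw p-distances with pairwise deletion of gap/ambiguous columns.

    ``sequences`` is a list of equal-length strings or a
    :class:`HaplotypeSet`.  Per pair, positions where either sequence carries
    N/-/? are excluded from the denominator; a pair with no comparable site is
    NaN.  Returns a DataFrame (percent by default).
    """
    if isinstance(sequences, HaplotypeSet):
        ids = sequences.ids
        seqs = [sequences.sequences[h] for h in ids]
    else:
        seqs = list(sequences)
        ids = list(ids) if ids is not None else [f"S{i+1}" for i in range(len(seqs))]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diffs = comp = 0
            for x, y in zip(seqs[i], seqs[j]):
                if x in _MISSING or y in _MISSING:
                    continue
                comp += 1
                if x != y:
                    diffs += 1
            d = diffs / comp if comp else np.nan
            D[i, j] = D[j, i] = d
    if percent:
        D = D * 100.0
    return pd.DataFrame(D, index=ids, columns=ids)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


# ---------------------------------------------------------------------------
# statistical parsimony


def parsimony_probability(j: int, seq_length: int) -> float:
    """Probability that j observed differences equal j true steps.

    Finite-sites Jukes-Cantor hit model (see module docstring).  Returns 0
    when the JC correction is undefined (j/L >= 3/4).
    """
    if j == 0:
        return 1.0
    L = seq_length
    p = j / L
    if p >= 0.75:
        return 0.0
    d = -0.75 * math.log1p(-4.0 * p / 3.0)
    per_diff = d * math.exp(-d) / p
    per_same = math.exp(-d) / (1.0 - p)
    return (per_diff ** j) * (per_same ** (L - j))


def parsimony_connection_limit(seq_length: int, alpha: float = 0.95) -> int:
    """Largest step count whose probability of parsimony is >= alpha.

    The limit never drops below 1: single-step connections are parsimonious
    by construction.  ``alpha`` must lie in (0, 1).
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    limit = 1
    for j in range(2, seq_length + 1):
        if parsimony_probability(j, seq_length) >= alpha:
            limit = j
        else:
            break
    return limit


def build_parsimony_network(hapset: HaplotypeSet, limit: int):
    """Statistical-parsimony haplotype network as a networkx graph.

    Clusters are agglomerated greedily in increasing-distance order; joining
    two haplotypes d steps apart inserts d-1 inferred intermediate nodes
    (mutated sites realized in ascending position order).  Pairs whose
    distance exceeds ``limit`` are never joined directly, so the graph may
    stay disconnected.  Ties break on the lexicographically smallest
    haplotype-id pair, making the result input-order independent.

    Node attributes: ``observed`` (bool), ``frequency``, ``sequence``.
    """
    import networkx as nx

    if limit < 1:
        raise ValueError("limit must be >= 1")
    G = nx.Graph()
    for h in hapset.ids:
        G.add_node(h, observed=True, frequency=hapset.frequencies[h],
                   sequence=hapset.sequences[h])
    pairs = []
    for i, a in enumerate(hapset.ids):
        for b in hapset.ids[i + 1:]:
            d = _hamming(hapset.sequences[a], hapset.sequences[b])
            lo, hi = sorted((a, b))
            pairs.append((d, lo, hi))
    pairs.sort()
    n_inferred = 0
    for d, a, b in pairs:
        if d > limit:
            continue
        if d == 0:
            continue
        try:
            import networkx as nx
            span = nx.shortest_path_length(G, a, b)
            if span <= d:
                continue
        except nx.NetworkXNoPath:
            pass
        # realize a path mutating differing sites in ascending position order
        sa, sb = hapset.sequences[a], hapset.sequences[b]
        sites = [i for i, (x, y) in enumerate(zip(sa, sb)) if x != y]
        prev = a
        seq = list(sa)
        for step, site in enumerate(sites):
            seq[site] = sb[site]
            if step == len(sites) - 1:
                node = b
            else:
                n_inferred += 1
                node = f"i{n_inferred}"
                G.add_node(node, observed=False, frequency=0,
                           sequence="".join(seq))
            G.add_edge(prev, node)
            prev = node
    return G


# ---------------------------------------------------------------------------
# UPGMA with bootstrap


@dataclass
class UpgmaNode:
    """Binary UPGMA tree node; leaves carry a name, internals a height."""

    name: Optional[str] = None
    height: float = 0.0
    children: tuple = ()
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset:
        if self.is_leaf:
            return frozenset([self.name])
        out = frozenset()
        for c in self.children:
            out |= c.leaves()
        return out

    def newick(self, with_support: bool = True) -> str:
        return self._nwk(parent_height=None, with_support=with_support) + ";"

    def _nwk(self, parent_height, with_support):
        if self.is_leaf:
            label = self.name
        else:
            inner = ",".join(c._nwk(self.height, with_support)
                             for c in self.children)
            sup = ""
            if with_support and self.support is not None:
                sup = f"{self.support:g}"
            label = f"({inner}){sup}"
        if parent_height is None:
            return label
        return f"{label}:{parent_height - self.height:g}"


def upgma_tree(D, ids: Optional[Sequence[str]] = None) -> UpgmaNode:
    """Arithmetic-mean agglomerative (UPGMA) tree from a distance matrix.

    Ties between candidate merges break on the smallest pair of cluster ids
    (the smallest leaf name within each cluster), giving a deterministic
    topology.  Node heights are half the merge distance, so an ultrametric
    input is reproduced exactly.
    """
    if isinstance(D, pd.DataFrame):
        ids = list(D.index)
        M = D.values.astype(float)
    else:
        M = np.asarray(D, dtype=float)
        if ids is None:
            ids = [f"S{i+1}" for i in range(M.shape[0])]
    if not np.allclose(M, M.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    clusters = {i: UpgmaNode(name=ids[i]) for i in range(len(ids))}
    sizes = {i: 1 for i in range(len(ids))}
    label = {i: ids[i] for i in range(len(ids))}  # smallest leaf name
    dist = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dist[(i, j)] = M[i, j]
    next_id = len(ids)
    while len(clusters) > 1:
        best = min(dist.items(),
                   key=lambda kv: (kv[1], min(label[kv[0][0]], label[kv[0][1]]),
                                   max(label[kv[0][0]], label[kv[0][1]])))
        (i, j), d = best
        node = UpgmaNode(height=d / 2.0,
                         children=(clusters[i], clusters[j]))
        merged = next_id
        next_id += 1
        new_size = sizes[i] + sizes[j]
        new_dists = {}
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            new_dists[k] = (sizes[i] * dik + sizes[j] * djk) / new_size
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        del clusters[i], clusters[j], sizes[i], sizes[j]
        clusters[merged] = node
        sizes[merged] = new_size
        label[merged] = min(label[i], label[j])
        for k, v in new_dists.items():
            dist[(min(k, merged), max(k, merged))] = v
    return next(iter(clusters.values()))


def _bipartitions(node: UpgmaNode, all_leaves: frozenset) -> set:
    parts = set()

    def walk(n):
        if n.is_leaf:
            return
        lv = n.leaves()
        if 1 < len(lv) < len(all_leaves):
            parts.add(lv)
        for c in n.children:
            walk(c)

    walk(node)
    return parts


def upgma_with_bootstrap(alignment_or_hapset, n_bootstrap: int = 1000,
                         seed: int = 0, percent: bool = True):
    """UPGMA tree of haplotypes with column-resampling bootstrap supports.

    Distances are raw p-distances.  Each replicate resamples alignment
    columns with replacement, recomputes the distance matrix and tree, and
    counts recovered bipartitions; supports are attached to internal nodes as
    percentages of replicates.
    """
    if isinstance(alignment_or_hapset, HaplotypeSet):
        ids = alignment_or_hapset.ids
        seqs = [alignment_or_hapset.sequences[h] for h in ids]
    else:
        ids = alignment_or_hapset.ids
        seqs = list(alignment_or_hapset.sequences)
    D = p_distance_matrix(seqs, ids, percent=percent)
    tree = upgma_tree(D)
    if n_bootstrap <= 0:
        return tree
    rng = np.random.default_rng(seed)
    L = len(seqs[0])
    arr = np.array([list(s) for s in seqs])
    counts = Counter()
    all_leaves = frozenset(ids)
    for _ in range(n_bootstrap):
        cols = rng.integers(0, L, size=L)
        boot_seqs = ["".join(row) for row in arr[:, cols]]
        Db = p_distance_matrix(boot_seqs, ids, percent=percent)
        bt = upgma_tree(Db)
        for part in _bipartitions(bt, all_leaves):
            counts[part] += 1

    def attach(n):
        if n.is_leaf:
            return
        lv = n.leaves()
        if 1 < len(lv) < len(all_leaves):
            n.support = 100.0 * counts.get(lv, 0) / n_bootstrap
        for c in n.children:
            attach(c)

    attach(tree)
    return tree


# ---------------------------------------------------------------------------
# haplotype-frequency FST


def haplotype_pairwise_fst(hapset: HaplotypeSet, n_perm: int = 1023,
                           seed: int = 0):
    """Pairwise haplotype-frequency FST = (H_T - H_S) / H_T with permutations.

    H_S is the mean within-population haplotype heterozygosity of the pair
    and H_T the pooled heterozygosity.  Permutations shuffle sequences
    between the two populations.  Populations with fewer than two sequences
    give NaN entries.
    """
    pops = sorted({p for d in hapset.pop_counts.values() for p in d})
    hap_of_seq = {}
    for h, sids in hapset.members.items():
        for sid in sids:
            hap_of_seq[sid] = h
    pop_of_seq = {s: hapset.seq_pops[s] for s in hap_of_seq}
    k = len(pops)
    fst = pd.DataFrame(np.zeros((k, k)), index=pops, columns=pops)
    pvals = pd.DataFrame(np.ones((k, k)), index=pops, columns=pops)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = pops[i], pops[j]
            seqs_a = [s for s, p in pop_of_seq.items() if p == a]
            seqs_b = [s for s, p in pop_of_seq.items() if p == b]
            if len(seqs_a) < 2 or len(seqs_b) < 2:
                fst.iloc[i, j] = fst.iloc[j, i] = np.nan
                pvals.iloc[i, j] = pvals.iloc[j, i] = np.nan
                continue
            haps = np.array([hap_of_seq[s] for s in seqs_a + seqs_b])
            na = len(seqs_a)
            obs = _freq_fst(haps[:na], haps[na:])
            fst.iloc[i, j] = fst.iloc[j, i] = obs
            if n_perm:
                hits = 0
                for _ in range(n_perm):
                    perm = rng.permutation(haps)
                    if _freq_fst(perm[:na], perm[na:]) >= obs - 1e-12:
                        hits += 1
                p = (hits + 1) / (n_perm + 1)
                pvals.iloc[i, j] = pvals.iloc[j, i] = p
    return fst, pvals


def _heterozygosity(haps) -> float:
    counts = Counter(haps)
    n = len(haps)
    return 1.0 - sum((c / n) ** 2 for c in counts.values())


def _freq_fst(haps_a, haps_b) -> float:
    hs = 0.5 * (_heterozygosity(haps_a) + _heterozygosity(haps_b))
    ht = _heterozygosity(list(haps_a) + list(haps_b))
    return (ht - hs) / ht if ht > 0 else 0.0
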