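"""Independent oracles and small builders shared by the test modules.

Everything here deliberately re-derives results from first principles
(exhaustive enumeration, naive loops, closed forms) so the package code
paths are checked against code that does not share their logic.
"""

from __future__ import annotations

import math
from itertools import permutations

import dendropy
import numpy as np

BASES = "ACGT"

# ----------------------------------------------------------- genetic code

_CODON_TABLE_RAW = """
TTT F TTC F TTA L TTG L CTT L CTC L CTA L CTG L
ATT I ATC I ATA I ATG M GTT V GTC V GTA V GTG V
TCT S TCC S TCA S TCG S CCT P CCC P CCA P CCG P
ACT T ACC T ACA T ACG T GCT A GCC A GCA A GCG A
TAT Y TAC Y TAA * TAG * CAT H CAC H CAA Q CAG Q
AAT N AAC N AAA K AAG K GAT D GAC D GAA E GAG E
TGT C TGC C TGA * TGG W CGT R CGC R CGA R CGG R
AGT S AGC S AGA R AGG R GGT G GGC G GGA G GGG G
"""
_toks = _CODON_TABLE_RAW.split()
CODE = {_toks[i]: _toks[i + 1] for i in range(0, len(_toks), 2)}
STOPS = {c for c, aa in CODE.items() if aa == "*"}


def ng86_brute(codons_a: list[str], codons_b: list[str]):
    """Naive per-codon NG86 counter: returns (S, N, Sd, Nd)."""
    def syn_sites(codon):
        total = 0.0
        for pos in range(3):
            for base in BASES:
                if base == codon[pos]:
                    continue
                mut = codon[:pos] + base + codon[pos + 1:]
                if mut not in STOPS and CODE[mut] == CODE[codon]:
                    total += 1.0 / 3.0
        return total

    S = 0.5 * (sum(syn_sites(c) for c in codons_a)
               + sum(syn_sites(c) for c in codons_b))
    N = 3.0 * len(codons_a) - S
    Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        diff = [i for i in range(3) if ca[i] != cb[i]]
        if not diff:
            continue
        ok_paths, bad_paths = [], []
        for order in permutations(diff):
            cur = ca
            sd = nd = 0
            stopped = False
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if nxt in STOPS:
                    stopped = True
                if (nxt not in STOPS and cur not in STOPS
                        and CODE[nxt] == CODE[cur]):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            (bad_paths if stopped else ok_paths).append((sd, nd))
        paths = ok_paths if ok_paths else bad_paths
        Sd += sum(p[0] for p in paths) / len(paths)
        Nd += sum(p[1] for p in paths) / len(paths)
    return S, N, Sd, Nd


def random_codons(rng: np.random.Generator, n: int) -> list[str]:
    pool = sorted(set(CODE) - STOPS)
    return [pool[i] for i in rng.integers(0, len(pool), size=n)]


# ------------------------------------------------------------ hypergeom

def hypergeom_tail_enum(k: int, N: int, K: int, n: int) -> float:
    """Exact upper tail P(X >= k) by direct enumeration."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


# ------------------------------------------------------------ trees

def random_binary_tree(n_taxa: int, rng: np.random.Generator
                       ) -> tuple[dendropy.Tree, list[str]]:
    """Random unrooted binary tree with positive branch lengths."""
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        node.edge.length = float(rng.uniform(0.05, 1.0))
        nodes.append(node)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.05, 1.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [x for idx, x in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    root = dendropy.Node()
    for x in nodes:
        root.add_child(x)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree, labels


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    tns = t1.taxon_namespace
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"),
                          schema="newick", taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"),
                          schema="newick", taxon_namespace=tns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


# ----------------------------------------------------------- chains

def longest_chain_bruteforce(matches: list[tuple], max_gap: int):
    """Longest strictly monotone chain by an independent memoized DP over
    (match, orientation)."""
    best_len = 0
    for sign in (1, -1):
        order = sorted(matches, key=lambda m: (m[0], sign * m[1]))
        n = len(order)
        memo = [1] * n
        for i in range(n):
            for j in range(i):
                if (order[j][0] < order[i][0]
                        and sign * order[j][1] < sign * order[i][1]
                        and order[i][0] - order[j][0] <= max_gap
                        and abs(order[i][1] - order[j][1]) <= max_gap):
                    memo[i] = max(memo[i], memo[j] + 1)
        if n:
            best_len = max(best_len, max(memo))
    return best_len


def is_valid_chain(pairs_ranked: list[tuple[int, int]], max_gap: int
                   ) -> bool:
    ra = [p[0] for p in pairs_ranked]
    rb = [p[1] for p in pairs_ranked]
    inc_a = all(x < y and y - x <= max_gap for x, y in zip(ra, ra[1:]))
    inc_b = all(x < y and y - x <= max_gap for x, y in zip(rb, rb[1:]))
    dec_b = all(x > y and x - y <= max_gap for x, y in zip(rb, rb[1:]))
    return inc_a and (inc_b or dec_b)


# -------------------------------------------------------- duplication

def classify_bruteforce(genes: dict[str, tuple[str, int]],
                        pairs: set[tuple[str, str]],
                        block_genes: set[str],
                        proximal_max_gap: int = 19) -> dict[str, str]:
    """Independent rule-by-rule duplicate classifier."""
    out = {}
    for g, (chrom, rank) in genes.items():
        labels = {"singleton"}
        partners = {b if a == g else a for a, b in pairs if g in (a, b)}
        if partners:
            labels.add("dispersed")
        for o in partners:
            oc, orank = genes[o]
            if oc == chrom:
                gap = abs(rank - orank)
                if gap == 1:
                    labels.add("tandem")
                elif 2 <= gap <= proximal_max_gap:
                    labels.add("proximal")
        if g in block_genes:
            labels.add("wgd_segmental")
        for cls in ("wgd_segmental", "tandem", "proximal", "dispersed",
                    "singleton"):
            if cls in labels:
                out[g] = cls
                break
    return out
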