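"""Independent reference implementations used only to check the package.

Everything here is written from the mathematical definition, separately from
the implementation under test: a recursive memoized semi-global aligner, a
random additive tree generator with exact path-length distances, and
brute-force bipartition extraction for Robinson--Foulds comparison.
"""

from __future__ import annotations

import itertools
import random
from functools import lru_cache

_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def _compat(x: str, y: str) -> bool:
    return bool(_IUPAC_SETS[x] & _IUPAC_SETS[y])


def oracle_identity(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Recursive memoized semi-global identity: the shorter sequence aligns
    end to end, terminal gaps on the longer are free and excluded.

    Returns (identity_percent, aligned_columns).  Traceback preference:
    diagonal, then up (consume the contained sequence), then left; the
    endpoint is the smallest-index maximum on the final row.
    """
    if (len(a), a) > (len(b), b):
        a, b = b, a
    m, n = len(a), len(b)

    @lru_cache(maxsize=None)
    def score(i, j):
        if i == 0:
            return 0
        if j == 0:
            return i * gap
        s = match if _compat(a[i - 1], b[j - 1]) else mismatch
        return max(score(i - 1, j - 1) + s, score(i - 1, j) + gap,
                   score(i, j - 1) + gap)

    end_j = 0
    best = score(m, 0)
    for j in range(1, n + 1):
        if score(m, j) > best:
            best = score(m, j)
            end_j = j
    matches = columns = 0
    i, j = m, end_j
    while i > 0:
        if j == 0:
            columns += 1
            i -= 1
            continue
        s = match if _compat(a[i - 1], b[j - 1]) else mismatch
        if score(i, j) == score(i - 1, j - 1) + s:
            columns += 1
            matches += s == match
            i, j = i - 1, j - 1
        elif score(i, j) == score(i - 1, j) + gap:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return (100.0 * matches / columns if columns else 0.0), columns


# ---------------------------------------------------------------------------
# Trees


def random_additive_tree(labels, rng: random.Random, min_bl=0.05, max_bl=1.0):
    """Random binary tree over ``labels`` with its exact additive distances.

    Returns (newick_string, dist) where dist maps frozenset({a, b}) to the
    path length between tips a and b.
    """
    nodes = [(lbl, [(lbl, 0.0)]) for lbl in labels]
    dist: dict[frozenset, float] = {}
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        nwk_j, tips_j = nodes.pop(j)
        nwk_i, tips_i = nodes.pop(i)
        bi = rng.uniform(min_bl, max_bl)
        bj = rng.uniform(min_bl, max_bl)
        for la, da in tips_i:
            for lb, db in tips_j:
                dist[frozenset((la, lb))] = da + bi + db + bj
        merged = [(l, d + bi) for l, d in tips_i] + [(l, d + bj) for l, d in tips_j]
        nodes.append((f"({nwk_i}:{bi:.6f},{nwk_j}:{bj:.6f})", merged))
    return nodes[0][0] + ";", dist


def random_topology_newick(labels, rng: random.Random) -> str:
    """Random binary topology without branch lengths."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def _parse_simple_newick(text: str):
    """Minimal parser for the newick strings produced above (no quoting)."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse():
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children = [parse()]
            while text[pos] == ",":
                pos += 1
                children.append(parse())
            assert text[pos] == ")"
            pos += 1
            if pos < len(text) and text[pos] == ":":  # skip length
                pos += 1
                while pos < len(text) and text[pos] not in ",()":
                    pos += 1
            return tuple(children)
        start = pos
        while pos < len(text) and text[pos] not in ":,()":
            pos += 1
        name = text[start:pos]
        if pos < len(text) and text[pos] == ":":
            pos += 1
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
        return name

    return parse()


def oracle_bipartitions(newick: str) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree by brute force.

    Each split is canonicalized as the side not containing the overall
    smallest tip label.
    """
    root = _parse_simple_newick(newick)

    def tips(node):
        if isinstance(node, tuple):
            return [t for child in node for t in tips(child)]
        return [node]

    all_tips = sorted(tips(root))
    anchor = all_tips[0]
    full = frozenset(all_tips)
    out: set[frozenset] = set()

    def walk(node):
        if not isinstance(node, tuple):
            return
        for child in node:
            side = frozenset(tips(child))
            if anchor in side:
                side = full - side
            if 2 <= len(side) <= len(all_tips) - 2:
                out.add(side)
            walk(child)

    walk(root)
    return out


def oracle_rf(newick1: str, newick2: str) -> int:
    b1, b2 = oracle_bipartitions(newick1), oracle_bipartitions(newick2)
    return len(b1 ^ b2)
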