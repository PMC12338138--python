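"""Phylogenetic congruence between the 16S and amoA marker trees.

The clade-transfer approach is only valid if the two markers tell the same
evolutionary story for the paired references.  This module restricts both
trees to the shared pairs, measures topological agreement with the
Robinson--Foulds bipartition distance, and checks whether every amoA-defined
clade forms a monophyletic group in each tree (reporting an impurity
fraction when it does not).  When externally inferred trees are not
available, neighbor-joining trees built from pairwise-alignment distances
serve as desk-scale surrogates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .classify import global_identity
from .formats import SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CongruenceReport",
    "p_distance_matrix",
    "nj_tree",
    "prune_to_shared",
    "robinson_foulds",
    "bipartitions",
    "clade_monophyly",
    "congruence_report",
]


@dataclass
class CladeStatus:
    monophyletic_a: bool
    monophyletic_b: bool
    impurity_a: float
    impurity_b: float


@dataclass
class CongruenceReport:
    shared_pairs: int
    rf_distance: int
    rf_max: int
    per_clade: dict[str, CladeStatus]

    @property
    def normalized_rf(self) -> float:
        return self.rf_distance / self.rf_max if self.rf_max > 0 else 0.0

    @property
    def mean_impurity(self) -> float:
        if not self.per_clade:
            return 0.0
        vals = [s.impurity_a + s.impurity_b for s in self.per_clade.values()]
        return float(np.mean(vals)) / 2

    def to_rows(self) -> list[dict]:
        rows = []
        for clade, s in sorted(self.per_clade.items()):
            rows.append({
                "clade": clade,
                "monophyletic_16s": s.monophyletic_a,
                "monophyletic_amoa": s.monophyletic_b,
                "impurity_16s": round(s.impurity_a, 6),
                "impurity_amoa": round(s.impurity_b, 6),
            })
        return rows


# ---------------------------------------------------------------------------
# Distances


def p_distance_matrix(seqs: Sequence[SequenceRecord], mode: str = "pairwise_align"
                      ) -> tuple[np.ndarray, list[str]]:
    """Symmetric matrix of pairwise distances in [0, 1].

    ``pairwise_align`` uses the semi-global aligner (distance =
    1 - identity/100); ``aligned_columns`` expects pre-aligned equal-length
    sequences and counts mismatching columns over columns where both have a
    residue.
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    labels = [s.id for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    if mode == "pairwise_align":
        for i in range(n):
            for j in range(i + 1, n):
                ident, _ = global_identity(seqs[i].seq, seqs[j].seq)
                D[i, j] = D[j, i] = 1.0 - ident / 100.0
    elif mode == "aligned_columns":
        lengths = {len(s.seq) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("aligned_columns mode requires equal-length sequences")
        arrs = [np.frombuffer(s.seq.encode(), dtype=np.uint8) for s in seqs]
        gap = ord("-")
        for i in range(n):
            for j in range(i + 1, n):
                both = (arrs[i] != gap) & (arrs[j] != gap)
                cols = int(both.sum())
                if cols == 0:
                    raise ValueError(f"no shared columns between {labels[i]} and {labels[j]}")
                mism = int((arrs[i][both] != arrs[j][both]).sum())
                D[i, j] = D[j, i] = mism / cols
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return D, labels


# ---------------------------------------------------------------------------
# Neighbor joining


def _check_distance_matrix(D: np.ndarray) -> None:
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distance matrix must be non-negative")


def nj_tree(D: np.ndarray, labels: Sequence[str]) -> TreeNode:
    """Saitou--Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the pair whose contained tip labels
    sort smallest.  Negative branch lengths are clamped to zero and the
    total clamped deficit logged.  The returned tree is unrooted (root of
    degree 3 for > 3 taxa).
    """
    D = np.asarray(D, dtype=float)
    _check_distance_matrix(D)
    n = D.shape[0]
    if n != len(labels):
        raise ValueError("labels must match matrix size")
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes = [TreeNode(name=lbl) for lbl in labels]
    # Deterministic tie-break key: smallest tip label within each subtree.
    keys = [str(lbl) for lbl in labels]
    D = D.copy()
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while n > 3:
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                if Q[i, j] <= qmin + 1e-12:
                    pair_key = tuple(sorted((keys[i], keys[j])))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, i, j)
        _, i, j = best
        li = clamp(0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2)))
        lj = clamp(D[i, j] - (0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        Dn = np.zeros((n - 1, n - 1))
        Dn[: n - 2, : n - 2] = D[np.ix_(keep, keep)]
        Dn[n - 2, : n - 2] = Dn[: n - 2, n - 2] = dnew[keep]
        D = Dn
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        n -= 1

    # Join the last three nodes on a central (unrooted) vertex.
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = clamp(0.5 * (d01 + d02 - d12))
    l1 = clamp(0.5 * (d01 + d12 - d02))
    l2 = clamp(0.5 * (d02 + d12 - d01))
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = ln
    root = TreeNode(children=list(nodes))
    if deficit > 0:
        logger.info("neighbor joining clamped %.6g of negative branch length", deficit)
    return root


# ---------------------------------------------------------------------------
# Robinson--Foulds


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the (unrooted) tree.

    Each is canonicalized as the side *not* containing the lexicographically
    smallest tip, so identical splits compare equal across rootings.
    """
    tips = sorted(tip.name for tip in tree.tips())
    tipset = frozenset(tips)
    anchor = tips[0]
    n = len(tips)
    out: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = tipset - side
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> tuple[int, int]:
    """Unnormalized RF distance and its maximum for these two trees.

    ``rf`` is the size of the symmetric difference of the non-trivial
    bipartition sets; ``rf_max`` is the total number of internal edges of
    both trees (well-defined for multifurcating trees).
    """
    tips1 = {t.name for t in t1.tips()}
    tips2 = {t.name for t in t2.tips()}
    if tips1 != tips2:
        raise ValueError(
            f"trees have different tip sets ({len(tips1 - tips2)} only in first, "
            f"{len(tips2 - tips1)} only in second)"
        )
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2), len(b1) + len(b2)


# ---------------------------------------------------------------------------
# Shared-pair pruning and monophyly


def prune_to_shared(tree_a: TreeNode, tree_b: TreeNode,
                    pairing: Mapping[str, str]) -> tuple[TreeNode, TreeNode]:
    """Restrict both trees to paired tips present in both, relabeled to the
    pair id (the tree-A tip name)."""
    values = list(pairing.values())
    if len(set(pairing)) != len(values) or len(set(values)) != len(values):
        raise ValueError("pairing must be injective in both directions")
    tips_a = {t.name for t in tree_a.tips()}
    tips_b = {t.name for t in tree_b.tips()}
    shared = {a: b for a, b in pairing.items() if a in tips_a and b in tips_b}
    dropped = set(pairing) - set(shared)
    if dropped:
        logger.warning("dropping %d pair(s) with tips absent from a tree: %s",
                       len(dropped), sorted(dropped))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared pairs between the trees")
    pa = tree_a.shear(list(shared.keys()))
    pb = tree_b.shear(list(shared.values()))
    back = {b: a for a, b in shared.items()}
    for tip in pb.tips():
        tip.name = back[tip.name]
    return pa, pb


def clade_monophyly(tree: TreeNode, clade_of: Mapping[str, str]
                    ) -> dict[str, tuple[bool, float]]:
    """Monophyly and impurity of each clade on an unrooted tree.

    A clade is monophyletic iff some edge (or a single leaf) separates
    exactly its tips.  Impurity is the smallest foreign-tip fraction over
    all bipartition sides containing the clade (0 iff monophyletic).
    """
    tips = [t.name for t in tree.tips()]
    unmapped = [t for t in tips if t not in clade_of]
    if unmapped:
        raise KeyError(f"tips missing from clade mapping: {sorted(unmapped)}")
    tipset = frozenset(tips)
    # All bipartition sides, trivial ones included (single leaves and the
    # full tip set), from both sides of every edge.
    sides: set[frozenset[str]] = {tipset}
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) if not node.is_tip() \
            else frozenset([node.name])
        sides.add(side)
        sides.add(tipset - side)
    clades: dict[str, set[str]] = {}
    for tip in tips:
        clades.setdefault(clade_of[tip], set()).add(tip)
    out = {}
    for clade, members in clades.items():
        impurity = 1.0
        for side in sides:
            if members <= side:
                impurity = min(impurity, (len(side) - len(members)) / len(side))
        out[clade] = (impurity == 0.0, impurity)
    return out


def congruence_report(tree_16s: TreeNode, tree_amoa: TreeNode,
                      pairing: Mapping[str, str],
                      clade_of: Mapping[str, str]) -> CongruenceReport:
    """Full congruence check between the two marker trees.

    ``clade_of`` maps pair ids (tree-16S tip names) to amoA clade labels.
    """
    pa, pb = prune_to_shared(tree_16s, tree_amoa, pairing)
    rf, rf_max = robinson_foulds(pa, pb)
    mono_a = clade_monophyly(pa, clade_of)
    mono_b = clade_monophyly(pb, clade_of)
    per_clade = {
        clade: CladeStatus(
            monophyletic_a=mono_a[clade][0],
            monophyletic_b=mono_b[clade][0],
            impurity_a=mono_a[clade][1],
            impurity_b=mono_b[clade][1],
        )
        for clade in mono_a
    }
    return CongruenceReport(
        shared_pairs=len(list(pa.tips())),
        rf_distance=rf,
        rf_max=rf_max,
        per_clade=per_clade,
    )


def write_report(report: CongruenceReport, path) -> None:
    import pandas as pd

    df = pd.DataFrame(report.to_rows())
    with open(path, "w") as fh:
        fh.write(f"# shared_pairs\t{report.shared_pairs}\n")
        fh.write(f"# rf_distance\t{report.rf_distance}\n")
        fh.write(f"# rf_max\t{report.rf_max}\n")
        fh.write(f"# normalized_rf\t{report.normalized_rf:.6f}\n")
        df.to_csv(fh, sep="\t", index=False)
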