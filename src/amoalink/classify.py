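"""UCLUST-style consensus taxonomy assignment of 16S amplicons.

A query is aligned semi-globally against candidate references: the shorter
sequence aligns end to end while the overhangs of the longer one are free,
so a short amplicon pays nothing for covering only part of a full-length
gene yet cannot shrink the alignment to a deceptively identical fragment.  References at >= ``min_identity``
percent identity are hits; the ``max_accepts`` best hits vote rank by rank,
and the taxonomy is truncated at the first rank where the leading label's
fraction of hits fails the consensus threshold.  With the defaults
(identity >= 90%, consensus fraction strictly > 0.51, at least 3 hits) this
mirrors the consensus assigner commonly used for transferring clade labels
onto short amplicons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .formats import SequenceRecord, TaxMap, TaxonomyLabel, reverse_complement

__all__ = [
    "ClassifierParams",
    "Hit",
    "Assignment",
    "global_identity",
    "kmer_prefilter",
    "search_hits",
    "consensus_taxonomy",
    "classify_queries",
    "Classifier",
]


@dataclass(frozen=True)
class ClassifierParams:
    """Tunables of the consensus assigner.

    min_identity
        Percent identity a reference must reach to count as a hit.  The
        default 90.0 is inclusive (identity >= 90 is a hit); set
        ``strict_identity`` for a strictly-greater reading.
    min_consensus_fraction
        A rank is assigned only when the leading label's fraction of hits is
        strictly greater than this (default 0.51).
    max_accepts
        Number of top-identity hits that vote (default 3).
    min_hits
        Minimum number of accepted hits before any assignment is attempted
        (default 3).
    kmer_size, prefilter_candidates
        Shared-k-mer prefilter: only the ``prefilter_candidates`` references
        sharing the most canonical k-mers with the query are aligned.  The
        prefilter is heuristic; ``use_prefilter=False`` restores exhaustive
        search.
    """

    min_identity: float = 90.0
    min_consensus_fraction: float = 0.51
    max_accepts: int = 3
    min_hits: int = 3
    kmer_size: int = 8
    prefilter_candidates: int = 32
    use_prefilter: bool = True
    strict_identity: bool = False
    match: int = 1
    mismatch: int = -1
    gap: int = -2

    def __post_init__(self):
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if not 0.5 <= self.min_consensus_fraction < 1:
            raise ValueError("min_consensus_fraction must be in [0.5, 1)")
        if self.max_accepts < 1 or self.min_hits < 1:
            raise ValueError("max_accepts and min_hits must be >= 1")
        if self.kmer_size < 4:
            raise ValueError("kmer_size must be >= 4")


@dataclass(frozen=True)
class Hit:
    query_id: str
    ref_id: str
    identity: float
    aligned_columns: int


@dataclass(frozen=True)
class Assignment:
    """Per-query classification result, possibly truncated above clade rank."""

    query_id: str
    taxonomy: TaxonomyLabel | None
    depth: int
    confidence: float
    n_hits: int
    hit_ids: tuple[str, ...]

    @property
    def assigned(self) -> bool:
        return self.depth > 0


# ---------------------------------------------------------------------------
# Pairwise alignment

# 4-bit nucleotide encoding; IUPAC codes carry the union of their bases and
# any non-empty intersection scores as a match.
_CODE = np.zeros(256, dtype=np.uint8)
for _ch, _bits in {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}.items():
    _CODE[ord(_ch)] = _bits
    _CODE[ord(_ch.lower())] = _bits


def encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 0).any():
        bad = sorted({c for c, code in zip(seq, arr) if code == 0})
        raise ValueError(f"cannot align characters {bad}")
    return arr


@njit(cache=False)
def _semi_global(a, b, match, mismatch, gap):  # pragma: no cover - numba
    """Align ``a`` end-to-end against ``b`` with free terminal gaps on ``b``.

    Containment semi-global alignment: every residue of ``a`` is part of the
    alignment, while any prefix/suffix of ``b`` may hang off unpenalized (and
    is excluded from the columns).  Callers put the shorter sequence in ``a``.
    """
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    for i in range(1, m + 1):
        H[i, 0] = i * gap
    for i in range(1, m + 1):
        ai = a[i - 1]
        row = H[i]
        prev = H[i - 1]
        for j in range(1, n + 1):
            s = match if (ai & b[j - 1]) != 0 else mismatch
            best = prev[j - 1] + s
            t = prev[j] + gap
            if t > best:
                best = t
            t = row[j - 1] + gap
            if t > best:
                best = t
            row[j] = best
    # Endpoint: best cell on the last row (the rest of b is a free
    # terminal gap); ties resolve to the smallest j.
    bj = 0
    bs = H[m, 0]
    for j in range(1, n + 1):
        if H[m, j] > bs:
            bs = H[m, j]
            bj = j
    # Traceback, preferring diagonal, then up (consume a), then left.
    matches = 0
    columns = 0
    i, j = m, bj
    while i > 0:
        if j == 0:
            columns += 1
            i -= 1
            continue
        s = match if (a[i - 1] & b[j - 1]) != 0 else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            columns += 1
            if s == match:
                matches += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + gap:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return bs, matches, columns, 0, m, j, bj


def global_identity(a: str, b: str,
                    scoring: tuple[int, int, int] = (1, -1, -2)) -> tuple[float, int]:
    """Percent identity of the optimal semi-global alignment of two sequences.

    The shorter sequence aligns end to end; terminal gaps on the longer
    sequence are free and excluded from the alignment columns, while
    internal gap columns count.  Identity is ``100 * matches / columns``.
    Ties in the traceback are broken deterministically (diagonal, then up,
    then left), and the argument pair is ordered canonically first so the
    result is exactly symmetric.

    Returns ``(identity_percent, aligned_columns)``.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if (len(a), a) > (len(b), b):
        a, b = b, a
    match, mismatch, gap = scoring
    _, matches, columns, *_ = _semi_global(encode(a), encode(b), match, mismatch, gap)
    if columns == 0:
        return 0.0, 0
    return 100.0 * matches / columns, columns


def align_span(a: str, b: str,
               scoring: tuple[int, int, int] = (1, -1, -2)
               ) -> tuple[float, int, tuple[int, int], tuple[int, int]]:
    """Like :func:`global_identity` but also report the aligned spans.

    Returns ``(identity, columns, (a_start, a_end), (b_start, b_end))`` with
    half-open 0-based spans on each input.  Argument order is preserved;
    internally the shorter sequence is the contained one.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    match, mismatch, gap = scoring
    swap = (len(a), a) > (len(b), b)
    x, y = (b, a) if swap else (a, b)
    _, matches, columns, x0, x1, y0, y1 = _semi_global(
        encode(x), encode(y), match, mismatch, gap
    )
    ident = 100.0 * matches / columns if columns else 0.0
    if swap:
        return ident, columns, (y0, y1), (x0, x1)
    return ident, columns, (x0, x1), (y0, y1)


# ---------------------------------------------------------------------------
# K-mer prefilter


def _canonical_kmers(seq: str, k: int) -> set[str]:
    rc = reverse_complement(seq)
    n = len(seq)
    out = set()
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        rev = rc[n - k - i : n - i]
        out.add(fwd if fwd <= rev else rev)
    return out


def kmer_prefilter(query: SequenceRecord, refs: Sequence[SequenceRecord],
                   k: int = 8, top_m: int = 32,
                   ref_kmers: dict[str, set[str]] | None = None) -> list[str]:
    """Rank references by shared canonical k-mers with the query.

    Returns at most ``top_m`` reference ids, best first; references sharing
    no k-mer are dropped.  Ties break on ref_id.  ``ref_kmers`` may carry
    precomputed reference k-mer sets.
    """
    if not refs:
        raise ValueError("reference set is empty")
    qk = _canonical_kmers(query.seq, k)
    scored = []
    for ref in refs:
        rk = ref_kmers[ref.id] if ref_kmers is not None else _canonical_kmers(ref.seq, k)
        shared = len(qk & rk)
        if shared > 0:
            scored.append((-shared, ref.id))
    scored.sort()
    return [ref_id for _, ref_id in scored[:top_m]]


# ---------------------------------------------------------------------------
# Search + consensus


class Classifier:
    """Search index over a reference set with its taxonomy map."""

    def __init__(self, refs: Sequence[SequenceRecord], taxmap: TaxMap,
                 params: ClassifierParams | None = None,
                 undersupported: set[str] | None = None):
        self.refs = list(refs)
        self.taxmap = taxmap
        self.params = params or ClassifierParams()
        self.undersupported = undersupported or set()
        self._by_id = {r.id: r for r in self.refs}
        self._kmers = {
            r.id: _canonical_kmers(r.seq, self.params.kmer_size) for r in self.refs
        }

    def search_hits(self, query: SequenceRecord) -> list[Hit]:
        p = self.params
        if p.use_prefilter:
            candidate_ids = kmer_prefilter(
                query, self.refs, p.kmer_size, p.prefilter_candidates, self._kmers
            )
        else:
            candidate_ids = [r.id for r in self.refs]
        hits = []
        for ref_id in candidate_ids:
            ref = self._by_id[ref_id]
            ident, cols = global_identity(
                query.seq, ref.seq, (p.match, p.mismatch, p.gap)
            )
            ok = ident > p.min_identity if p.strict_identity else ident >= p.min_identity
            if ok and cols >= 1:
                hits.append(Hit(query.id, ref_id, ident, cols))
        hits.sort(key=lambda h: (-h.identity, h.ref_id))
        return hits[: p.max_accepts]

    def consensus(self, hits: Sequence[Hit], query_id: str = "") -> Assignment:
        return consensus_taxonomy(hits, self.taxmap, self.params,
                                  undersupported=self.undersupported,
                                  query_id=query_id)

    def classify(self, queries: Iterable[SequenceRecord]) -> list[Assignment]:
        return [self.consensus(self.search_hits(q), q.id) for q in queries]


def search_hits(query: SequenceRecord, refs: Sequence[SequenceRecord],
                params: ClassifierParams | None = None) -> list[Hit]:
    """Hits of one query against a reference collection (convenience form)."""
    params = params or ClassifierParams()
    dummy_map = TaxMap({r.id: TaxonomyLabel(("x",)) for r in refs})
    return Classifier(refs, dummy_map, params).search_hits(query)


def consensus_taxonomy(hits: Sequence[Hit], taxmap: TaxMap,
                       params: ClassifierParams | None = None,
                       undersupported: set[str] | None = None,
                       allow_undersupported: bool = False,
                       query_id: str = "") -> Assignment:
    """Per-rank majority consensus over the taxonomies of the hits.

    Walking from the highest rank down, a rank prefix is fixed only when the
    most frequent prefix at that depth exceeds ``min_consensus_fraction``
    (strictly).  Counting whole prefixes keeps the assigned path internally
    consistent.  Fewer than ``min_hits`` hits means Unassigned.
    """
    params = params or ClassifierParams()
    if hits:
        query_id = hits[0].query_id
    hit_ids = tuple(h.ref_id for h in hits)
    missing = [h.ref_id for h in hits if h.ref_id not in taxmap]
    if missing:
        raise KeyError(f"hit reference(s) missing from taxonomy map: {missing}")
    if len(hits) < params.min_hits:
        return Assignment(query_id, None, 0, 0.0, len(hits), hit_ids)

    paths = [taxmap[h.ref_id].ranks for h in hits]
    n = len(paths)
    fixed: tuple[str, ...] = ()
    confidence = 0.0
    depth = 0
    while True:
        d = depth + 1
        counts: dict[tuple[str, ...], int] = {}
        for p in paths:
            if len(p) >= d and p[:depth] == fixed:
                pref = p[:d]
                counts[pref] = counts.get(pref, 0) + 1
        if not counts:
            break
        best_pref, best_count = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        frac = best_count / n
        if frac > params.min_consensus_fraction:
            fixed = best_pref
            confidence = frac
            depth = d
        else:
            break
    if depth == 0:
        return Assignment(query_id, None, 0, 0.0, n, hit_ids)
    if (undersupported and not allow_undersupported
            and fixed[-1] in undersupported and depth >= 2):
        # Clade-level call backed only by an under-supported clade: truncate
        # to the parent rank, keeping the parent's own supporting fraction.
        parent = fixed[:-1]
        support = sum(1 for p in paths if p[: depth - 1] == parent)
        return Assignment(query_id, TaxonomyLabel(parent), depth - 1,
                          support / n, n, hit_ids)
    return Assignment(query_id, TaxonomyLabel(fixed), depth, confidence, n, hit_ids)


def classify_queries(queries: Sequence[SequenceRecord],
                     refs: Sequence[SequenceRecord], taxmap: TaxMap,
                     params: ClassifierParams | None = None,
                     undersupported: set[str] | None = None,
                     allow_undersupported: bool = False) -> list[Assignment]:
    """Classify queries in input order against a reference set.

    ``undersupported`` names clades with too few references; clade-level
    calls into them are truncated to the parent rank unless
    ``allow_undersupported`` is set.
    """
    if not queries:
        raise ValueError("query collection is empty")
    if not refs:
        return [Assignment(q.id, None, 0, 0.0, 0, ()) for q in queries]
    clf = Classifier(refs, taxmap, params,
                     undersupported=None if allow_undersupported else undersupported)
    return clf.classify(queries)


def write_assignments(assignments: Sequence[Assignment], path) -> None:
    """TSV report: query_id, taxonomy, depth, confidence, n_hits, hit_ids."""
    with open(path, "w") as fh:
        fh.write("query_id\ttaxonomy\tdepth\tconfidence\tn_hits\thit_ids\n")
        for a in assignments:
            tax = a.taxonomy.canonical if a.taxonomy else "Unassigned"
            fh.write(
                f"{a.query_id}\t{tax}\t{a.depth}\t{a.confidence:.4f}"
                f"\t{a.n_hits}\t{','.join(a.hit_ids)}\n"
            )


def read_assignments(path) -> list[Assignment]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            q, tax, depth, conf, n_hits, hit_ids = line.rstrip("\n").split("\t")
            label = None if tax == "Unassigned" else TaxonomyLabel.parse(tax)
            out.append(Assignment(q, label, int(depth), float(conf), int(n_hits),
                                  tuple(h for h in hit_ids.split(",") if h)))
    return out
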