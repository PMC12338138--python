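"""Construction and validation of the paired 16S--amoA reference database.

Genomes and long contigs are screened for both marker genes with a seeded
similarity search; only sequences carrying the 16S rRNA gene *and* amoA
yield a reference record, because the amoA copy is what lets the clade
label be transferred onto the 16S gene.  Records flagged as contaminants or
symbiont-derived are removed, byte-identical 16S sequences are collapsed,
and every clade's reference support is checked against the minimum the
consensus classifier needs (3 by default).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .classify import Classifier, ClassifierParams, align_span
from .formats import (
    SequenceRecord,
    TaxMap,
    TaxonomyLabel,
    write_fasta,
    write_taxmap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerHit",
    "ReferenceRecord",
    "PairedDatabase",
    "locate_marker",
    "pair_genomes",
    "assign_clade_to_records",
    "filter_flagged",
    "validate_database",
    "dereplicate",
    "build_database",
]

SSU = "SSU"
AMOA = "AMOA"

#: Minimum extracted gene lengths; fragments shorter than this are likely
#: partial operon copies or spurious matches.
DEFAULT_MIN_LENGTH = {SSU: 800, AMOA: 400}

_ANCHOR_K = 16


@dataclass(frozen=True)
class MarkerHit:
    """One located marker gene on a genome, 1-based inclusive coordinates."""

    genome_id: str
    marker: str
    start: int
    end: int
    strand: str
    identity_to_seed: float
    seed_id: str

    def __post_init__(self):
        if self.marker not in (SSU, AMOA):
            raise ValueError(f"unknown marker {self.marker!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError("hit interval must satisfy 1 <= start <= end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReferenceRecord:
    """A genome-derived pair of 16S and amoA genes with a clade taxonomy."""

    ref_id: str
    genome_id: str
    ssu: SequenceRecord | None
    amoa: SequenceRecord | None
    taxonomy: TaxonomyLabel | None = None
    flags: set[str] = field(default_factory=set)

    @property
    def exportable(self) -> bool:
        return (
            self.ssu is not None
            and self.taxonomy is not None
            and not ({"contaminant", "symbiont", "unassignable"} & self.flags)
        )

    @property
    def clade(self) -> str | None:
        return self.taxonomy.ranks[-1] if self.taxonomy else None


@dataclass
class PairedDatabase:
    """Validated collection of reference records, exportable as 16S FASTA +
    taxonomy map (and the paired amoA FASTA)."""

    records: list[ReferenceRecord]

    @property
    def exported(self) -> list[ReferenceRecord]:
        out = [r for r in self.records if r.exportable]
        ids = [r.ref_id for r in out]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate ref_id(s) in export: {sorted(dupes)}")
        return out

    @property
    def clade_support(self) -> dict[str, int]:
        return dict(Counter(r.clade for r in self.exported))

    def ssu_records(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(r.ref_id, r.ssu.seq, r.ssu.description)
            for r in self.exported
        ]

    def amoa_records(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(r.ref_id, r.amoa.seq, r.amoa.description)
            for r in self.exported
            if r.amoa is not None
        ]

    def taxmap(self) -> TaxMap:
        return TaxMap({r.ref_id: r.taxonomy for r in self.exported})

    def undersupported_clades(self, min_support: int = 3) -> set[str]:
        return {c for c, n in self.clade_support.items() if n < min_support}

    def export(self, outdir, *, prefix: str = "db") -> None:
        """Write 16S FASTA + taxonomy map + amoA FASTA under ``outdir``."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.ssu_records(), outdir / f"{prefix}_16s.fasta", allow_empty=True)
        write_taxmap(self.taxmap(), outdir / f"{prefix}_taxonomy.tsv")
        write_fasta(self.amoa_records(), outdir / f"{prefix}_amoa.fasta", allow_empty=True)


# ---------------------------------------------------------------------------
# Marker location


def _anchor_clusters(seed: str, target: str, k: int) -> list[tuple[int, int]]:
    """Clusters of exact shared-k-mer positions on the target (0-based)."""
    index: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        index.setdefault(target[i : i + k], []).append(i)
    positions = sorted(
        {p for i in range(len(seed) - k + 1) for p in index.get(seed[i : i + k], ())}
    )
    if not positions:
        return []
    clusters = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p - prev > len(seed):
            clusters.append((start, prev + k))
            start = p
        prev = p
    clusters.append((start, prev + k))
    return clusters


def locate_marker(genome: SequenceRecord, seeds: Sequence[SequenceRecord],
                  marker: str, min_identity: float = 80.0,
                  min_length: int | None = None,
                  scoring: tuple[int, int, int] = (1, -1, -2)) -> list[MarkerHit]:
    """Find copies of a marker gene on either strand of a genome.

    Seeds are anchored by exact shared 16-mers, each anchor cluster is
    extended by semi-global alignment of the seed against a padded window,
    and overlapping hits (>50% reciprocal overlap) collapse to the best one.
    Coordinates are reported 1-based inclusive on the forward strand.
    """
    if not seeds:
        raise ValueError("seed set is empty")
    if not 0 < min_identity <= 100:
        raise ValueError("min_identity must be in (0, 100]")
    if min_length is None:
        min_length = DEFAULT_MIN_LENGTH[marker]
    L = len(genome.seq)
    raw_hits: list[MarkerHit] = []
    for seed in seeds:
        pad = len(seed.seq) // 2 + 50
        for strand in "+-":
            target = genome.seq if strand == "+" else genome.reverse_complement().seq
            for c0, c1 in _anchor_clusters(seed.seq, target, _ANCHOR_K):
                w0 = max(0, c0 - pad)
                w1 = min(len(target), c1 + pad)
                window = target[w0:w1]
                ident, cols, _, (b0, b1) = align_span(seed.seq, window, scoring)
                if cols == 0 or ident < min_identity:
                    continue
                t0, t1 = w0 + b0, w0 + b1  # half-open on the search strand
                if strand == "+":
                    start, end = t0 + 1, t1
                else:
                    start, end = L - t1 + 1, L - t0
                if end - start + 1 < min_length:
                    continue
                raw_hits.append(
                    MarkerHit(genome.id, marker, start, end, strand, ident, seed.id)
                )
    return _collapse_overlaps(raw_hits)


def _collapse_overlaps(hits: list[MarkerHit]) -> list[MarkerHit]:
    """Collapse hits with >50% reciprocal overlap to the best-identity one."""
    order = sorted(
        hits, key=lambda h: (-h.identity_to_seed, -h.length, h.start, h.seed_id)
    )
    kept: list[MarkerHit] = []
    for h in order:
        redundant = False
        for k in kept:
            ov = min(h.end, k.end) - max(h.start, k.start) + 1
            if ov > 0 and ov > 0.5 * h.length and ov > 0.5 * k.length:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end))
    return kept


# ---------------------------------------------------------------------------
# Pairing and annotation


def _extract(genome: SequenceRecord, hit: MarkerHit) -> SequenceRecord:
    if hit.end > len(genome.seq):
        raise ValueError(
            f"hit {hit.start}..{hit.end} exceeds genome {genome.id} "
            f"length {len(genome.seq)}"
        )
    sub = genome.seq[hit.start - 1 : hit.end]
    rec = SequenceRecord(genome.id, sub, f"{hit.marker} {hit.start}..{hit.end} ({hit.strand})")
    return rec.reverse_complement() if hit.strand == "-" else rec


def pair_genomes(hits: Iterable[MarkerHit],
                 genomes: Sequence[SequenceRecord]) -> list[ReferenceRecord]:
    """Keep genomes with at least one hit of *each* marker and extract genes.

    When a genome carries multiple copies of a marker, the longest wins
    (ties: highest identity to seed, then lowest start).  Extracted genes
    are reported 5'->3' in gene orientation.
    """
    by_genome: dict[str, dict[str, list[MarkerHit]]] = {}
    genome_by_id = {g.id: g for g in genomes}
    for h in hits:
        if h.genome_id not in genome_by_id:
            raise KeyError(f"hit references unknown genome {h.genome_id!r}")
        by_genome.setdefault(h.genome_id, {}).setdefault(h.marker, []).append(h)
    records = []
    for genome in genomes:  # preserve input genome order
        markers = by_genome.get(genome.id, {})
        if SSU not in markers or AMOA not in markers:
            continue
        chosen = {}
        for marker in (SSU, AMOA):
            chosen[marker] = min(
                markers[marker],
                key=lambda h: (-h.length, -h.identity_to_seed, h.start),
            )
        records.append(
            ReferenceRecord(
                ref_id=genome.id,
                genome_id=genome.id,
                ssu=_extract(genome, chosen[SSU]),
                amoa=_extract(genome, chosen[AMOA]),
            )
        )
    return records


def assign_clade_to_records(records: Sequence[ReferenceRecord],
                            amoa_refs: Sequence[SequenceRecord],
                            amoa_taxmap: TaxMap,
                            params: ClassifierParams | None = None
                            ) -> list[ReferenceRecord]:
    """Set each record's taxonomy from its amoA gene via consensus assignment.

    Records whose amoA cannot be assigned are flagged ``unassignable`` and
    thereby excluded from export.  Records without an amoA sequence must be
    flagged ``environmental_16s_only`` (and must already carry a taxonomy).
    """
    missing = [r.id for r in amoa_refs if r.id not in amoa_taxmap]
    if missing:
        raise KeyError(f"amoA references missing from taxonomy map: {missing}")
    clf = Classifier(amoa_refs, amoa_taxmap, params)
    out = []
    for rec in records:
        if rec.amoa is None:
            if "environmental_16s_only" not in rec.flags:
                raise ValueError(
                    f"record {rec.ref_id} lacks an amoA sequence and is not "
                    "flagged environmental_16s_only"
                )
            out.append(rec)
            continue
        query = SequenceRecord(rec.ref_id, rec.amoa.seq)
        assignment = clf.consensus(clf.search_hits(query), query.id)
        new = replace(rec, flags=set(rec.flags))
        if assignment.assigned:
            new.taxonomy = assignment.taxonomy
        else:
            new.flags.add("unassignable")
            logger.warning("amoA of %s could not be assigned (n_hits=%d); excluded",
                           rec.ref_id, assignment.n_hits)
        out.append(new)
    return out


def filter_flagged(records: Sequence[ReferenceRecord],
                   flag_list: Iterable[str],
                   flag: str = "contaminant"
                   ) -> tuple[list[ReferenceRecord], list[ReferenceRecord]]:
    """Split records into (kept, removed) by a list of flagged ref_ids."""
    flagged = set(flag_list)
    present = {r.ref_id for r in records}
    for absent in sorted(flagged - present):
        logger.warning("flag-listed id %s not present in records", absent)
    kept, removed = [], []
    for r in records:
        if r.ref_id in flagged:
            r = replace(r, flags=set(r.flags) | {flag})
            removed.append(r)
        else:
            kept.append(r)
    logger.info("flag filter: %d kept, %d removed", len(kept), len(removed))
    return kept, removed


def validate_database(db: PairedDatabase, min_support: int = 3
                      ) -> list[tuple[str, int, bool]]:
    """Per-clade support report: (clade, n_records, under_supported).

    Export is never blocked, but the classifier refuses clade-level calls
    into under-supported clades unless explicitly overridden.
    """
    support = db.clade_support
    if not support:
        logger.warning("database has no exportable records")
    report = [
        (clade, n, n < min_support) for clade, n in sorted(support.items())
    ]
    for clade, n, flagged in report:
        if flagged:
            logger.warning("clade %s has only %d reference(s) (< %d)",
                           clade, n, min_support)
    return report


def dereplicate(records: Sequence[ReferenceRecord]
                ) -> tuple[list[ReferenceRecord], list[tuple[str, str]]]:
    """Collapse records with byte-identical 16S *and* identical taxonomy.

    The lexicographically smallest ref_id represents each group.  Identical
    sequences with different taxonomies are all kept and reported as
    conflicts ``(ref_id_a, ref_id_b)``.
    """
    groups: dict[tuple[str, str], list[ReferenceRecord]] = {}
    no_tax: list[ReferenceRecord] = []
    order: list[tuple[str, str]] = []
    for r in records:
        if r.ssu is None or r.taxonomy is None:
            no_tax.append(r)
            continue
        key = (r.ssu.seq, r.taxonomy.canonical)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(r)
    kept = [min(groups[key], key=lambda r: r.ref_id) for key in order]
    conflicts = []
    by_seq: dict[str, list[ReferenceRecord]] = {}
    for r in kept:
        by_seq.setdefault(r.ssu.seq, []).append(r)
    for same_seq in by_seq.values():
        for i in range(len(same_seq)):
            for j in range(i + 1, len(same_seq)):
                conflicts.append((same_seq[i].ref_id, same_seq[j].ref_id))
                logger.warning(
                    "identical 16S, conflicting taxonomy: %s (%s) vs %s (%s)",
                    same_seq[i].ref_id, same_seq[i].taxonomy,
                    same_seq[j].ref_id, same_seq[j].taxonomy,
                )
    return kept + no_tax, conflicts


# ---------------------------------------------------------------------------
# Pipeline


def build_database(genomes: Sequence[SequenceRecord],
                   ssu_seeds: Sequence[SequenceRecord],
                   amoa_seeds: Sequence[SequenceRecord],
                   amoa_refs: Sequence[SequenceRecord],
                   amoa_taxmap: TaxMap,
                   flag_ids: Iterable[str] = (),
                   external_records: Sequence[ReferenceRecord] = (),
                   locator_min_identity: float = 80.0,
                   min_genome_length: int = 2000,
                   params: ClassifierParams | None = None,
                   features: Iterable[MarkerHit] | None = None,
                   ) -> tuple[PairedDatabase, list[ReferenceRecord]]:
    """End-to-end database construction.

    Locates both markers in each genome (or takes precomputed ``features``),
    pairs genomes carrying both, transfers the amoA clade label, removes
    flag-listed records, dereplicates, and returns the database together
    with the removed records (the removal log).  ``external_records`` lets
    curated environmental 16S sequences be added to rescue clades with too
    few genome-derived references; they are never fetched automatically.
    """
    genomes = [g for g in genomes if len(g.seq) >= min_genome_length]
    if features is not None:
        hits = list(features)
    else:
        hits = []
        for g in genomes:
            hits.extend(locate_marker(g, ssu_seeds, SSU, locator_min_identity))
            hits.extend(locate_marker(g, amoa_seeds, AMOA, locator_min_identity))
    paired = pair_genomes(hits, genomes)
    annotated = assign_clade_to_records(paired, amoa_refs, amoa_taxmap, params)
    kept, removed = filter_flagged(annotated, flag_ids)
    kept = kept + list(external_records)
    kept, _conflicts = dereplicate(kept)
    db = PairedDatabase(kept)
    validate_database(db)
    return db, removed
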