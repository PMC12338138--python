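"""Readers and writers for every external representation the tool touches.

FASTA files carry reference genes and query amplicons; a two-column TSV
("taxonomy map") links each reference sequence id to a semicolon-separated
rank path ending in an amoA clade label (e.g. ``NS;NS-gamma``); trees travel
as newick.  Clade labels may be written with Greek letters (``NS-γ``) or
ASCII spellings (``NS-gamma``); internally everything is normalized to one
canonical ASCII form so that labels compare reliably across files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from skbio import TreeNode

__all__ = [
    "SequenceRecord",
    "TaxonomyLabel",
    "TaxMap",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_taxmap",
    "write_taxmap",
    "read_newick",
    "write_newick",
    "reverse_complement",
]


class FormatError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


# IUPAC nucleotide alphabet (after U->T normalization); '-' tolerated only
# in explicitly aligned input.
_IUPAC = set("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHV",
    "TGCANYRSWMKVHDB",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_seq(raw: str, *, allow_gaps: bool = False) -> str:
    seq = raw.upper().replace("U", "T")
    alphabet = _IUPAC | {"-"} if allow_gaps else _IUPAC
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"invalid nucleotide character(s): {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with a whitespace-free id.

    Sequences are stored uppercase with U converted to T, so RNA-deposited
    rRNA genes compare equal to their DNA form.  The description (anything
    after the first whitespace in a FASTA header) is preserved verbatim but
    never used as an identifier.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a non-empty token, got {self.id!r}")
        object.__setattr__(self, "seq", _normalize_seq(self.seq, allow_gaps=True))
        if len(self.seq.replace("-", "")) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, reverse_complement(self.seq), self.description)


# Greek letters appearing in AOA clade names and their ASCII spellings.
_GREEK_TO_ASCII = {
    "α": "alpha",
    "β": "beta",
    "γ": "gamma",
    "δ": "delta",
    "ε": "epsilon",
    "ζ": "zeta",
    "η": "eta",
}
_ASCII_TO_GREEK = {v: k for k, v in _GREEK_TO_ASCII.items()}


def _normalize_rank(rank: str) -> str:
    rank = rank.strip()
    for greek, ascii_name in _GREEK_TO_ASCII.items():
        rank = rank.replace(greek, ascii_name)
    return rank


@dataclass(frozen=True)
class TaxonomyLabel:
    """An ordered rank path, highest rank first (order, then amoA clade).

    The canonical text form joins ranks with ";" and spells Greek clade
    suffixes in ASCII (``NS;NS-gamma``).  Normalization is idempotent.
    """

    ranks: tuple[str, ...]

    def __post_init__(self):
        if not self.ranks:
            raise ValueError("taxonomy label needs at least one rank")
        norm = []
        for r in self.ranks:
            r = _normalize_rank(r)
            if not r:
                raise ValueError("empty rank name in taxonomy label")
            if ";" in r or "\t" in r:
                raise ValueError(f"rank name {r!r} contains a reserved separator")
            norm.append(r)
        object.__setattr__(self, "ranks", tuple(norm))

    @classmethod
    def parse(cls, text: str) -> "TaxonomyLabel":
        return cls(tuple(part for part in text.split(";")))

    @property
    def canonical(self) -> str:
        return ";".join(self.ranks)

    @property
    def depth(self) -> int:
        return len(self.ranks)

    def prefix(self, depth: int) -> "TaxonomyLabel":
        if not 1 <= depth <= len(self.ranks):
            raise ValueError(f"depth {depth} out of range for {self.canonical}")
        return TaxonomyLabel(self.ranks[:depth])

    def is_prefix_of(self, other: "TaxonomyLabel") -> bool:
        return self.ranks == other.ranks[: len(self.ranks)]

    def display(self, greek: bool = False) -> str:
        """Canonical text, optionally with Greek clade suffixes restored."""
        if not greek:
            return self.canonical
        ranks = []
        for r in self.ranks:
            for ascii_name, g in _ASCII_TO_GREEK.items():
                if r.endswith("-" + ascii_name):
                    r = r[: -len(ascii_name)] + g
                    break
            ranks.append(r)
        return ";".join(ranks)

    def __str__(self) -> str:
        return self.canonical


class TaxMap(Mapping[str, TaxonomyLabel]):
    """Mapping from sequence id to its :class:`TaxonomyLabel`."""

    def __init__(self, entries: Mapping[str, TaxonomyLabel] | Iterable[tuple[str, TaxonomyLabel]] = ()):
        self._entries: dict[str, TaxonomyLabel] = dict(entries)

    def __getitem__(self, key: str) -> TaxonomyLabel:
        return self._entries[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __repr__(self) -> str:
        return f"TaxMap({len(self._entries)} entries)"


# ---------------------------------------------------------------------------
# FASTA


def _fasta_structure_check(path) -> dict[int, int]:
    """Pre-scan a FASTA file for structural defects Bio.SeqIO glosses over.

    Returns a map from record index to the 1-based line number of its header,
    used for error reporting.
    """
    header_lines: dict[int, int] = {}
    n_records = 0
    last_header_line = None
    has_seq = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if not has_seq:
                    raise FormatError(
                        "header with no sequence before next header",
                        path, last_header_line,
                    )
                header_lines[n_records] = lineno
                last_header_line = lineno
                n_records += 1
                has_seq = False
            else:
                if last_header_line is None:
                    raise FormatError(
                        "sequence data before first '>' header", path, lineno
                    )
                has_seq = True
    if last_header_line is not None and not has_seq:
        raise FormatError("header with no sequence at end of file", path, last_header_line)
    return header_lines


def read_fasta(path, *, allow_gaps: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Records come back in file order.  Duplicate ids, headers without
    sequence, and stray text before the first header are rejected with the
    offending line number.
    """
    path = Path(path)
    header_lines = _fasta_structure_check(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        line = header_lines.get(idx)
        if rec.id in seen:
            raise FormatError(
                f"duplicate sequence id {rec.id!r} (first seen on line {seen[rec.id]})",
                path, line,
            )
        seen[rec.id] = line
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        try:
            records.append(SequenceRecord(rec.id, str(rec.seq), desc))
        except ValueError as exc:
            raise FormatError(str(exc), path, line) from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path, *, wrap: int | None = 80,
                allow_empty: bool = False) -> None:
    """Write records as FASTA; ``wrap`` is the line width (None = one line)."""
    records = list(records)
    if not records and not allow_empty:
        raise ValueError("refusing to write an empty FASTA (pass allow_empty=True)")
    if wrap is not None and wrap < 1:
        raise ValueError("wrap must be a positive integer or None")
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            if wrap is None:
                fh.write(rec.seq + "\n")
            else:
                for i in range(0, len(rec.seq), wrap):
                    fh.write(rec.seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Taxonomy map TSV


def read_taxmap(path) -> TaxMap:
    """Read a two-column TSV of sequence id -> semicolon-joined taxonomy."""
    path = Path(path)
    entries: dict[str, TaxonomyLabel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"expected 2 tab-separated columns, found {len(parts)}", path, lineno
                )
            seq_id, tax_text = parts[0].strip(), parts[1].strip()
            if not seq_id:
                raise FormatError("empty sequence id", path, lineno)
            if seq_id in entries:
                raise FormatError(f"duplicate id {seq_id!r}", path, lineno)
            if not tax_text:
                raise FormatError(f"empty taxonomy for id {seq_id!r}", path, lineno)
            try:
                entries[seq_id] = TaxonomyLabel.parse(tax_text)
            except ValueError as exc:
                raise FormatError(str(exc), path, lineno) from exc
    return TaxMap(entries)


def write_taxmap(taxmap: TaxMap, path) -> None:
    with open(path, "w") as fh:
        for seq_id in taxmap:
            fh.write(f"{seq_id}\t{taxmap[seq_id].canonical}\n")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path_or_handle) -> TreeNode:
    """Parse one newick statement into an (arbitrarily rooted) TreeNode.

    Quoted tip labels are supported; internal support values are retained as
    internal node names and ignored by every topology operation downstream.
    Duplicate tip labels are rejected.
    """
    if isinstance(path_or_handle, (str, Path)):
        handle = open(path_or_handle)
        close = True
    else:
        handle = path_or_handle
        close = False
    try:
        tree = TreeNode.read(handle, format="newick")
    finally:
        if close:
            handle.close()
    names = [tip.name for tip in tree.tips()]
    if any(n is None for n in names):
        raise FormatError("tree contains an unlabeled tip", getattr(handle, "name", None))
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise FormatError(f"duplicate tip label(s): {sorted(dupes)}", getattr(handle, "name", None))
    return tree


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        tree.write(fh, format="newick")


def newick_string(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()
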