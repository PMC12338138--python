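"""Synthetic paired-marker reference databases and amplicon queries.

The generator mimics the hierarchical structure of the ammonia-oxidizing
archaea: four orders (NC, NS, NT, NP), Greek-letter clades within each
order, and a handful of reference genomes per clade.  Both marker genes
(a full-length ~1.4 kb 16S rRNA gene and a ~600 bp amoA gene) evolve down
the *same* genealogy by independent per-site substitutions, which is what
makes the two marker trees congruent by construction.  Queries are ~250 bp
amplicons cut from a fixed window of a reference 16S gene (emulating a
515F/806R-type fragment) and mutated at a chosen per-site rate, with the
generating reference and clade recorded in a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .formats import SequenceRecord, TaxonomyLabel
from .pairdb import PairedDatabase, ReferenceRecord
from .classify import Assignment

__all__ = [
    "SimulationParams",
    "TruthTable",
    "evolve_sequence",
    "simulate_reference_set",
    "simulate_queries",
    "evaluate_classification",
]

_ORDER_NAMES = ("NC", "NS", "NT", "NP")
_GREEK = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta",
          "theta", "iota", "kappa", "lambda", "mu", "nu", "xi", "omicron",
          "pi", "rho", "sigma", "tau", "upsilon", "phi", "chi", "psi", "omega")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationParams:
    """Conditions of the synthetic study system.

    Divergences are per-site substitution probabilities along one branch of
    the descent hierarchy and must satisfy
    ``within_clade < between_clade < between_order``; the defaults (0.02 /
    0.10 / 0.20) keep same-clade references well above the classifier's 90%
    identity threshold while separating clades and orders clearly, which is
    the regime the real reference set occupies.
    """

    n_orders: int = 4
    clades_per_order: int = 3
    refs_per_clade: int = 4
    ssu_length: int = 1400
    amoa_length: int = 600
    between_order_divergence: float = 0.20
    between_clade_divergence: float = 0.10
    within_clade_divergence: float = 0.02
    amplicon_window: tuple[int, int] = (500, 250)
    query_mutation_rate: float = 0.02
    seed: int = 42
    break_congruence: bool = False
    indel_rate: float = 0.0

    def __post_init__(self):
        if not (0 <= self.within_clade_divergence
                < self.between_clade_divergence
                < self.between_order_divergence <= 0.75):
            raise ValueError(
                "divergences must satisfy 0 <= within_clade < between_clade "
                "<= between_order <= 0.75"
            )
        start, length = self.amplicon_window
        if not (0 <= start and start + length <= self.ssu_length):
            raise ValueError("amplicon window must fit inside the 16S gene")
        if not 1 <= self.n_orders <= len(_ORDER_NAMES) + 26:
            raise ValueError("n_orders out of range")
        if not 1 <= self.clades_per_order <= len(_GREEK):
            raise ValueError("clades_per_order out of range")


class TruthTable(dict):
    """query_id -> (source ref_id, true TaxonomyLabel)."""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("query_id\tsource_ref\ttaxonomy\n")
            for q, (ref, tax) in self.items():
                fh.write(f"{q}\t{ref}\t{tax.canonical}\n")

    @classmethod
    def read(cls, path) -> "TruthTable":
        out = cls()
        with open(path) as fh:
            fh.readline()
            for line in fh:
                q, ref, tax = line.rstrip("\n").split("\t")
                out[q] = (ref, TaxonomyLabel.parse(tax))
        return out


# ---------------------------------------------------------------------------
# Sequence evolution


def _evolve_arr(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability ``rate``, drawing
    the new base uniformly from the three alternatives."""
    if not 0 <= rate <= 0.75:
        raise ValueError("substitution rate must be in [0, 0.75]")
    out = arr.copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        # index of current base among ACGT, shifted by 1..3 (mod 4)
        cur = np.searchsorted(_BASES, out[hit])
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = _BASES[(cur + shift) % 4]
    return out


def evolve_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Point-substitution evolution of an A/C/G/T sequence (length preserved)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if not np.isin(arr, _BASES).all():
        raise ValueError("evolve_sequence requires an unambiguous A/C/G/T sequence")
    return _evolve_arr(arr, rate, rng).tobytes().decode("ascii")


def _apply_indels(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return arr
    keep = rng.random(arr.size) >= rate / 2
    arr = arr[keep]
    n_ins = rng.binomial(arr.size, rate / 2)
    if n_ins:
        pos = np.sort(rng.integers(0, arr.size + 1, size=n_ins))
        ins = _BASES[rng.integers(0, 4, size=n_ins)]
        arr = np.insert(arr, pos, ins)
    return arr


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _random_join_topology(n: int, rng: np.random.Generator):
    """Random binary genealogy over leaf indices 0..n-1, as nested tuples."""
    nodes: list = list(range(n))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append((left, right))
    return nodes[0]


def _evolve_down(topology, ancestor: np.ndarray, edge_rate: float,
                 rng: np.random.Generator, out: dict[int, np.ndarray]) -> None:
    node_seq = _evolve_arr(ancestor, edge_rate, rng)
    if isinstance(topology, int):
        out[topology] = node_seq
    else:
        left, right = topology
        _evolve_down(left, node_seq, edge_rate, rng, out)
        _evolve_down(right, node_seq, edge_rate, rng, out)


def _order_name(i: int) -> str:
    if i < len(_ORDER_NAMES):
        return _ORDER_NAMES[i]
    return f"O{i + 1}"


# ---------------------------------------------------------------------------
# Reference set


def simulate_reference_set(params: SimulationParams,
                           rng: np.random.Generator | None = None
                           ) -> tuple[PairedDatabase, dict[str, str]]:
    """Generate a clade-structured paired database with known genealogy.

    One random root per marker; order ancestors evolve from the root at the
    between-order rate, clade ancestors from order ancestors at the
    between-clade rate, and references descend from each clade ancestor
    along a random binary within-clade genealogy (shared by both markers)
    whose every edge carries half the within-clade rate.  Returns the
    database plus the ancestral sequences keyed by lineage.

    With ``break_congruence`` the amoA genes of the later half of the
    members of the first clades of the first two orders descend from the
    *other* clade's amoA ancestor, so the two marker trees genuinely
    disagree while the taxonomy labels still follow the 16S descent.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.break_congruence and params.n_orders < 2:
        raise ValueError("breaking congruence requires at least 2 orders")

    roots = {
        "ssu": _random_seq(params.ssu_length, rng),
        "amoa": _random_seq(params.amoa_length, rng),
    }
    ancestors: dict[str, str] = {
        f"root:{m}": s.tobytes().decode() for m, s in roots.items()
    }

    # Shared descent: draw the genealogical structure once, then realize
    # mutations independently per marker along identical branches.
    order_anc = {}
    clade_anc = {}
    clade_topologies = {}
    clade_ids = []
    for oi in range(params.n_orders):
        order = _order_name(oi)
        order_anc[order] = {
            m: _evolve_arr(roots[m], params.between_order_divergence, rng)
            for m in ("ssu", "amoa")
        }
        for m in ("ssu", "amoa"):
            ancestors[f"order:{order}:{m}"] = order_anc[order][m].tobytes().decode()
        for ci in range(params.clades_per_order):
            clade = f"{order}-{_GREEK[ci]}"
            clade_anc[clade] = {
                m: _evolve_arr(order_anc[order][m], params.between_clade_divergence, rng)
                for m in ("ssu", "amoa")
            }
            for m in ("ssu", "amoa"):
                ancestors[f"clade:{clade}:{m}"] = clade_anc[clade][m].tobytes().decode()
            clade_topologies[clade] = _random_join_topology(params.refs_per_clade, rng)
            clade_ids.append((order, clade))

    swapped: dict[str, str] = {}
    foreign_rng = None
    if params.break_congruence:
        a = f"{_order_name(0)}-{_GREEK[0]}"
        b = f"{_order_name(1)}-{_GREEK[0]}"
        swapped = {a: b, b: a}
        # separate stream so the clean sequences are identical to a
        # non-broken run with the same seed
        foreign_rng = rng.spawn(1)[0]

    records: list[ReferenceRecord] = []
    edge_rate = params.within_clade_divergence / 2
    for order, clade in clade_ids:
        tips: dict[str, dict[int, np.ndarray]] = {}
        for m in ("ssu", "amoa"):
            tips[m] = {}
            _evolve_down(clade_topologies[clade], clade_anc[clade][m],
                         edge_rate, rng, tips[m])
        if clade in swapped:
            # later half of this clade's members take the partner clade's
            # amoA ancestry, so the amoA tree splits the clade
            half = params.refs_per_clade // 2
            foreign: dict[int, np.ndarray] = {}
            _evolve_down(clade_topologies[clade], clade_anc[swapped[clade]]["amoa"],
                         edge_rate, foreign_rng, foreign)
            for idx in range(params.refs_per_clade - half, params.refs_per_clade):
                tips["amoa"][idx] = foreign[idx]
        taxonomy = TaxonomyLabel((order, clade))
        for idx in range(params.refs_per_clade):
            ref_id = f"{clade}.r{idx + 1}"
            ssu = SequenceRecord(ref_id, tips["ssu"][idx].tobytes().decode())
            amoa = SequenceRecord(ref_id, tips["amoa"][idx].tobytes().decode())
            records.append(ReferenceRecord(ref_id, ref_id, ssu, amoa, taxonomy))
    return PairedDatabase(records), ancestors


# ---------------------------------------------------------------------------
# Queries


def simulate_queries(db: PairedDatabase, params: SimulationParams,
                     n_queries: int, rng: np.random.Generator
                     ) -> tuple[list[SequenceRecord], TruthTable]:
    """Cut amplicons from random references and mutate them.

    Each query picks a reference uniformly at random, extracts the amplicon
    window from its 16S gene, and applies point substitutions at
    ``query_mutation_rate`` (plus optional indels at ``indel_rate``).
    """
    refs = db.exported
    if not refs:
        raise ValueError("database has no exportable records")
    start, length = params.amplicon_window
    queries = []
    truth = TruthTable()
    for qi in range(n_queries):
        ref = refs[int(rng.integers(0, len(refs)))]
        if start + length > len(ref.ssu.seq):
            raise ValueError(
                f"amplicon window {start}+{length} outside reference "
                f"{ref.ref_id} of length {len(ref.ssu.seq)}"
            )
        window = np.frombuffer(
            ref.ssu.seq[start : start + length].encode(), dtype=np.uint8
        )
        arr = _evolve_arr(window, params.query_mutation_rate, rng)
        arr = _apply_indels(arr, params.indel_rate, rng)
        qid = f"q{qi + 1:04d}"
        queries.append(SequenceRecord(qid, arr.tobytes().decode()))
        truth[qid] = (ref.ref_id, ref.taxonomy)
    return queries, truth


# ---------------------------------------------------------------------------
# Evaluation


def evaluate_classification(assignments: Sequence[Assignment],
                            truth: Mapping[str, tuple[str, TaxonomyLabel]]
                            ) -> dict:
    """Score assignments against the simulation truth.

    Reports the clade-level assignment rate, per-rank accuracy among the
    queries assigned at that rank (``None`` when nothing was assigned), and
    clade-by-clade confusion counts; unassigned queries are tracked
    separately.
    """
    missing = [a.query_id for a in assignments if a.query_id not in truth]
    if missing:
        raise KeyError(f"truth table missing query id(s): {missing}")
    n = len(assignments)
    max_depth = max((truth[a.query_id][1].depth for a in assignments), default=0)
    per_rank_correct = [0] * max_depth
    per_rank_assigned = [0] * max_depth
    confusion: dict[tuple[str, str], int] = {}
    n_unassigned = 0
    n_clade_assigned = 0
    for a in assignments:
        _, true_tax = truth[a.query_id]
        if not a.assigned:
            n_unassigned += 1
            confusion[(true_tax.ranks[-1], "Unassigned")] = (
                confusion.get((true_tax.ranks[-1], "Unassigned"), 0) + 1
            )
            continue
        if a.depth >= true_tax.depth:
            n_clade_assigned += 1
        for d in range(1, min(a.depth, true_tax.depth) + 1):
            per_rank_assigned[d - 1] += 1
            if a.taxonomy.ranks[d - 1] == true_tax.ranks[d - 1]:
                per_rank_correct[d - 1] += 1
        pred_clade = a.taxonomy.ranks[-1] if a.depth >= true_tax.depth else "truncated"
        key = (true_tax.ranks[-1], pred_clade)
        confusion[key] = confusion.get(key, 0) + 1
    accuracy = [
        (per_rank_correct[d] / per_rank_assigned[d]) if per_rank_assigned[d] else None
        for d in range(max_depth)
    ]
    return {
        "n_queries": n,
        "assignment_rate": n_clade_assigned / n if n else 0.0,
        "assigned_any_rate": (n - n_unassigned) / n if n else 0.0,
        "accuracy_per_rank": accuracy,
        "clade_accuracy": accuracy[-1] if accuracy else None,
        "n_unassigned": n_unassigned,
        "confusion": confusion,
    }


def write_metrics(metrics: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key in ("n_queries", "assignment_rate", "assigned_any_rate",
                    "clade_accuracy", "n_unassigned"):
            fh.write(f"{key}\t{metrics[key]}\n")
        for d, acc in enumerate(metrics["accuracy_per_rank"], start=1):
            fh.write(f"accuracy_rank_{d}\t{acc}\n")
        for (true_c, pred_c), count in sorted(metrics["confusion"].items()):
            fh.write(f"confusion:{true_c}->{pred_c}\t{count}\n")
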