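# Methods

## Scope and model

`amoalink` links two marker genes of ammonia-oxidizing archaea (AOA): the
16S rRNA gene, on which most amplicon surveys are based, and *amoA*, on
which the high-resolution clade taxonomy (orders NC/NS/NT/NP with
Greek-letter clades) is defined.  The link rests on one assumption — that
the two markers share their evolutionary history in AOA, so a clade defined
on one marker is a coherent group on the other.  The package makes the
assumption testable (the `congruence` module) rather than taking it on
faith.

## Pairwise identity

All similarity decisions reduce to one primitive: semi-global alignment
with unit match score, −1 mismatch, −2 linear gap.  The shorter sequence is
aligned end to end; any prefix/suffix of the longer sequence is a free
terminal gap and is excluded from the alignment columns, while internal gap
columns count.  Identity = 100 × matches / columns.  This containment form
is the right shape for a ~250 bp amplicon against a ~1.4 kb gene, and it is
deliberate that *both* ends of the shorter sequence are anchored: if
terminal gaps were free on both sequences symmetrically, the optimal
alignment for a divergent pair would collapse to a few perfectly matching
columns and report 100 % identity, flooding the classifier with spurious
hits.  IUPAC ambiguity codes match any compatible base and count as
matches.  Determinism: traceback ties prefer diagonal, then consuming the
contained sequence, then the container; tied endpoints resolve to the
smallest index; the argument pair is ordered canonically (length, then
lexicographic) before alignment so identity is exactly symmetric.  The
dynamic program runs as a numba kernel; an independently written memoized
recursion in the test suite checks it exactly.

## Consensus classification

Defaults mirror the thresholds commonly used when transferring clade labels
onto amplicons: a reference is a hit at identity ≥ 90 % (a strict-inequality
mode exists; at the fractions reachable with ≤ 3 hits the two readings
coincide), at most 3 top-identity hits are accepted, and no assignment is
attempted with fewer than 3 hits — consistent with requiring at least 3
references per clade in the database.  Consensus walks rank prefixes from
the top: a prefix is fixed only when its fraction of all hits is strictly
greater than 0.51, and counting whole prefixes keeps the reported path
internally consistent.  Hits are selected by identity with ties on
reference id, never by database order.  Clade-level calls into a clade with
fewer than `min_support` references are truncated to the parent rank unless
explicitly overridden.

The shared-k-mer prefilter (canonical 8-mers, top 32 candidates) is purely
an accelerator: it ranks references by the number of shared canonical
k-mers and the aligner then scores candidates in that order.  It is not
guaranteed to be lossless in adversarial cases, which is why exhaustive
search remains one flag away and the test suite demonstrates equality of
results on databases of the realistic size.

## Database construction

Marker genes are located by exact 16-mer anchoring of seed sequences on
both strands followed by semi-global extension of each anchor cluster in a
padded window; hits under 800 bp (16S) / 400 bp (*amoA*) or below 80 %
identity to the seed are dropped, and >50 % reciprocally overlapping hits
collapse to the best.  These locator thresholds are assumptions — permissive
enough for cross-order seeds on well-conserved markers, strict enough to
reject background — and externally annotated coordinates can bypass the
locator entirely via a feature TSV.  When a genome carries several copies
of a marker the longest is taken (draft assemblies often contain rRNA
fragments).  Only genomes with both markers yield a reference record; the
record's taxonomy is the consensus assignment of its *amoA* gene against a
labeled *amoA* reference set, and records whose *amoA* cannot be assigned
are excluded.  Flag-listed contaminant/symbiont records are removed with a
log; byte-identical 16S sequences with identical taxonomy dereplicate to
the lexicographically smallest id, while identical sequences with
conflicting taxonomy are all kept and reported.  Clades below 3 references
are reported, never silently dropped; curated environmental 16S-only
records can be added explicitly to rescue such clades (they are never
fetched automatically).  Coordinates are 1-based inclusive in all files and
half-open 0-based internally, converted in one place.

## Congruence

Both trees are restricted to the paired references, relabeled to pair ids,
with degree-2 nodes suppressed (branch lengths summed).  Robinson–Foulds is
the size of the symmetric difference of the non-trivial bipartition sets,
unnormalized and not halved; its maximum is the total internal-edge count
of both trees, which stays well-defined for multifurcations.  Monophyly is
evaluated on the unrooted tree: a clade is monophyletic iff some edge (or a
leaf, for singletons) separates exactly its tips, and impurity is the
smallest foreign-tip fraction over all bipartition sides containing the
clade.  When external maximum-likelihood trees are unavailable, the package
builds neighbor-joining surrogates from pairwise alignment distances
(1 − identity/100): standard Saitou–Nei with the Q criterion, ties broken
on the smallest contained tip label, negative branch lengths clamped to
zero with the deficit logged.  No numeric threshold separates "congruent"
from "incongruent"; the report is descriptive and the defaults leave that
judgement to the user.

## Synthetic data

The generator mirrors the hierarchical structure of the real reference set:
4 orders × 3 clades × 4 references by default, a 1,400 bp 16S gene and a
600 bp *amoA* gene per reference.  Sequences evolve by independent per-site
substitutions (uniform base at the root, substituted bases drawn uniformly
from the three alternatives): order ancestors at 0.20 per site from the
root, clade ancestors at 0.10 from their order, and references along a
random binary within-clade genealogy whose every edge carries 0.01.  The
within-clade genealogy is drawn once and shared by both markers — mutations
are realized independently per marker along identical branches — which is
what makes the two marker trees congruent by construction and their
internal within-clade edges resolvable rather than arbitrary.  The default
rates keep same-clade references above the 90 % identity threshold
(within-clade pairwise divergence ≤ ~5 %) and other clades far below it
(≥ ~18 %), the regime the curated database occupies.  Queries are 250 bp
windows starting at position 500 of a uniformly chosen reference's 16S gene
(a 515F/806R-like fragment), mutated at 2 % per site by default; a truth
table records the generating reference and clade.  Substitution-only
evolution keeps truth identities binomially predictable; an optional indel
rate exercises gap handling.  The `break_congruence` flag re-derives the
*amoA* genes of the later half of two clades (one in each of the first two
orders) from the partner clade's *amoA* ancestor, drawn from a spawned RNG
stream so every other sequence is identical to the intact run — a controlled
violation for testing the congruence report's sensitivity.

What the generator does **not** emulate: indels and rate heterogeneity
across sites or lineages, chimeras, sequencing error profiles, compositional
bias, and incomplete reference databases (every query descends from a
reference that is present).  Passing recovery tests therefore shows the
pipeline is correct and well-calibrated under clade-structured divergence,
not that real ASVs from clades missing in the database would be handled
gracefully — on real data such ASVs should appear as order-level or
unassigned calls, as the undefined-clade behavior of the truncating
consensus intends.

## Problem sizes and numerical choices

Tests and the acceptance script run the simulation at the default
4×3×4 = 48 references with 100 queries per run, five seeds per condition;
oracle comparisons use 200 random pairs ≤ 30 bp (alignment), 50 random
6–10-tip additive trees (neighbor joining) and 100 random 8-tip tree pairs
(Robinson–Foulds) — sizes at which the independent oracles are exhaustive
yet the statistics are stable.  Everything downstream of a seed is
deterministic: the only randomness enters through `numpy` generators seeded
from the command line, simulation is reproducible byte for byte, and the
classifier, database build and congruence modules contain no randomness at
all.

## Known limitations

The marker locator is a similarity search, not a gene caller: it needs at
least one seed within ~20 % identity of the target and exact 16-mer
anchors, so highly divergent novel orders could be missed.  Consensus
confidence is a hit fraction, not a bootstrap probability.  Robinson–Foulds
saturates quickly for large noisy trees; the per-clade impurity is the more
interpretable signal there.  The neighbor-joining surrogate is a desk-scale
stand-in: for publication-grade congruence figures, externally inferred
maximum-likelihood trees should be supplied as newick.
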