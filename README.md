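# amoalink

Transfer the fine-grained *amoA*-clade taxonomy of ammonia-oxidizing archaea
(AOA) onto 16S rRNA gene amplicons.

## The problem

AOA (class *Nitrososphaeria*) drive ammonia oxidation in soils, sediments
and the ocean.  Their highest-resolution taxonomy is defined on the *amoA*
gene (ammonia monooxygenase subunit A): four orders — *Ca.* Nitrosocaldales
(NC), *Nitrososphaerales* (NS), *Ca.* Nitrosotaleales (NT), *Nitrosopumilales*
(NP) — each subdivided into Greek-letter clades (NS-γ, NS-δ, NP-η, …) with
distinct ecophysiologies.  Most microbiome surveys, however, sequence only
the 16S rRNA gene, on which these clades were never defined.

Because the *amoA* and 16S phylogenies of AOA are congruent, the clade
labels can be carried across markers.  `amoalink` implements that transfer
end to end:

1. **pairdb** — build a paired-marker reference database: screen genomes and
   contigs for co-occurring 16S and *amoA* genes, label each pair with the
   *amoA* clade of its *amoA* copy, remove flagged contaminant/symbiont
   records, dereplicate, and check that every clade keeps at least 3
   references.
2. **classify** — assign query 16S amplicons (ASVs) to clades with a
   UCLUST-style consensus assigner over the paired database.
3. **congruence** — validate the transfer by comparing neighbor-joining (or
   externally inferred) trees of the two markers: Robinson–Foulds distance
   plus per-clade monophyly/impurity.
4. **simulate** — generate synthetic paired databases and amplicons with
   known truth, so the whole pipeline is testable without any download.

## The classifier

A query *q* is aligned semi-globally against candidate references (the
shorter sequence aligns end to end; overhangs of the longer are free).
With identity defined over the aligned columns,

* references with identity ≥ 90 % are **hits**;
* the top 3 hits by identity vote rank by rank: a rank-*d* prefix *t* is
  accepted iff  #{hits with prefix *t*} / #hits > 0.51;
* no assignment is made with fewer than 3 hits, and the taxonomy is
  truncated at the first rank where the majority fails.

All thresholds (`--min-identity`, `--min-consensus`, `--max-accepts`,
`--min-hits`) are exposed on the command line.  A shared-k-mer prefilter
accelerates the search and can be disabled (`--no-prefilter`) for provably
exhaustive search.

## Worked example

Simulate a database shaped like the real one (4 orders × 3 clades × 4
references), classify 100 simulated ~250 bp amplicons carrying 2 %
divergence, and score against the truth:

```bash
amoalink simulate --orders 4 --clades 3 --refs 4 --queries 100 --seed 42 -o demo
amoalink classify --query demo/queries.fasta --db-seqs demo/db_16s.fasta \
                  --db-tax demo/db_taxonomy.tsv -o demo/assignments.tsv
amoalink evaluate --assignments demo/assignments.tsv --truth demo/truth.tsv \
                  -o demo/metrics.tsv
amoalink congruence --seqs-a demo/db_16s.fasta --seqs-b demo/db_amoa.fasta \
                    --clades demo/db_taxonomy.tsv -o demo/congruence.tsv
```

which prints

```
INFO amoalink: simulated 48 references, 100 queries
INFO amoalink: assigned 100 of 100 queries
INFO amoalink: clade assignment rate 1.000, clade accuracy 1.0
INFO amoalink: RF 6 / 90 (normalized 0.067) over 48 shared pairs
```

`assignments.tsv` holds one row per query:

```
query_id  taxonomy     depth  confidence  n_hits  hit_ids
q0001     NP;NP-gamma  2      1.0000      3       NP-gamma.r4,NP-gamma.r1,NP-gamma.r2
q0002     NT;NT-beta   2      1.0000      3       NT-beta.r2,NT-beta.r3,NT-beta.r1
```

Every query was assigned (rate 1.0) to its generating clade (accuracy 1.0):
at 2 % amplicon divergence all same-clade references clear the 90 % identity
threshold while other clades stay far below it.  The congruence report shows
the two marker trees nearly coincide (normalized Robinson–Foulds 0.067;
every clade monophyletic in both trees with impurity 0), which is the
property that justifies transferring clade labels between the markers.

To classify real ASVs, point `--db-seqs`/`--db-tax` at a curated reference
database (16S FASTA + two-column taxonomy map ending in the *amoA* clade)
and `--query` at your ASV FASTA.  `amoalink build-db` constructs such a
database from genome FASTA plus marker seed sequences, and accepts a flag
list of contaminant/symbiont record ids and precomputed gene coordinates.

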