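# ssrbank

Local SSR fingerprint database management for plant variety
identification: audited three-tier storage, hierarchical weighted
consensus merging of replicate experiments, offset-tolerant fingerprint
comparison, quality control, and genetic analysis — as a Python library
with a thin CLI.

## The problem

A variety's DNA fingerprint is its diploid genotype profile over a panel
of SSR (microsatellite) markers, with alleles named by capillary-
electrophoresis fragment size in bp. Building a reference database from
bench data means reconciling repeated experiments by several
experimenters on several DNA extractions per sample — all subject to a
1–2 bp sizing error and occasional failed runs — and only then comparing
candidate fingerprints against the reference store. `ssrbank` implements
that pipeline for a single lab's desk: raw uploads land in an
experimental tier (EFD), auditing merges them per sample into a sample
tier (SFD), and audited consensus fingerprints are promoted to a local
reference tier (LFD) that can be locked and queried.

## Core machinery

**Locus comparison.** Genotypes `[a1,b1]` and `[a2,b2]` are *same* iff
the direct or the crossed allele pairing agrees within the base offset
`n` (default 2 bp, absorbing CE read error):
`(|a1−a2| ≤ n ∧ |b1−b2| ≤ n) ∨ (|a1−b2| ≤ n ∧ |a2−b1| ≤ n)`.
Per fingerprint pair the loci tally into different/same/missing counts
with `p = D + S + M` and dissimilarity `x = D/p`; results are filtered by
`p − M ≥ 20`, `D ≤ 20`, `x ≤ 0.05` by default. Comparison scopes: whole
database, homonymy (same name/synonyms), non-homonymy, sub-database, or
explicit pairs.

**Consensus merging.** Replicates form a weighted tree (experiment →
DNA → experimenter → sample → variety); each leaf under a branch with
counts `(i,j,k,m)` weighs `1/(i·j·k·m)`, so weights conserve at every
node. Each merge clusters genotypes by offset-equality and keeps the
heaviest cluster's modal genotype — but only if its support strictly
exceeds 60% (the complement of a 40% noise boundary). Anything weaker is
flagged for manual audit and reselection. With odd replicate counts,
strictly less than 40% whole-run noise never costs an effective locus;
40% or more does.

**Genetics.** Allele ("gene") frequency tables, twelve genetic distance
methods (shared-allele, Nei standard, Nei DA, Rogers, modified Rogers,
Cavalli-Sforza chord, simple matching, Jaccard, Dice, Euclidean,
difference count, difference ratio), and UPGMA / neighbour-joining trees
as newick.

See `docs/methods.md` for the full model description and design choices.

## Worked example

A complete synthetic campaign through the CLI — simulate three varieties
with three replicate runs each, import, audit, promote, then identify
the (noise-free) truth fingerprints against the locked reference store:

```sh
$ ssrbank simulate --out sim --seed 7 --varieties 3
wrote panel (20 markers), 3 truth fingerprints, 9 experiment replicates, SIT to sim
$ ssrbank init --store db --panel sim/panel.csv
store initialized at db
$ ssrbank import --store db --table sim/experiments.csv --owner e1
imported 9 EFD records (EFD-000001..EFD-000009)
$ ssrbank sit --store db --sit sim/sit.csv --owner e1
registered SIT sit: 9 rows, owner e1
$ ssrbank audit --store db --sit-id sit --auditor e1
promoted: 3 sample(s)
  V001-S1 -> SFD-000001
  V002-S1 -> SFD-000002
  V003-S1 -> SFD-000003
$ ssrbank promote --store db --samples V001-S1,V002-S1,V003-S1 --lock
promoted 3 LFD record(s) [locked]
$ ssrbank compare --store db --pending sim/truth.csv --max-diff-loci 0
pending_id reference_id  p  D  S  M   x verdict
      V001      V001-S1 20  0 20  0 0.0   match
      V002      V002-S1 20  0 20  0 0.0   match
      V003      V003-S1 20  0 20  0 0.0   match
```

Each truth fingerprint matches exactly one reference — its own merged
consensus — with zero different loci (`D=0`, `x=0.0`) over all 20 panel
markers; cross-variety pairs are filtered out by the `--max-diff-loci 0`
threshold. The same operations are available as library calls
(`ssrbank.compare.fcpp`, `ssrbank.merge.cross_layer_merge`,
`ssrbank.storage.FingerprintStore`, …).

The replicate-audit noise boundary:

```sh
$ ssrbank qc-scan --seed 1
...
noise tolerance boundary: 40%
```

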