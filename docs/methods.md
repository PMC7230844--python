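# Methods

`ssrbank` manages diploid SSR (microsatellite) DNA fingerprints for plant
variety identification: it stores raw genotyping uploads, consolidates
replicate experiments into audited consensus fingerprints, compares
fingerprints offset-tolerantly against a reference database, and runs
standard genetic analyses on the result. This note documents the models
and procedures, the parameters that matter, the numerical choices, and
what the synthetic-data tests do and do not demonstrate.

## Data model

A fingerprint is a map from a fixed panel of `p` SSR markers to diploid
genotypes. Alleles are named by CE fragment size in bp at 0.1 bp
resolution; a genotype is an ordered pair `(allele_low, allele_high)`
(homozygotes are stored as an equal pair) or a missing call. A
half-called locus is not representable: under the diploid contract a
single surviving call carries too little information to distinguish a
homozygote from allele dropout, so importers reject one-allele rows
unless explicitly told to duplicate them into homozygotes
(`duplicate_single_allele`). Polyploid genotypes are out of scope.

Because high-polymorphism panels lean on dinucleotide (2 bp repeat)
markers, alleles of adjacent repeat classes differ by only 2 bp and CE
sizing carries a systematic 1–2 bp read error. All comparison and merging
therefore runs through a **base offset** `n`: two allele sizes are
treated as identical when they differ by at most `n` bp.

## Locus comparison and pairwise fingerprint comparison

Two effective genotypes `[a1,b1]`, `[a2,b2]` at one marker are **same**
iff the direct pairing (`|a1−a2| ≤ n` and `|b1−b2| ≤ n`) or the crossed
pairing (`|a1−b2| ≤ n` and `|a2−b1| ≤ n`) holds; otherwise **different**.
The comparison is inclusive (`≤ n`), symmetric, and monotone in `n`. If
either side of a pair lacks a complete call, the locus is **missing** for
that pair.

For a fingerprint pair the locus classes tally into `D` (different), `S`
(same) and `M` (missing) with the conservation identity

    p = D + S + M,        x = D / p,

where `x`, the differential-locus fraction, is the headline dissimilarity
(denominator `p`, not `p − M`, so heavy dropout cannot silently inflate
similarity). Queue comparison scores every (pending × reference) ordered
pair, walking the reference queue in the outer loop, and yields exactly
`|reference| × |pending|` results.

Results are filtered for reporting by three thresholds; a result is kept
iff

* shared non-missing loci `p − M ≥ min_comparison_loci` (default 20),
* `D ≤ max_diff_loci` (default 20),
* `x ≤ max_diff_fraction` (default 0.05).

The default base offset is 2 bp, the upper end of the CE read error. The
ranges are enforced at construction (`0 ≤ offset ≤ 2`,
`0 ≤ max_diff_fraction ≤ 1`, counts ≥ 0). The filters commute, so their
application order is irrelevant.

Comparison scope is selected by mode: the entire reference database
(LFD); **homonymy** (reference entries sharing any trimmed,
case-sensitive name or synonym with the pending fingerprints) and
**non-homonymy** (its exact complement — the two partition the
database); or externally assigned sub-database / explicit-pair scopes
read from CSV/XLSX. Fuzzy name matching is deliberately not attempted.

## Hierarchical weighted merging

Replicates are organized as experiment → DNA → experimenter → sample →
variety, with branch counts `i` (experiments per DNA), `j` (DNA
extractions per experimenter), `k` (experimenters per sample) and `m`
(samples per variety; `m = 1` treats a sample as its own variety). Every
experiment leaf under a branch carries weight `1/(i·j·k·m)` computed from
that branch's local counts; merged fingerprints at the DNA, experimenter
and sample layers carry `1/(j·k·m)`, `1/(k·m)` and `1/m`. Weights are
conserved at every node and total 1 over the tree, so the contribution of
each laboratory stage to the final fingerprint is explicit and an audit
flag can be traced to the stage (instrument run, extraction, analyst,
batch) that produced it. Multiple DNA extractions by one experimenter
from the same plant are one repeat: SIT rows sharing (experimenter,
plant) collapse into a single DNA node at tree construction.

**Peer merging** consolidates the fingerprints within one layer locus by
locus:

1. Missing calls are excluded from voting but stay in the support
   denominator, so heavy dropout forces an audit rather than promoting a
   minority call.
2. Effective genotypes are clustered greedily in input order by
   offset-equality against each cluster's first member, so ±1–2 bp read
   scatter around one true genotype lands in one cluster.
3. The cluster with the greatest summed weight wins. Its representative
   is the exact modal genotype within the cluster; modal ties break to
   the smallest `(allele_low, allele_high)` pair, a deterministic,
   order-free rule.
4. The winning support fraction is `winning weight / total locus weight`.
   A locus is effective only if support **strictly exceeds 0.6** — the
   complement of a 40% noise boundary. At or below that, or on a
   weight tie between clusters, the locus is flagged `AUDIT_REQUIRED`
   and dropped to missing pending manual reselection; a locus with no
   effective input is `DROPPED_TO_MISSING`.

The strict 60% rule reproduces the odd-replicate behavior that motivates
three-repeat designs: 1 noise set in 3 (33%) still merges every locus
(support 2/3), while 2 in 5 (40%, support exactly 3/5) is flagged. The
strict comparison carries a 1e-9 guard so float accumulation of equal
weights (3 × (1/5) = 0.6000000000000001) cannot tip an exact-boundary
locus.

**Manual reselection** clears a flagged locus to a chosen candidate; the
choice must be one of the observed cluster representatives unless a
`force` override is given, and the provenance note records `manual` vs
`override`.

**Cross-layer merging** applies peer merging bottom-up to the variety
fingerprint, collecting every non-OK flag with its layer of origin into
an audit report. A locus that stays unresolved to the top surfaces as
`AUDIT_REQUIRED` on the final outcome, carrying the candidates from the
stage where the conflict arose, so reselection can be applied to the end
result.

Support is weight-weighted; because siblings at any node share one weight
by construction, this coincides with count voting within each merge and
the question of mixed weights inside one peer merge does not arise (it is
rejected outright).

## Three-tier store

* **EFD** (experimental): raw uploads, validated against the panel,
  owner-scoped, never altered — the trace anchor.
* **SFD** (sample): written by auditing a SIT. Only the SIT's owning
  experimenter may audit. Each sample's replicates are merged with
  `m = 1`; a sample whose consensus carries audit flags is stored as an
  *unaudited draft* that blocks promotion until resolved, while clean
  samples promote independently.
* **LFD** (local/reference): audited sample fingerprints promoted per
  sample; this is the comparison scope. Records can be locked; locked
  records reject every mutation and deletion.

The store is a single-file SQLite database whose tables mirror the bench
entities (sample, DNA, experimenter, variety, panel/marker, PCR and CE
plates with per-well rows, SIT rows, and the three record tiers).
Fingerprint payloads and CE image references are **path-indirect**:
sidecar JSON files named from a `fingerprint_file` table, keeping bulky,
crop-specific payloads out of the relational tables. `trace()` walks
LFD → SFD → EFD → (plate wells, image paths). Foreign keys are enforced
(`PRAGMA foreign_keys`), and `check_integrity()` exposes the check.
Ownership fields enforce the permission rules at operation level; there
is deliberately no authentication layer.

## Genetic analysis

Allele frequencies are tallied per marker over both alleles of every
effective genotype (basis `2 ×` non-missing fingerprints; missing loci
leave the denominator). For frequency work, observed sizes are optionally
snapped to each marker's repeat-unit grid — without binning, a 1 bp read
error splits one allele into spurious classes.

The distance registry implements twelve standard methods, treating each
fingerprint as a one-individual population (per-locus allele frequencies
1 or ½): shared-allele distance (1 − mean proportion of shared alleles),
Nei's standard distance, Nei's DA, Rogers' distance, modified Rogers,
Cavalli-Sforza chord, simple matching on offset-equal loci, Jaccard and
Dice on allele presence, Euclidean on allele-frequency vectors, and the
comparison-derived raw difference count `D` and ratio `x`. Sums run over
loci effective in both fingerprints. All methods are symmetric with zero
diagonal; identical fingerprints are at distance 0.

Trees are built by UPGMA (ultrametric by construction) or neighbour
joining via Bio.Phylo's distance-tree constructors and emitted as newick
with full-precision branch lengths (internal labels stripped, tiny
negative NJ branch lengths clamped to 0). A plain-text dendrogram render
is available; image output is out of scope.

## Quality control

* **Reference check**: in-run standard samples are compared to their
  stored standards; a check passes iff `D = 0` at the default offset,
  and any failure marks the whole run suspect (per-reference detail
  retained).
* **Replicate audit**: each sample's repeated experiments (three is the
  canonical design) are peer-merged; flagged and missing locus counts
  quantify run consistency.
* **Noise-tolerance scan**: for each odd replicate count `r ∈ {3,5,7}`
  and noise proportion `f` in a grid, a set of `round(f·r)` whole noise
  replicates plus exact truth copies is merged and the scan records
  whether the merged effective-locus count dropped. The reported boundary
  is the smallest realized noise fraction that degrades — 40% under the
  default support rule, independent of the seed, because the governing
  ratio is combinatorial (support `3/5` at 2-of-5 noise) rather than
  stochastic. Even replicate counts are rejected: with no strict
  majority possible the boundary claim does not apply.

## Synthetic data

The generator emulates a routine variety-fingerprinting campaign and is
the sole source of test inputs. Defaults: a 20-locus dinucleotide panel
(10 alleles per marker on the 2 bp grid, marker-specific size windows),
heterozygosity 0.5, three repeated experiments per DNA by one
experimenter (`i=3, j=k=m=1`), allele dropout 0.02 per locus, and a
per-allele read-error model of ±1 bp with probability 0.05 and ±2 bp
with probability 0.01 — the error magnitude that motivates the 2 bp
offset. All randomness flows from one seed; identical config + seed
reproduces identical output.

Two deliberate choices:

* Truth alleles are drawn from the *interior* of each marker's grid so a
  ±2 bp read error can never leave the declared size range (otherwise
  valid uploads would fail panel validation on a boundary allele).
* A **noise replicate** (modelling a failed or swapped run) redraws every
  locus uniformly from the marker grid, excluding genotypes within
  `noise_clearance_bp` (default 4 = base offset 2 + max read error 2) of
  the truth in the offset-comparison sense. With a plain exclusion of
  the true genotype only, a noise call landing 3–4 bp from truth can sit
  within the offset of an erred clean read, chain into the truth cluster
  under greedy clustering, and occasionally win the modal tie-break —
  about 5% of seeded runs flagged a locus that way. Real noise data
  (another sample's profile) is genuinely distinct, so the clearance is
  the faithful emulation; it is configurable for studying the ambiguous
  regime.

What passing tests show — and do not. The generator covers replicate
scatter, dropout and whole-run noise, which is what the merging and QC
machinery is about. It does not model stutter or plus-A artifacts,
electropherogram peak shapes, null alleles, sample mixtures, or
population structure among varieties; conclusions about those phenomena
cannot be drawn from these tests. The 40% boundary is a property of the
majority rule under the stated noise model, not a statement about
arbitrary correlated noise: two noise replicates that agree with each
other still lose to a 3-of-5 truth cluster but would win in a 2-of-4
design, which is why only odd counts are certified.

## Numerical and interface choices

* Allele sizes are decimals rounded to 0.1 bp (CE resolution); offset
  comparisons are inclusive (`≤ n`).
* Ties anywhere in merging are surfaced, never silently resolved: a
  cluster-weight tie flags the locus; a modal tie inside the winning
  cluster resolves deterministically to the smallest allele pair.
* `x ∈ [0,1]` with both endpoints attainable (identical and fully
  distinct fingerprints both occur in practice).
* Sub-database / paired comparison assignments, genotype tables and SITs
  are CSV-canonical with XLSX accepted through the same column mapping;
  the canonical genotype dialect is
  `Sample Name,Marker,Allele 1,Allele 2`.
* Plate design fills 96-well plates row-major (A1…H12) with the first
  `refs_per_plate` wells reserved for reference samples;
  `ceil(jobs/(96−refs))` plates, fully deterministic. The fill rule is a
  convention, not a claim about optimal bench layout.
* Problem sizes in the test-suite and acceptance computations (20-locus
  panels, replicate counts up to 7, hierarchies up to (4,3,3,2), 10^3–10^4
  random pairs for the comparator checks) are desk-scale choices that
  already exercise every code path; all quantities checked are either
  combinatorial or concentrate well below these sizes.

## Known limitations

Diploid only; no FSA/electropherogram parsing (image association is
path metadata); no multi-user concurrency or authentication; no bootstrap
support on trees; no mixed-sample (cultivar blend) comparison mode; the
homonymy match is exact string equality, so spelling variants of a
variety name are different names.
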