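# Methods

## Model and procedure

`scattercall` models a scatter-gather variant-calling pipeline as five
cooperating pieces: a genomic-interval data model, a two-stage load
balancer, the data movements at three synchronization barriers, an
orchestrator that drives pluggable external stage commands, and a VCF
concordance evaluator. All coordinates are 0-based half-open internally;
SAM and VCF 1-based positions are converted exactly once, at ingest.
Contig order is the file order of the reference index (`.fai` or `@SQ`
dictionary) and defines the global sort order of every output.

### Static partitioning

With genome size `S` bp and requested region count `R`, the target region
size is the exact rational `S/R`. Chromosome boundaries are respected
first; a chromosome of length `L` is split into
`k = max(1, floor(L / (S/R)))` equal pieces, remainder base pairs assigned
to the last piece. Two consequences follow from the rule: every contig
holds at least one region (so the realized count `RsLB >=` both the contig
count and, on references with many small contigs, the request itself), and
a contig shorter than the target size is never split. Two boundary choices
are ours: the equal-size-with-remainder-to-last intra-contig scheme (any
tiling scheme satisfies the downstream contracts; equal sizes make the
arithmetic auditable), and a cap `k <= L` so that the degenerate request
`R > S` still yields non-empty regions.

### Dynamic refinement

After alignment, mapped reads are counted per static region by their
leftmost mapping position; with `N` total routed reads over `RsLB` regions
the target load is the exact rational `N/RsLB`. A region with `n` reads
splits into `k = floor(n / (N/RsLB))` sub-regions when `k >= 2`, otherwise
stays whole. Cut points sit at read-count quantiles: the j-th cut falls at
the start coordinate of the read ranked just past `ceil(j*n/k)`, so
sub-region loads differ by at most one read where positions are distinct.
When reads are tied across a quantile rank the cut shifts forward past the
tie run (the left piece absorbs the run); a region whose reads all share
one coordinate is never split, because the tiling invariant outranks load
balance. Whether the original formulation floors, rounds or ceils `k` is
not specified anywhere we could anchor to; we floor, consistently with the
static stage.

Averages are kept as `fractions.Fraction` throughout and flooring happens
only at `k`, so exact multiples (e.g. `n` exactly twice the target) behave
identically on every platform.

The widely quoted load guarantee "no region exceeds twice the target" is
provable only for distinct read positions. A tie run spanning the single
quantile of a `k = 2` region suppresses its only cut and leaves up to
`3x` the target in one region; the property suite therefore asserts the
`2x + 1` bound exactly where positions are distinct and only tiling plus
read conservation where they are not.

### Barrier data movements

* **FASTQ chunking** — contiguous blocks of `ceil(total/n_chunks)`
  records; paired files are cut at identical record indices so mates stay
  aligned; concatenating the chunks reproduces the input byte-identically.
  Contiguous (not round-robin) blocks are what make the byte-level
  concatenation contract possible.
* **Splice-junction merging** — 9-column junction tables are merged one
  row per `(contig, intron start, intron end, strand, motif)` key; support
  counts add, overhang and annotation flags take the max. Output order is
  `(contig, intron interval)` with contigs sorted lexicographically unless
  a reference dictionary is supplied — either way the merge is associative
  and byte-for-byte insensitive to input order.
* **SAM routing** — each mapped record goes to exactly the region
  containing its leftmost position, however far it extends; shards are
  sorted by `(position, read name)`; unmapped reads go to an overflow
  shard. Secondary/supplementary records route like primary ones. Sorting
  is in-memory: the contract is the sorted output, and desk-scale shards
  need no external sort.
* **VCF merging** — header from the first input (all inputs must agree on
  `##contig` lines); data lines sorted by `(contig rank, position)`; exact
  duplicates of `(contig, pos, ref, alt)` — the signature of a boundary
  variant called by two adjacent regions — collapse to the first
  occurrence, and the count of dropped duplicates is reported so read/call
  conservation stays checkable.

Record handling at these barriers is deliberately text-level (parse the
few fields the rule needs, keep the verbatim line) because the contracts
are byte-level round-trips; record-object libraries normalize fields and
would break them.

### Orchestration

The runner executes: chunk → parallel pass-1 alignment → barrier 1 (merge
junctions, rebuild index once, sequentially) → parallel pass-2 alignment →
barrier 2 (route to static regions, profile, refine, re-route) → parallel
per-region calling → barrier 3 (merge VCFs). External stages are shell
command templates with `{input}`, `{input2}`, `{output}`, `{index}`,
`{region_bed}`, `{reference}` placeholders, validated before anything
runs. A thread pool bounded by `workers` runs the independent shard
commands; the static plan is computed up front (it needs only the
reference), the dynamic plan at barrier 2. A failing shard aborts the run
at its barrier with every intermediate preserved; successful external
shards leave `.ok` markers, so a rerun with the same configuration resumes
from completed artifacts, and since every internal computation is
deterministic the resumed run's final VCF equals a clean run's. Failure
semantics are not specified by the flow the package models;
abort-at-barrier with resumability is our choice.

### Concordance evaluation

Variants match on exact `(contig, pos, ref, alt)` keys after multi-allelic
lines are split per alt allele; FILTER and genotype columns are ignored.
`sensitivity = 100*TP/(TP+FN)` and `precision = 100*TP/(TP+FP)`, reported
to two decimals, with an explicit undefined-metric error when a
denominator is zero. Exact-key matching is *not* haplotype-aware: tools
that canonicalize equivalent representations of complex loci can count
TP/FP/FN differently, while the metric formulas applied to given counts
are exact.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `num_regions` | 1 | requested region count; realized counts `RsLB`, `RdLB` generally differ |
| `n_chunks` | = `workers` | FASTQ chunk count; one chunk per available thread |
| `workers` | 1 | bound on concurrently running external stage commands |
| `min_alt` (mock caller) | 3 reads | minimum reads carrying the same alt base |
| `min_frac` (mock caller) | 0.30 | minimum fraction of covering reads carrying it |
| `read_length` (simulator) | 100 bp | typical short-read length |
| `coverage` (simulator) | 30x | typical whole-genome depth |
| allele `fraction` (simulator) | 1.0 | per-read probability of the alt base (1.0 = homozygous, error-free) |

## What the synthetic data does and does not emulate

The simulator generates uniform-random A/C/G/T references, uniformly
placed reads whose names encode their true origin, SNVs planted at a
chosen allele fraction, and a truth VCF. The mock aligner places reads at
their encoded origin and emits deterministic junction tables by hashing
read origins into a fixed per-contig junction set — enough to exercise the
barrier-1 merge with real additive counts. The mock caller is a naive
pileup restricted to reads *starting* in its region and to positions
*inside* its region, which reproduces the boundary behavior of
start-position sharding in its cleanest form and makes the final VCF
exactly independent of the partitioning.

Deliberately absent: sequencing errors, quality-score realism, spliced
reads (junctions are synthetic metadata), indels and complex variants,
non-uniform coverage along a contig, and any real alignment algorithmics.
Passing tests therefore demonstrate the correctness of the *scaffold* —
partitioning, routing, barriers, merging, determinism — not the accuracy
of any real aligner/caller combination on real RNA-seq data.

The partition-invariance study plants variants at least one read length
away from every region boundary of the partitionings under test. With
uniformly sampled reads the dynamic stage performs no splits (no region
approaches twice the mean load), so those boundaries are the closed-form
static ones and the guard is exact. At 30x coverage every variant site has
far more than `min_alt` supporting reads, so truth recovery at 100.00%
sensitivity is the expected outcome, not a tuned one.

## Problem sizes

Test and acceptance workloads are sized for a single CPU: the invariance
study uses 2 contigs x 50 kb at 30x (30,000 reads, 20 planted SNVs) across
eight pipeline configurations; the tiling suite draws 100 random
references up to 10 contigs and 100 kb; conservation suites use 10,000
records; the skew study uses 20,000 reads with 90% on one region.

## Known limitations

* Exact-key concordance understates agreement on complex loci compared to
  haplotype-aware comparison.
* The orchestrator is a single-machine thread pool; it reproduces the
  barrier-and-independent-task contract of a cluster framework but none of
  its scheduling, data locality, or resilience behavior.
* In-memory SAM shard sorting assumes desk-scale shards.
* The load-balance bound degrades gracefully but unavoidably under heavy
  coordinate ties (see above).
* BAM/CRAM are out of scope; all formats are their uncompressed text
  forms.
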