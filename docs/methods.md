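# Methods

## Reference model

A reference is a set of precursor hairpins plus mature annotations
located on them, mirroring miRBase's hairpin FASTA / mature FASTA /
GFF3 triple. Coordinates are 0-based half-open internally (GFF3's
1-based inclusive intervals are converted on load) so that end offsets
are plain integer arithmetic. RNA alphabets are normalized U→T on
input; writers echo the convention the reference arrived in. When no
GFF3 is given, matures are placed by exact search; the leftmost
occurrence wins and multiple occurrences are logged (repeats of an
18+-mer within a hairpin set are rare enough that determinism matters
more than modelling them). Arm labels come from the GFF3 (an `arm`
attribute or a `-5p`/`-3p` name suffix) and otherwise from the mature's
midpoint relative to the hairpin midpoint; an exactly centered mature is
assigned 3p so the rule is total and deterministic.

## Read ingest

Adapter trimming truncates at the leftmost match of the adapter's first
8 nt allowing one mismatch — the standard small-RNA heuristic; reads
without a match are kept (an insert longer than the read has no adapter)
and pure-adapter reads (empty insert) are discarded. Filtering keeps
16–36 nt reads with mean Phred ≥ 20. The 16-nt floor is the usual
shortest assignable miRNA fragment; the mean-quality rule is this
package's explicit, logged stand-in for vendor "low-quality read"
removal, whose exact definition commercial pipelines do not publish.
All thresholds are configurable. Surviving reads are collapsed to
(sequence, count) pairs; downstream cost then scales with sequence
diversity rather than depth, and count conservation
(Σ collapsed = reads kept) is asserted in tests.

## IsomiR classification

For a given (mature, 5′ offset) the 3′ offset is fixed by read length,
so the interpretation space is small and enumerable exactly:
offset5 ∈ [−3, +3], offset3 ∈ [−5, +5], ≤ 2 substitutions (defaults;
all configurable). The rules:

* 5′ extensions must match the hairpin template exactly — non-templated
  5′ additions are not modelled (they are biologically rare, and
  allowing them would make every unassignable prefix "explainable").
* Substitutions are counted over the template-aligned portion only.
* A 3′ extension is decomposed greedily: walk along the hairpin from the
  canonical 3′ end while bases match; the remaining suffix is the NTA
  tail. Greediness makes the decomposition unique; a planted "A" that
  happens to match the template is, truthfully, templated. Tails are
  classified adenylated (all A), uridylated (all U/T), or other.
* The best interpretation minimizes, lexicographically:
  (substitution count, |offset5| + |offset3|, tail length, |offset5|,
  mature name). The trailing name term makes selection total; when the
  first four components tie across k matures the read is assigned
  fractionally (1/k each), which conserves counts and is deterministic.
* Categories: canonical (no change); substitution / del3p / add3p /
  del5p / add5p when exactly one axis changed; mixed when two or more of
  {5′ change, 3′ change, substitution} hold. Per-end offsets are always
  carried on the call, so per-end tallies can also be computed without
  the category rollup.

The seed is bases 2–8 of the read; a 5′ offset shifts the seed window by
exactly that many bases (`seed_shift = offset5`), and 3′-only variants
leave it untouched. Classification is validated against an independent
brute-force enumerator (tests/_oracle.py) that re-derives the whole
interpretation space with naive loops.

## Quantification

Counts are aggregated per variant signature
(mature, offset5, offset3, substitutions, tail) × sample, fractional
under multi-mapping. CPM = count / sample total × 10⁶. Ranking sums
variant CPM per mature and averages across samples before computing
percentage and cumulative contribution; pooling raw counts instead is a
one-line variation (run the ranking on a summed table) — which of the
two a given published figure used is generally not recoverable, and the
mean-CPM form is depth-robust. Arm usage calls a precursor 5p-only /
3p-only / both / none at a mean-CPM ≥ 1 detection floor — the
conventional "detected" threshold; it is a parameter, not a claim.
Isoform diversity counts distinct variant signatures with ≥ 100 total
reads, a floor that suppresses singleton sequencing noise. Group
comparisons use the two-tailed pooled-variance Student *t* on CPM
(the classical small-sample choice when per-group variances cannot be
estimated well); zero-variance rows are flagged `degenerate` and
reported as p = 1 (equal means) or p = 0 (different means) rather than
dropped.

## RIP differential association

Counts are pooled within each condition and each variant is tested with
a two-sided Fisher's exact test of its proportion between the two pooled
libraries — exact at any count, assumption-light, and well-defined
without replicates; the test is a pluggable callable so a replicate-
aware model can be substituted when the design supports one. Note the
pooled test treats reads as independent draws, so its p-values are
calibrated against sampling noise only, not biological replicate
variance. M = log₂((b+c)/(a+c)) and A = ½(log₂(a+c)+log₂(b+c)) on
CPM-scale means with pseudocount c = 0.5 (configurable) to keep zeros
finite. Multiple testing uses Benjamini–Hochberg; variants with fewer
than one pooled read are dropped before testing since they only dilute
the correction. Candidate selection keeps variants with mean raw read
count > 1000 (an expression floor on reads, not CPM), |M| ≥ 1 and
q ≤ 0.05, sorted by |M|. Both contrasts are supported: condition within
a fraction (e.g. RIP: IL-1β vs control) and fraction within a condition
(e.g. IL-1β: RIP vs input).

## Synthetic data

The generator emulates what matters for validating this pipeline:

* Hairpins of 60–82 nt carrying 22-nt matures on the 5p and 3p arms.
  Every mature window and all its ±3-nt shifts are screened to occur
  exactly once across the whole reference, so each error-free read has a
  single truthful interpretation and recovery can be scored exactly.
* Mature abundances are log-normal (σ = 1 by default; σ = 1.5 in the
  RIP experiments, giving the heavier concentration seen in real miRNA
  pools where a few species dominate).
* Categories are drawn per read from a configurable mixture. The default
  is 48 % canonical with the variant mass split
  71.1 : 15.4 : 3 : 2 : 1 : 1 across del3p / add3p / add5p / del5p /
  mixed / substitution (normalized to sum to the 52 % variant share) —
  3′ trimming dominant, 3′ addition next, 5′ changes and the rest rare.
  Offsets use short-biased magnitude distributions (1 nt most likely);
  3′ additions are templated with probability 0.3, otherwise an NTA tail
  with composition 60 % A-tails / 35 % U-tails / 5 % mixed. Recorded
  truth applies the same greedy templated/NTA decomposition as the
  classifier definition, so truth is the canonical description of the
  constructed read, not of the intermediate recipe.
* Sequencing error is per-base (default 0; 22 nt at ε = 0.005 means
  ≈10 % of reads carry an error, which is the ceiling on exact category
  recovery — the tests assert that error-free reads recover perfectly
  and that errors are the only source of misses).
* RIP experiments build a deterministic variant pool (canonical + ~3
  sampled variants per mature, weighted by mature abundance × category
  share) and draw each library multinomially at fixed depth; spiked
  variants have their weight multiplied by 2^log2FC in the IL-1β RIP
  library. Fixed-depth sampling renormalizes weights (compositional
  closure, as in real sequencing), so a spike on a variant holding
  fraction w of the pool realizes a ratio 2^l2fc / (1 + (2^l2fc − 1)·w);
  recovery experiments therefore spike high-abundance variants with
  small pool shares. One integer seed drives everything through a single
  `numpy` generator; draw order is reference construction, abundances,
  then per-read draws.

What the generator does **not** emulate: patient-to-patient biological
variance, ligation/PCR bias, adapter read-through chemistry, genomic
multi-mapping outside the miRNA reference, or RNA editing beyond plain
substitutions. Passing recovery tests therefore demonstrates the
correctness of the algorithms under the stated read model, not
robustness to every artefact of real libraries.

## Problem sizes and numerics

Validation runs use 1,000 reads for oracle equivalence, 100,000 reads
for mixture recovery (binomial ±3σ at that depth is ≈0.47 pp, inside
the ±0.5 pp check), 10,000 reads for seed-shift checks, and RIP
experiments of ~2,000 variants at 500,000 reads × 4 libraries with 20
spikes at |log₂FC| = 1.5 — sizes at which every targeted effect is
detectable with wide margin while a full run stays in the minutes
range. CPM sums are checked to 10⁻⁶ relative; Fisher p-values match
exhaustive hypergeometric enumeration (tables with row margins ≤ 30,
using a 1+10⁻⁷ relative cushion on the two-sided pmf cutoff, the
standard guard against float ties) to ≤ 10⁻⁹; Student *t* p-values match
the regularized-incomplete-beta closed form to 10⁻⁹. Pipeline outputs
are plain TSV/JSON with fixed float formatting and no timestamps, so
identical (inputs, config, seed) reproduce byte-identical outputs.

## Known limitations

* Fractional multi-mapping splits ties uniformly; no EM reassignment.
* The pooled Fisher test understates uncertainty when biological
  replicates exist — swap in a replicate-aware test for such designs.
* Arm usage and the t-test layer assume the variant table is already
  well-normalized by CPM; no batch or composition correction is applied.
* The classifier reports substitutions as plain mismatches; it does not
  infer A-to-I editing or distinguish SNPs from modification.
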