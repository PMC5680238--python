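# isomirseq

Small RNA-seq profiling of miRNAs and their sequence variants
(**isomiRs**), with differential **AGO2-RIP** association analysis.

Deep-sequenced small-RNA libraries rarely contain only the canonical
mature miRNA sequences annotated in miRBase. Reads carry 5′ and 3′
trimming, templated extensions, non-templated 3′ additions (adenylation
and uridylation) and internal substitutions. These variants matter:
a shifted 5′ end moves the **seed** (bases 2–8), the main determinant of
mRNA target recognition, so 5′ isomiRs silence a different gene set than
their archetype. And because a miRNA only represses targets while loaded
in the silencing complex, profiling the AGO2-immunoprecipitated fraction
(RIP-seq) against total input reveals which miRNAs/isomiRs are actually
functional and how a stimulus (e.g. IL-1β in primary chondrocytes)
redistributes them.

`isomirseq` is a library-first toolkit for this analysis:

* **Classification** — each read is interpreted against every annotated
  mature within a hairpin-anchored search window and assigned the
  minimal-edit interpretation (fewest substitutions, then smallest total
  end shift, then shortest non-templated tail). Reads fall into seven
  categories: canonical, substitution, 3′ deletion, 3′ addition,
  5′ deletion, 5′ addition, and mixed (two or more change types).
  3′ extensions are decomposed greedily into a templated part (matching
  the hairpin downstream of the canonical 3′ end) and a non-templated
  **NTA tail**; all-A tails are adenylation, all-U tails uridylation.
* **Quantification** — counts-per-million (CPM) normalization, abundance
  ranking with cumulative contribution, 5p/3p arm usage at a detection
  floor, per-miRNA isomiR composition, isoform diversity at a read-count
  floor, per-variant two-group Student *t*-tests, and seed-shift
  reporting (`seed shift = offset5`).
* **RIP enrichment** — per-variant M-A statistics
  (M = log₂ FC, A = mean log₂ abundance), a two-sided Fisher's exact
  test on pooled counts vs library sizes, Benjamini–Hochberg q-values,
  and the candidate filter *mean count > 1000, |log₂FC| ≥ 1, q ≤ 0.05*.
* **Simulation** — synthetic hairpin references with unambiguously
  placed 22-nt matures, FASTQ libraries with a configurable category
  mixture (default ≈48 % canonical with 3′ deletions dominating the
  variant mass), sequencing error, and paired control/IL-1β × input/RIP
  experiments with planted log₂ fold changes — every read backed by a
  truth record for exact recovery testing.

## Worked example

`examples/02_profile_simulated_library.py` simulates a 20-hairpin
reference and a 20,000-read library, then profiles it:

```
kept 20000 reads (893 distinct sequences)

Top 5 miRNAs by abundance (% of pool, cumulative %):
      name  rank    pct  cumulative_pct
hp-0014-5p     1 12.855          12.855
hp-0003-5p     2 10.345          23.200
hp-0003-3p     3  5.175          28.375
hp-0017-5p     4  5.020          33.395
hp-0006-5p     5  4.630          38.025

Global isomiR composition (fraction of all reads):
canonical       0.4761
substitution    0.0055
del3p           0.3981
add3p           0.0869
del5p           0.0104
add5p           0.0172
mixed           0.0058

47.6% canonical vs 52.4% variant; 93.7% of isomiRs carry a 3' change
```

The ranking shows the characteristic concentration of the miRNA pool in
a few species; the composition table recovers the simulated mixture
(the generator planted 48 % canonical), and the 3′-change share reflects
that 3′ deletion/addition dominate the variant mass.
`examples/01_reference_and_classification.py` walks single reads through
classification and seed-shift calls;
`examples/03_rip_enrichment.py` plants ±2 log₂ spikes in the IL-1β RIP
fraction and shows exactly those two variants passing the selection
filter.

A thin CLI wraps the same entry points:

```bash
isomirseq simulate-ref --n-hairpins 20 --seed 1 --out-dir ref/
isomirseq simulate-reads --ref-dir ref/ --n-reads 20000 --seed 2 --fastq lib.fastq
isomirseq profile --hairpin-fasta ref/hairpin.fa --mature-fasta ref/mature.fa \
    --coords-gff3 ref/coords.gff3 --sample-sheet samples.tsv --out-dir out/
isomirseq rip --config pipeline.json --contrast RIP:IL1B-vs-control --out-dir rip_out/
isomirseq report --run-dir out/
```

Real data plugs in the same way: a miRBase hairpin FASTA, mature FASTA
and (optionally) the miRBase GFF3, plus one FASTQ per library and a
sample sheet (`sample_id  fastq  condition  fraction`).

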