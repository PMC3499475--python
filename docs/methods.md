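# Methods

## Coordinate and window model

All coordinates are 0-based half-open; BED conventions apply only at file
boundaries. For a gene `[start, end)` the TSS is `start` on the + strand and
`end − 1` on the − strand; the 3′ end is the opposite anchor. A peak is
classified by its summit alone:

| category   | window (transcription direction)          |
|------------|-------------------------------------------|
| ingene     | summit in `[start, end)`                   |
| promoter   | 1–2,000 bases 5′ of the TSS                |
| upstream   | 2,001–100,000 bases 5′ of the TSS          |
| downstream | 1–100,000 bases 3′ of the gene end         |
| intergenic | none of the above, for any gene            |

The promoter window is closed at the −2 kb edge and open at the TSS (the
TSS base itself is ingene); the published window notation "−2 kb∼0 bp" does
not fix the edges, so this choice is documented here and enforced by tests.
Promoter and upstream windows are strand-aware (5′ in the transcription
direction); the gene body is taken as the annotated interval with no
exon/CDS structure.

When a summit falls in windows of several genes, the primary call follows
the precedence **ingene > promoter > upstream > downstream**, with the
nearest TSS breaking remaining ties and gene id as a final deterministic
tie-break. Besides the primary call, an exhaustive per-(peak, gene) table is
kept: gene-level statistics (bound-gene sets, peaks per gene) count a peak
once per gene it hits, so a peak between two genes contributes to both. The
mean peaks per gene divides the deduplicated (peak, gene) pair count by the
number of genes with at least one peak, and is reported to one decimal.
Candidate genes are found through per-chromosome interval trees over gene
envelopes extended by 100 kb; the test suite checks exact agreement with an
independent all-pairs brute-force classification on dense random fixtures
where the windows overlap freely.

Peak filtering keeps `fdr ≤ 0.1` (peaks *greater than* 0.1 are eliminated)
and `pvalue < 1e-5` (strict), matching the stated rules' phrasing. Score
bins are closed on the left: strong ≥ 200, medium in [100, 200), weak < 100.

## Response-element model

The half-site model is a length-6 position-specific log-odds matrix against
a background distribution (uniform by default), built either from aligned
ACGT sites with a pseudocount — entry `log(((c+1)/(N+4))/0.25)` at
pseudocount 1 — or from an IUPAC consensus (default RGGTCA), where allowed
bases are equiprobable and the acceptance threshold sits at the maximal
score, so AGGTCA and GGGTCA tie at the top and N never matches. In PWM mode
the default threshold is 0.8 of the maximal score. The published analysis
describes its motif stage only as a hidden Markov model built from known
nuclear-receptor sites; for fixed-length hexameric half-sites a
position-specific scoring model plus deterministic arrangement enumeration
has the same expressive power, and that substitution is made deliberately
here.

Scanning scores every window on both strands (a − strand hit at forward
offset *p* means the reverse complement of that window matches).
Classification enumerates all ordered hit pairs with spacer `0 ≤ n ≤
max_spacer`: same strands → DRn; (+,−) → IRn (head-to-head,
`AGGTCA …n… TGACCT`); (−,+) → ERn (tail-to-tail). `max_spacer` defaults to
8 because ER8 elements are documented receptor targets while observed DR/IR
spacers run to about 5. A sequence's best arrangement maximizes the combined
score with the deterministic tie-break *higher score → smaller spacer →
DR < IR < ER → leftmost*; the per-sequence arrangement spectrum counts one
best call per sequence (all pairs are also available, since the published
per-peak reduction is unstated). Class and spacer of the best call are
invariant under reverse complement, which the suite checks. Two targeted
detectors cover the patterns reported among the strongest peaks: three
equally spaced same-strand half-sites at `p, p+(6+s), p+2(6+s)` (two DR1s
sharing the middle half-site, s = 1 by default) and the Sp1 GC-box core
GGGCGG on either strand.

## Differential expression

Genes with mean signal ≥ τ in either genotype group are detected
("hepatic"); τ is a required configuration value standing in for the
array-platform detection calls, which the source analysis delegates to a
prior publication. Detected genes get a classical equal-variance two-sided
Student *t*-test (df = n₁+n₂−2, sign convention WT − KO) and are labeled
UIK/DIK at raw `p < α` (default 0.05) by the direction of the KO−WT mean
difference — no multiple-testing correction, a faithful-but-liberal
reproduction of the stated rule. Fold change is KO/WT on the linear scale.
Degenerate zero-variance genes: equal means give (t = 0, p = 1); unequal
means are flagged with p = 0 and a warning. Undetected genes carry no test
result.

## Integration and enrichment

The five-way partition is pure set algebra over (hepatic, dependent, bound);
"bound" means at least one filtered peak assigned to the gene in any
non-intergenic category — the source text never defines gene-level binding
explicitly, so this is fixed here. Dependent genes outside the hepatic set
are contradictory and dropped with a warning. The partition invariants
(disjointness, `II = dependent − III`, `V = bound − III − IV`) are asserted
after every construction. Percentages are reported raw and at display
rounding (one decimal, except the dependent fraction at two, matching the
published precision). The published bound fraction of hepatic genes appears
as both 79.1% and 78.7% in different sections of the source; the count
fixture realizes the 79.1% (7,174/9,068) figure and the discrepancy is
recorded, not resolved.

Enrichment uses the exact hypergeometric upper tail `P[X ≥ k]` for a term of
size K (after intersection with the universe), query size n, universe N; the
Bonferroni multiplier is the number of terms with nonzero universe overlap,
and a term is accepted when `p < 0.05` and Bonferroni `< 0.1`. An EASE-style
conservative variant (upper tail at k−1) is available behind a flag; which
variant the original annotation server used is unknown.

## Synthetic-data generator

The generator produces the study conditions the analysis assumes, with full
ground truth:

* **Genome/genes.** Genes are packed round-robin into per-chromosome slots
  of width `2×105 kb + max gene length`, jittered within the slot, ≥ 250 kb
  from chromosome ends. Each gene's full annotation envelope (body ±100 kb)
  is therefore isolated, so a summit planted in a category window is
  recovered as exactly that category; infeasible packings raise a capacity
  error. Intergenic summits go to a reserved zone near each chromosome
  start, > 100 kb from every gene.
* **Peaks.** The location category of each peak is an i.i.d. draw from the
  configured mixture; non-intergenic peaks are anchored to designated bound
  genes, the first peak per bound gene forced non-intergenic and
  filter-passing so the realized bound set equals the designated one exactly
  after filtering. A configurable fraction of surplus peaks violates the FDR
  or Poisson-p threshold to exercise filtering. Scores are drawn from a
  three-bin mixture (≈35/35/30% weak/medium/strong) so all strength bins
  occur.
* **Sequences.** Summit-centred ±100 bp windows of i.i.d. uniform A/C/G/T;
  with probability per the motif mixture, one arrangement of the designated
  class is planted centred in the window (consensus half-sites, random
  spacer), at most one element per peak so classifier recall has
  unambiguous truth. Uniform background keeps the chance half-site rate
  closed-form: P(window matches RGGTCA) = (1/2)(1/4)⁵ per strand, ≈ 0.19
  expected hits per 201-bp window. For noise-free recall tests the
  `clean_background` option scrubs chance half-sites by mutating background
  bases (never planted ones) until only the planted hits remain.
* **Expression.** Detected genes draw baselines from U(200, 2000) signal
  units; UIK/DIK genes have the KO mean multiplied/divided by
  2^effect_log2fc; i.i.d. Gaussian noise (sd 40 by default) is added and
  values are clipped at zero (which never triggers for detected genes under
  the default ranges, preserving the exact null calibration of the t-test).
  Undetected genes sit below τ/4 in both groups rather than being removed,
  mirroring non-hepatic genes that still carry peaks. Label counts are
  exact rounded fractions assigned by permutation.
* **Terms.** Planted terms draw 80% of their members from a chosen DE label;
  the rest sample the universe uniformly.

Defaults mirror the emulated study design: 3 replicates per genotype,
~65% of genes detected, 8.5%/7.7% of detected genes planted UIK/DIK, a
one-log2 effect, location mixture (ingene .49, promoter .13, upstream .15,
downstream .15, intergenic .08) and a motif mixture with DR1 dominant at
12.5% — plausible fixtures shaped like the observed distributions, not
ground truth. One run seed fans out to named per-stage substreams
(`default_rng([seed, crc32(stage)])`), so stages rerun independently with
unchanged results and identical config+seed gives byte-identical artifacts.

What the generator does *not* emulate: real genomic base composition and
repeat structure (background is uniform i.i.d., so PWM-mode false-positive
rates on real sequence will be higher), overlapping gene annotations
(isolated envelopes by construction — the annotator's multi-gene precedence
is instead exercised by dense random fixtures built directly in the tests),
read-level noise, array probe effects and normalization, and correlated
expression. Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical model, not performance on real
liver data.

## Problem sizes and tolerances

The test suite runs the annotation oracle on 100 fixtures of 1,000 peaks ×
50 dense genes; motif recall on 5,000 noise-free plantings over DR0–5,
IR0–5, ER0–8 plus a 10,000-sequence ≤ 50 bp enumeration battery; mixture
recovery at ~10,000 peaks and 5,000 sequences with a ±0.02 band (the
binomial 99% bound at that n is ≈ ±0.013); null *t*-test calibration on
10,000 genes with a ±0.006 band around 0.05; and exhaustive hypergeometric
enumeration for all universes N ≤ 12. The acceptance script uses 25
annotation fixtures and 2,000 plantings and reports the same quantities.
Floating-point score ties in consensus mode are compared with a 1e-9
epsilon; TSV floats are written at 17 significant digits so round trips are
exact.

## Known limitations

* The location classifier uses gene bodies, not transcript structure; genes
  with multiple TSSs are not modeled.
* PWM-mode scanning has no statistical significance calibration (no
  q-values); the threshold is a fraction of the maximal score.
* The raw `p < 0.05` dependence rule is intentionally uncorrected; with
  ~9,000 detected genes it admits ~450 false labels under the null, exactly
  as the emulated analysis does.
* Enrichment assumes an unstructured universe; gene-length or expression
  biases are not modeled.
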