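# Methods

`tagdge` implements a tag-based digital gene expression (DGE) analysis of
the SAGE/NlaIII family: transcript abundance is measured by counting short
restriction-anchored cDNA tags, one library per condition, and candidate
pathway genes are prioritized by co-expression with anchor genes of known
function. This note documents the model, the numerical choices, and what
the synthetic data generator does and does not emulate.

## Tag model and the virtual tag database

In an NlaIII/MmeI protocol every mRNA 3' fragment yields 21-nt tags: the
palindromic NlaIII site CATG plus the 17 bases immediately downstream (the
MmeI cut offset). The mapping target is the *virtual tag database*: for
every reference gene, all sense-strand CATG sites with at least 17
downstream bases. Design choices:

* **All sites are indexed**, not just the 3'-most one. Library chemistry
  enriches the 3'-most site, but internal sites do appear (partial
  digestion), and indexing all of them makes the database a superset of
  whatever the protocol produced.
* **Sense strand only** — tags derive from oriented cDNA, and because CATG
  is its own reverse complement an "antisense tag" would simply be a
  leftward-reading window, which the extractor never emits.
* Tags containing N are excluded: they could never match a clean tag.
* Coordinates are 0-based half-open internally; reports print 1-based.

A tag present in more than one gene is *ambiguous*. Ambiguous tags count
toward library-level mapping totals (once per tag, never fractionally
split across genes) but are excluded from per-gene expression, which uses
unambiguous tags only.

## Clean-tag QC

Raw libraries are filtered to tags that are 21 nt, start with CATG,
contain no N, match no adapter (exact substring match — at 21 nt,
approximate adapter matching causes more harm than it prevents), pass a
low-complexity rule, and have copy number ≥ 2 (singletons are most likely
sequencing errors). Every removed copy is booked under exactly one reason
in a fixed precedence order (malformed → adapter → N → low-complexity →
singleton) so the accounting is deterministic and conserves the raw total.

The low-complexity rule had to be pinned down explicitly: a tag is low
complexity when its 17-nt variable region has a homopolymer run ≥ 15 or
contains at most 2 distinct bases. This is a package decision; "low
complexity" filters in tag protocols are conventionally named but rarely
defined, and the rule above flags only sequences that carry almost no
matching information.

## Mismatch-tolerant mapping

Clean tags map to the database allowing at most one substitution (Hamming
distance; no indels at this tag length). An exact hit takes absolute
priority: a tag with an exact database hit never claims 1-mismatch hits,
even in other genes. Without an exact hit, the gene set is the union over
all reference tags at distance exactly 1, found by enumerating the 63
single-substitution neighbors of the observed tag against the index hash —
exact, fast, and checkable against an exhaustive Hamming scan (the test
suite and acceptance script do exactly that on random transcriptomes with
planted 1- and 2-mismatch tags).

Per-library statistics report totals, distinct counts and percentages for
all-mapped, unambiguously-mapped and unknown tags, and for tag-mapped
genes, with percentages rounded half-up to two decimals (the convention of
the summary tables this output mirrors; note `round()`'s banker's rounding
would differ on exact halves).

## Expression and differential calls

Expression is TPM — tags per million clean tags: `1e6 * x / N`. With one
library per stage there is no replicate variance; differential expression
between libraries of sizes N1, N2 uses the Audic–Claverie statistic. Given
x tag copies in library 1, the probability of y copies in library 2 under
equal underlying expression is

    p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) ),

the posterior predictive of a Poisson count under a flat prior — a
negative binomial with x+1 successes and success probability N1/(N1+N2).
The two-sided p-value doubles the smaller tail (capped at 1). Numerical
choices:

* All pmf evaluation is in log space via log-gamma.
* **Both tails are direct log-space sums.** Computing the upper tail as
  `1 − Σ_{k<y} p(k|x)` is algebraically equivalent but loses all relative
  precision when the upper tail is tiny (catastrophic cancellation, e.g.
  x=0, y=200). The direct sum is truncated only when a geometric bound on
  the remaining terms certifies a relative remainder below 1e-18; the
  suite verifies agreement with an exact integer-arithmetic oracle to
  better than 1e-10 relative over x, y ≤ 200 across library-size ratios
  from 1:34 to 34:1, including p-values far below the double-precision
  underflow limit (compared on the log scale).
* `audic_claverie_log_p` exposes the log p-value for exactly that
  underflow regime; `audic_claverie_log_p_grid` evaluates a whole row of
  y values in one vectorized pass.

Multiple testing uses Benjamini–Hochberg step-up FDR (via statsmodels)
across all testable genes of a stage pair; genes with zero counts in both
libraries are untestable and are excluded from the BH family so they do
not dilute the FDR. A gene is called up (down) when q < 0.001 and its log2
TPM ratio is ≥ 1 (≤ −1). Zero TPM values are replaced by a floor of 0.001
TPM before taking ratios — only exact zeros; small nonzero values are used
as-is. The log2-ratio gate is deliberately `|log2| ≥ 1`: descriptions of
this threshold sometimes circulate with the inequality written the other
way, which would select the *unchanged* genes; both the direction and the
threshold are configurable (`lfc_threshold`).

Defaults: `fdr_threshold = 0.001`, `lfc_threshold = 1.0`,
`TPM floor = 0.001`.

## Candidate selection

Family members (e.g. CYP450, UDP-glucosyltransferase annotations, consumed
as an input table) are compared against anchor genes with known pathway
roles (e.g. squalene epoxidase, cucurbitadienol synthase). Profiles are
log2 TPM per stage, floored at 0.001 TPM and centered on the first stage.
A member is selected when all three gates pass:

1. differentially expressed in at least one stage pair;
2. net up-regulation across the period — last-stage minus first-stage
   log2 value > 0 (a strict-monotone variant is available; the relaxed
   gate is the default because single-library counts make per-step
   monotonicity noisy);
3. Pearson r > 0.99 to at least one anchor profile.

With only three stages, r over three points is coarse; a zero-variance
(flat) profile has undefined r and is assigned r = 0 rather than dropped,
so gate counts stay stable. Survivors plus anchors are hierarchically
clustered (average linkage on 1 − r, rows pre-sorted by label so ties
break deterministically) to produce the leaf order for heatmap rendering.

## Synthetic data generator

The generator emulates the *shape* of a three-stage fruit-development DGE
study so that every downstream stage is testable without sequencing data:

* random transcriptomes in which every gene is guaranteed at least one
  extractable CATG+17 site;
* two anchors with planted relative profiles (1.0, 1.25, 8.89) and
  (1.0, 2.85, 9.69) — i.e. 7.11× and 3.40× between stages 2→3 and 8.89× /
  9.69× between stages 1→3 — at a stage-1 abundance of 8 background units
  (`anchor_base_expression`), so their sampled profiles are tight, as
  expected for well-expressed pathway genes;
* candidates whose log2 profiles equal their anchor's plus Gaussian noise
  (default sd 0.05 — noiseless correlation exactly 1), decoy family
  members engineered to fail the gates, and planted DE genes at 8-fold
  with mirrored up/down patterns so stage totals stay balanced;
* flat background at 3× the planted scale, keeping planted genes a small
  fraction of each stage total;
* sequencing substitution errors at 0.001/base (a free parameter of the
  simulation, not an inferred value), singleton noise tags guaranteed to
  be ≥ 2 mismatches from every reference tag, N-containing tags and
  adapter contaminants.

Counts are multinomial over normalized expected expression per stage —
Poisson-equivalent at these library sizes and exactly the sampling model
the Audic–Claverie statistic assumes. Copies of a multi-tag gene pick the
3'-most tag with probability 0.8 and uniformly otherwise, so both the
enriched and the internal-site paths are exercised. Everything is
determined by `rng_seed`.

What it does **not** emulate: read-level FASTQ artifacts, quality scores,
overdispersion between biological replicates (there are none in this
design), assembly errors in the reference, and expression-dependent error
structure. Passing recovery tests therefore demonstrate correctness of
the pipeline under its own sampling model, not robustness to biological
replicate variance.

One known systematic effect: TPM renormalization couples genes, so a
planted k-fold change is recovered as k × (S_a/S_b), where S_s is the
stage's total relative expression. With defaults the distortion is ~4–6%
downward on the stage-3 ratios; the recovered anchor fold changes reported
by the acceptance script carry this compositional bias plus multinomial
sampling scatter (~2.5% CV per run, damped by averaging three replicate
simulated studies).

## Problem sizes used in tests and the acceptance script

Unit tests run at 60–300 genes and 30k–200k tags per library. The
acceptance script uses: the full x, y ≤ 200 grid against the exact oracle
at nine library-size pairs; 2,000-gene × 50-replicate null simulations at
N = 10^6; 100 seeded candidate-recovery runs at 80 genes × 200k tags; 20
random transcriptomes × 500 tags for the mapping oracle; and three full
pipeline runs at 1,000 genes × 10^6 tags per stage, averaged, for the
anchor fold-change recovery. These sizes give stable estimates at desk
scale; the generator accepts study-scale parameters unchanged.

## Limitations

* Single-library designs cannot separate biological from sampling
  variance; the Audic–Claverie test is exact for the latter only.
* Pearson r over three stages is a weak filter on its own; it is only
  meaningful combined with the DE and up-regulation gates.
* The low-complexity and adapter rules are package conventions (stated
  above), not a reconstruction of any specific vendor pipeline.
* Hamming-only matching ignores indels, which at 21 nt are rare but not
  impossible.
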