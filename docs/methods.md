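# Methods

## Scope and data flow

`varodds` implements a desk-scale variant-interpretation pipeline: VCF →
consequence annotation against a transcript model → rare-missense filter →
eight-descriptor evidence profile → Bayesian odds classification; plus two
side analyses (repeat-unit self-alignment conservation, cohort DXA
statistics) and a synthetic-data module that generates every input the
pipeline consumes. Raw sequencing, read alignment, variant calling, external
database queries, homology modelling and molecular dynamics are all out of
scope; their outputs enter the pipeline as curated input flags.

## Variant annotation

Coordinates are 1-based inclusive throughout. A `Transcript` carries its CDS
segments in transcription order, the spliced coding sequence (including the
terminal stop codon), and an optional transcript span for UTRs; construction
validates frame, splicing and translation. Only SNVs are handled — indels
are rejected at construction, which matches the intended use (cohorts where
no frameshift/nonsense calls survive filtering) and keeps HGVS generation
trivial. Consequences: codon substitution inside the CDS gives
synonymous/missense/nonsense with a one-letter HGVS p. short label
(`p.R1135C`; synonymous as `p.L3=`; nonsense as `p.Y2*`); intronic positions
within 2 nt of a CDS segment edge are `splice_region`, deeper intronic
positions `noncoding`, span positions outside the CDS `utr`. On '-'
transcripts alleles are complemented before codon lookup. A variant whose
REF disagrees with the transcript raises an error naming the position.

Limitation: a substitution destroying the terminal stop codon (stop-loss)
has no category of its own and is reported as a missense-type change
`p.*{n}{aa}`; extension semantics are not modelled.

The rarity filter keeps heterozygous missense variants in the configured
gene panel with MAF strictly below 1% (default). A missing MAF passes:
novel variants have no frequency record and must not be excluded. The
filter preserves order and is idempotent.

## Descriptor engine

The eight descriptors, in fixed order: conservation, functional domain, low
sequence complexity, structured domain, linear motif, predictor agreement,
database annotation, literature evidence. Computable ones:

* **conservation** — modal non-gap residue frequency in an alignment column;
  flag at ≥ 0.9. The 0.9 default is a package choice (the descriptor is
  usually reported only as a binary flag in published analyses); it is
  config-exposed.
* **complexity** — Shannon entropy (base 2) of residue frequencies over a
  window of ≥ 5 residues; flag (low complexity) below 2.0 bits. Entropy is
  permutation-invariant and bounded by log₂ 20 ≈ 4.32 bits.
* **linear motif** — membership of a position in, or within 5 residues of, a
  motif interval. The P-P-x-S-P regular expression covers both the PPSP and
  PPPSP spellings of the LRP-family phosphorylation motif; scanning is
  non-overlapping left-to-right.
* **predictor agreement** — positive when at least 2 of the 3 categorical
  predictors (PolyPhen-2-style ∈ {benign, possibly_damaging,
  probably_damaging}, SIFT-style ∈ {tolerated, not_tolerated}, Pmut-style ∈
  {neutral, disease}) call the variant damaging. The stability ΔΔG is
  reported but never counted: in the bundled example every ΔΔG is a
  decrease, so the value carries no discrimination between classes.

The remaining four (functional domain, structured domain, database
annotation, literature) are curated boolean inputs. Literature evidence and
the dbSNP low-frequency flag are mutually exclusive by construction, since
literature evidence supersedes the frequency class in the prior.

## Bayesian classifier

`posterior OR = (prediction + odd) × prior`, `posterior OR% = posterior/9 ×
100`, rounded half-up to two decimals. The normalization constant 9 is the
maximum merged score (4 + 5); it is the unique constant consistent with the
published percentage column of the worked example (2→22.22, 5→55.56,
6.25→69.44, 10→111.11) and is documented as a reconstruction, as is the
class banding 90/50/25/12.5 — the only simple banding reproducing every
published class. The published "62.5%" and "25%" agreement levels concern a
different axis (descriptor agreement, 5/8 and 2/8), which is computed and
reported separately per variant.

The odd score counts only d1, d2, d4, d5, d7: the predictor descriptor d6
already feeds the prediction score and the literature descriptor d8 already
feeds the prior, so counting them again would double-weight that evidence.
With prior 1 the posterior equals the merged score exactly; the posterior
percentage is monotone non-decreasing in prediction score, odd score and
prior, hence the class is monotone in every descriptor.

The bundled LRP5 example (`varodds.lrp5`) carries the published predictor
calls verbatim and a *reconstructed* evidence-flag table chosen to reproduce
the published odd scores (the source analysis reports only aggregates).
Recomputing from components reproduces the published class for all ten
variants and flags three rows whose printed cells disagree with their own
arithmetic: one posterior printed as 8.745 where merged × prior gives 8.75,
and two prediction scores that do not follow from the printed predictor
calls (including the row whose printed merged score 8 matches the
recomputed prediction 3 + odd 5 rather than its own printed prediction 2).
These are surfaced in `compare_with_published()`, never silently matched.

## Repeat self-alignment

Repeat proteins defeat ortholog-based conservation because the units diverge
within the protein; the self-analysis aligns the protein's own units against
each other instead. Unit boundaries are inputs (annotation-derived) — de
novo repeat detection is a non-goal. Alignment: BLOSUM62 (Biopython's
standard table), affine gaps with open −10 / extend −1 (a gap of length *k*
costs −(10 + *k*)), global (Needleman–Wunsch/Gotoh). Traceback ties break
deterministically: match, then gap in the second sequence, then gap in the
first. Units are aligned progressively in input order against a growing
profile — with ≤ 8 near-equal-length units a guide tree adds nothing but
nondeterminism. A residue scores against a profile column as the mean
substitution value over the column's rows, gap rows contributing the
gap-extend penalty.

Column conservation = (modal non-gap residue frequency among non-gap
symbols) × (non-gap fraction), so insertion columns present in few units
score low; the consensus symbol is the modal residue, or '-' where gaps hold
the strict majority, with residue ties broken alphabetically. Identical
units give an all-1.0 profile. Note that adding a duplicate of a unit can
*lower* a column score when the duplicated unit carries a minority residue
there; scores are guaranteed non-decreasing only when the duplicate matches
the modal residue column-wise.

## Cohort statistics

Subjects carry DXA measurements (BMD g/cm², T and Z scores in SD units) at
lumbar spine and total hip. Group comparison is a two-sided two-sample
t-test, pooled-variance by default (Welch as an option) since the classic
Student test is the conventional choice for these small carrier subsets;
both groups constant and equal yields (t=0, p=1) by convention. Summaries
report mean ± SD per field (SD 0 with a degenerate flag for n=1) and the
carrier fraction as a percent rounded half-up to one decimal
(11/128 → 8.6%). Lumbar and hip T/Z scores are compared as four separate
tests, matching the four comparisons such studies report.

## Synthetic data

All generators are pure functions of `SimulationConfig`; random streams are
split per generator by fixed offsets from the single seed
(`default_rng([offset, seed])`), so adding a generator never perturbs
existing outputs, and identical configs give byte-identical files.

* **Cohort** — ages ~ Normal(41.6, 8.7) truncated to [18, 60]; DXA fields
  normal with the published cohort moments as defaults (e.g. T_L −2.5 ±
  0.55); carrier count fixed deterministically at
  `round(carrier_fraction × n)` (11/128 by default) so fixture-level counts
  are exact, with carrier identity randomized.
* **Variant set** — `round(pathogenic_fraction × n)` variants are
  pathogenic-profile; each categorical predictor is damaging, and each
  evidence flag positive, with class-conditional probability 0.8
  (pathogenic) / 0.1 (benign) — defaults chosen to make truth recovery
  non-trivial but stable at n = 500. All MAFs < 1%. Truth labels live in a
  sidecar series, never in the tables the classifier reads.
* **Repeat protein** — a random consensus unit copied `n_units` times, each
  position substituted (always to a different residue) with probability
  `unit_mut_rate` (defaults 60 × 8 at 0.2), concatenated with exact
  boundaries; the true consensus is returned for recovery tests.
* **Toy transcript** — a 3-exon, 20-codon transcript on a 300 nt contig
  (either strand), with 20 planted variants of which exactly 7 satisfy the
  rarity filter and 13 each fail one predicate (synonymous, homozygous,
  common, off-panel, intronic/UTR/splice positions); expected annotations
  are recorded at construction.

What the generators do **not** emulate: read-level sequencing error,
linkage/population structure, realistic effect sizes of bone-density
genetics, correlated descriptors (each evidence flag is drawn
independently), or realistic amino-acid composition. Passing recovery tests
therefore demonstrates internal consistency of the pipeline under its own
generative model, not clinical performance on real cohorts.

## Problem sizes and numerical choices

Default test problem sizes: 500 variants for the recovery experiment
(balanced accuracy of class ≥ 4 vs ≤ 2 with uncertain calls excluded,
threshold 0.85), 1000 replicates for the t-test type-I check (nominal band
0.03–0.07 at α = 0.05), 8 × 60-residue units for conservation Monte-Carlo
(mean within ±0.05 of 1 − mutation rate), and exhaustive enumeration
elsewhere (all 2⁸ profiles × 3 priors × 4 prediction scores; every SNV of
the toy transcript; all pairs of ≤ 5-mers against a brute-force alignment
oracle). Percentages round half-up via `decimal` to avoid binary-float
banker's rounding; posterior ORs are reported unrounded.
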