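# Methods

## Scope and data model

`casrxkit` covers the desk side of a CasRx RNA-targeting experiment: guide
design against a supplied transcript sequence, cassette assembly, exact
Mendelian expectations for the validation crosses, and TPM-scale knockdown
quantification. It does not align reads, count features, or call
differential expression — the misexpression summary consumes boolean
significance flags produced elsewhere (or by the simulator).

All design and folding math runs on the RNA alphabet (ACGU); DNA is
accepted on input and emitted for cloning-facing files. Transcripts are
treated as single-stranded sense mRNA; there is no genomic strand or
isoform handling, so the user must supply the exact transcript to target.
Coordinates are 0-based half-open internally and 1-based closed in every
report.

## Structure prediction

Hairpin and accessibility screening uses a Nussinov-style dynamic program
that maximizes the number of nested base pairs, with a minimum hairpin
loop of `min_loop = 3` unpaired bases and G·U wobble pairs allowed by
default. The traceback is deterministic: within each subinterval the
5′-most base is paired whenever pairing attains the optimum, with its
smallest admissible partner. This is a deliberate substitution for
thermodynamic (nearest-neighbor free energy or partition function)
folding: it has no parameter tables, it is exactly checkable against
exhaustive structure enumeration (the test suite verifies equality for
all sequences up to length 12), and it captures the screening intent —
reject self-structured windows — without claiming free-energy accuracy.
Consequences of the substitution:

- **Hairpin screen.** "Strong hairpin" is operationalized as the longest
  contiguous helix (`max_stem`) in the max-pair fold of the 30-nt window;
  windows with `max_stem ≥ 5` bp are rejected. The threshold is exposed in
  `DesignConfig` because no quantitative criterion is standard.
- **Accessibility.** Each window is folded together with 50 nt of flanking
  transcript context per side (clipped at the ends), and the fraction of
  window bases left unpaired is the accessibility. A maximum-matching
  structure over-pairs relative to thermodynamic ensembles, so absolute
  values run low: on random-sequence transcripts typical windows score
  ~0.1–0.4 while windows locked in long perfect duplexes score 0. The
  default acceptance threshold `accessibility_min = 0.1` is calibrated to
  that scale — it removes duplex-buried windows, not the typical window.
  These scores rank windows within one transcript; they are not
  comparable across predictors.

## Spacer design

Windows of 30 nt are enumerated at stride 1. Filters (all inclusive
bounds, each attributed by name in the output):

| filter | rule | default |
|---|---|---|
| poly_u | longest U-run ≤ `max_u_run` | 4 nt, applied to target **and** spacer |
| gc | `gc_min` ≤ GC% ≤ `gc_max` | [30, 70] closed interval |
| hairpin | `max_stem` < threshold | 5 bp |
| accessibility | unpaired fraction ≥ `accessibility_min` | 0.1 |

The poly-U rule is applied to both orientations by default because a U-run
in the spacer itself acts as a pol-III terminator inside the U6-driven
array; `apply_u_filter_to` selects target/spacer/both. The spacer is the
reverse complement of the target window (the hybridizing orientation),
stated in output headers.

Ranking is a deterministic total order: ascending `max_stem`, then
descending accessibility, then GC closest to 50%, then 5′→3′ position.
Selection returns `n_spacers = 4` windows with pairwise gaps
≥ `min_separation_nt = 50`, chosen by exhaustive search over the top 30
ranked candidates to maximize the minimum pairwise gap (ties: better
summed rank, then 5′-most); a greedy rank-order pass is the fallback for
pathological inputs where that search is infeasible. Separation spreads
the four sites across the transcript; no positional rule beyond spacing is
imposed. The off-target scan is a sense-strand Hamming screen (pigeonhole
seeding + verification, default ≤ 3 mismatches); it is a convenience
report, not a model of CasRx mismatch tolerance.

## Cassette grammar

`assemble_array` concatenates `(DR + spacer) × 4 + DR + TTTTTTT`
(307 nt with defaults) and asserts that part annotations tile the cassette
exactly. The DR must be user-supplied and pass validation (36 nt, AAAAC
motif anywhere by default; `strict_5p` restricts it to the 5′ half). The
package ships only a synthetic placeholder DR for tests, to avoid
presenting an unverified sequence as the biological repeat.

## Genetics

The cross engine enumerates gamete combinations per chromosome with equal
probabilities, assorts chromosomes independently, removes offspring
classes carrying a lethal allele pair (e.g. CyO/CyO, TM6/TM6) and
renormalizes; probabilities are exact `Fraction`s that sum to 1. The model
assumes no recombination (balancers suppress it; Drosophila males lack
it), autosomal transgenes, and no viability differences beyond the
declared lethal classes — so observed rates below expectation are
interpreted as toxicity, not modeled. Inheritance rates pool replicates
and carry Wilson 95% intervals. The two-sample proportion test is the
pooled z-test, two-sided, continuity correction off by default; both it
and a replicate-level t-test are available because published figure
captions name the proportion test for one analysis and the t-test for
another without fully specifying the inheritance comparisons.

## Knockdown quantification

TPM is computed from counts and effective lengths, with effective length =
annotated transcript length (no fragment-length correction — a documented
simplification). Knockdown is reported as residual expression,
experimental-arm mean / control-arm mean × 100 on the TPM scale, with a
two-sided pooled-variance ("Student") t-test over per-replicate target
TPM (Welch optional). Because TPM is compositional, removing a large
target's mass inflates the remaining transcripts slightly; with the
simulator defaults (target ≈ 10% of library mass) this biases a true 2%
knockdown estimate to ≈ 2.2% — visible in recovery tests and inherent to
the TPM-ratio definition, which is labelled as such.

## Synthetic data

`simulate_counts` draws negative-binomial counts (variance μ + φμ²,
φ = 0.1 by default) around log-normal baseline means (meanlog ln 100,
sdlog 1.2), 3 replicates per arm as in the validation study design. The
target transcript gets a fixed high baseline mean (2000), reflecting that
targets are assayed at developmental stages of peak expression; in the
experimental arm it is scaled by `knockdown_factor` and a seeded 1% of
non-targets receive symmetric log-normal fold perturbations as a
collateral-activity stand-in. What the generator does **not** emulate:
library-size differences between samples, gene–gene correlation,
length-dependent counting biases, isoform mixtures, or any sequence
dependence of knockdown efficiency. Passing recovery tests therefore
demonstrates that the estimator and tests behave correctly under the
stated noise model, not that real libraries would behave identically.
Recovery tests use 300-transcript matrices over 500 seeded repetitions;
the folding equivalence tests use 1,000 random sequences of length ≤ 12,
and design-pipeline tests use 240–600-nt transcripts — sizes chosen to
exercise every code path at interactive speed.

## Numerical conventions and degenerate inputs

- Exact rational arithmetic in the cross engine; no floating renormalization.
- Proportion test with pooled p ∈ {0, 1} (identical saturated groups)
  returns p = 1 rather than NaN; t-test between identical constant arms
  returns t = 0, p = 1 (p = 0 for distinct constants).
- All-zero count columns, empty FASTA files, duplicate record ids,
  ambiguity codes, out-of-bounds windows and short transcripts raise
  descriptive errors naming the offending record/position.
- One global `--seed` governs every stochastic path; design and assembly
  are fully deterministic, and every output file carries a provenance
  header (version, seed, config hash).

## Known limitations

No guide-efficiency learning or CasRx mismatch-tolerance model; no
free-energy folding; no recombination or sex-linkage in the cross engine;
no differential-expression calling; TPM-only normalization. These bound
the claims: the package reproduces the design grammar and the analytic
expectations exactly, and recovers planted effects under its own noise
model.
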