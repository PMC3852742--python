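# Methods

This note documents the statistical models, defaults and design choices
behind circaphos, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic-data tests do and do not
establish about real data.

## Site collation

A phospho-site is identified by `(protein accession, sorted tuple of 1-based
residue positions)`. The positions of one key are the union of all
localization groups on the peptide: a confidently localized mod contributes
one position, an ambiguous localization (`T5(amb:T7)`) contributes its whole
group and flags the key ambiguous, and a multiply phosphorylated peptide
forms a single multi-position key. The last point is deliberate: each
precursor phospho-form is one quantified species, so attributing its full
intensity to every individual residue would double-count. With keys defined
this way, collation — summing abundances over charge states, missed
cleavages and repeat observations within each (condition, replicate) — is
exactly conservative: the site table total equals the peptide input total
minus explicitly skipped rows. This identity is enforced by tests and is the
reason unmappable peptides go to a skip report rather than being dropped
silently.

Peptides are located in the proteome by exact substring match. A peptide
matching several proteins is assigned to the first accession in sort order
and recorded in an ambiguity report; duplicating the row per match would be
the other defensible choice, but it breaks the conservation identity and
silently inflates totals, so we prefer the deterministic single assignment
with an audit trail. Missing cells stay missing — no zero-fill, no
imputation — and sites with fewer than 2 observed replicates in either
condition are reported as `untested` rather than receiving a fabricated
p-value. How missing LFQ values should be handled ahead of a t-test is
genuinely open; the ≥2-replicates rule is this package's choice.

## Differential testing

Abundances are arcsinh transformed (`ln(x + √(x²+1))`), which behaves like a
log at LFQ intensities but is defined at zero; no scale cofactor is applied.
The test is the classic pooled-variance Student t-test, two-tailed, on
transformed values; Welch's unequal-variance form is available via
`equal_var=False`. Fold changes are computed on *raw* within-group means, not
transformed ones, so the reported FC is the familiar intensity ratio.
Classification uses strict inequalities (`p < 0.05`, `FC > 1.5`, `FC <
0.67`): a site sitting exactly on a threshold is not significant. No
multiple-testing correction is applied by default — the criteria pair a raw
p-value with an effect-size filter — but a Benjamini–Hochberg helper is
provided for analysts who want it. Degenerate inputs are defined rather than
erroring: two zero-variance groups with equal means give t = 0, p = 1;
unequal means give |t| = ∞, p = 0.

The four classes (up/down/ns/untested) partition every table, and tightening
any threshold can only shrink the up and down sets; both invariants are
property-tested.

## Target-site prediction

The built-in scorer is an additive position-weight model over a ±7 window
centred on each S/T (Y optional): D/E score 1.0 at offsets −3…−1 — the
canonical CK1 preference for an acidic or phospho-primed patch upstream of
the acceptor — and 0.25 elsewhere in the window; a site is called when the
sum strictly exceeds 2.0. Windows truncate at sequence ends. This is a
transparent stand-in for dedicated kinase-specificity predictors, which can
be consumed instead through the TSV importer (rows are validated against the
proteome; residue mismatches and out-of-range positions are rejected with
reasons). Builtin and imported predictions satisfy the same contract and are
interchangeable downstream; a round-trip test (export builtin → import)
checks this.

## Enrichment

Both permutation tests use the add-one estimator `p = (b+1)/(N+1)`, which is
a valid p-value at any number of draws and can never return 0; the default
10⁵ draws put the reporting floor at 10⁻⁵. For the overlap-count statistic
the null redraws the differential set uniformly without replacement from the
detected universe, which is exactly the hypergeometric distribution — so an
exact tail computed by integer binomial summation ships alongside as an
independent oracle, and the Monte Carlo route is required (by test) to agree
with it within 3 binomial standard errors. Two-sided p for the count
statistic is `min(1, 2·min(p_greater, p_less))`; the fold-change shift test
uses the symmetric `|null| ≥ |observed|` form. Unseeded use is an error:
permutation results must be reproducible.

## Cross-dataset comparison

Sites are matched across experiments by site key, not peptide string, which
is robust to charge/missed-cleavage differences; a set-based matcher on
normalized peptide strings (`compare_site_sets`) is provided for legacy
tables without protein coordinates. Sites up in one dataset and down in the
other are counted as discordant, separately from "shared" — the convention
here is that shared means same direction. The chord export arranges the
overlap as a symmetric 4-group flow matrix (A_up, B_up, A_down, B_down)
whose row sums equal each dataset's classified counts.

The packaged candidate annotation table records, per predicted CK1 target
peptide among the detected responsive sites: the regulation category (both
lines / one line / neither), the closest human relative with BLAST E-value
and identity, whether knocking down that relative alters the human cellular
clock (period, amplitude, or both), and whether the mouse homolog's
transcript is clock-regulated. Homology and clock annotations are consumed
as curated inputs — nothing here runs BLAST or queries expression databases.
A display string like `ET(p1)KT(p2,3)LAELMS(p3)INMGA` carries three
localization groups and therefore counts as three sites in the summaries.

## Period estimation

The estimator fits `y(t) = b + m·t + A·e^(−λt)·cos(2π(t−φ)/τ)` by bounded
nonlinear least squares (trust-region reflective), with τ initialized on a
0.5 h grid across the search window (default 18–34 h, bracketing both
wild-type and lengthened periods) and the best fit chosen by residual RMS.
The linear baseline is estimated *jointly* with the oscillation: on a finite
grid a cosine is not orthogonal to a linear trend, so detrend-then-fit
leaves a small period bias even on noiseless data, whereas the joint fit
recovers a noiseless cosine to machine precision. A separate least-squares
detrend is used only to initialize. Optional higher harmonics are added
linearly at the fitted fundamental and affect only the residual RMS.

Rhythmicity is scored by the relative amplitude error, RAE = SE(A)/A from
the fit covariance, with a default threshold of 0.6 (conventional for
plate-based circadian screens; configurable). Simulation shows that on pure
white noise roughly 80% of traces exceed the threshold — RAE is a quality
score, not a hypothesis test, and single noise traces can occasionally fit a
spurious rhythm below it. On the standard synthetic setting (τ = 26 h,
amplitude:noise = 10:1, 96 h hourly) recovery is within ±0.2 h per trace
with |bias| < 0.05 h over 100 seeds; these sizes keep the whole recovery
study under ~15 s on one core and already give sub-0.01 h standard error on
the bias. Period estimates are invariant to positive affine transforms of
the signal (amplitude scales, RAE unchanged) and to time-origin shifts.

Group comparison is a two-tailed Student t-test on fitted periods;
dose–response reporting is deliberately non-parametric (per-dose mean ±
SD of the period shift against the matched vehicle, which appears as the
zero point by construction) — no logistic curve is fitted.

## Conservation and mutagenesis

Column profiles exclude gaps from the frequency vector and track the gap
fraction separately; information is `log2(20) − H` of the non-gap
distribution, so an invariant column scores log2(20) ≈ 4.32 bits and a
uniform 20-way column scores 0. Consensus ties break alphabetically and are
flagged. Column→position mapping counts non-gap characters up to the column;
a gap cell returns an explicit gap indicator rather than a position. The
packaged CK1 kinase-domain alignment is a *synthetic* stand-in (see the
fixture filename) constructed to have the structural properties the analysis
relies on — an invariant arginine column that maps to residue 200 of the
O. tauri row, inside a conserved block — not the real isoform sequences.

Primer verification is case-insensitive (mutagenesis primers conventionally
uppercase the mismatch), rejects ambiguity codes, checks the pair for exact
reverse complementarity, places the forward primer on the template by
minimal Hamming distance (error if the best placement has > 3 mismatches),
requires all mismatches to fall in one codon, and translates the
before/after codons under the standard genetic code. The reading frame and
the protein number of the first codon are caller-supplied, since a
template *fragment* carries no frame of its own.

## Synthetic data: what it does and does not establish

Site means are log-normal (`ln` mean 11, sd 1.2); replicate values multiply
the mean by log-normal noise parameterized by a CV (default 0.2); regulated
sites multiply the overexpression-group mean by the effect fold (default
2.5, planted in 24% up / 4% down of 156 sites — the detected-site design the
package targets, with 5 replicates per condition). Redundant peptide
variants (1–3 per site) split each cell by a symmetric Dirichlet draw so
summation restores the cell exactly; missingness is completely at random. A
`noise_seed` separate from the layout seed lets two runs share biological
ground truth while measuring with independent noise — the shared-truth
design behind cross-dataset overlap demonstrations.

These choices make the arcsinh/t-test pipeline exactly calibrated under the
null (verified: ~5% raw positives, uniform p-values), which is the point:
the generator tests the *machinery*. Real LFQ data adds what the generator
deliberately omits — intensity-dependent missingness, correlated peptide
variants, heavy-tailed outliers, mis-localized sites — so passing the
synthetic calibration and recovery suites demonstrates correctness of the
implementation, not robustness of the t-test to those violations. Likewise
the luminescence generator emulates damped cosinor rhythms with white
Gaussian noise, not the autocorrelated measurement noise or plate-position
effects of a real imaging rig. The effect size and CV defaults are
field-typical placeholders: the underlying study design reports neither.

## Known limitations

- Exact substring matching cannot place peptides across sequence variants or
  isoforms; there is no tolerant alignment.
- The built-in motif scorer is intentionally simple; it is a pluggable
  default, not a replacement for trained kinase-specificity models.
- No moderated (shrinkage) variance statistics; with n = 5 per group the
  plain t-test is what the pipeline reproduces.
- The period fitter assumes a single dominant oscillatory component within
  the search window; it does not resolve multiple simultaneous periods.
- Dose–response output is descriptive; IC50-style curve fitting is out of
  scope.
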