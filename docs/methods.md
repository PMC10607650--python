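# Methods

## Profile model and censoring

A profile is one organism under one growth condition, stored as a map from
canonical fatty-acid labels to cells. A cell is either *quantified*
(mean % of total peak area ± sd over `n` biological replicates, default
n = 3), *censored below* a reporting threshold (the `"<1"` token of GC
tables; threshold 1% by default), or *not detected* (`"nd"`). Quantified
means must lie in (0, 100] and sum to 90–102% per profile — real tables sum
to ~100% with small censored remainders. Replicate-level composition
vectors may accompany the summary; when present their per-acid mean/sd must
agree with the summary within 0.05 percentage points.

Censoring policy: `"zero"` (default) resolves `"<1"` to 0; `"midpoint"`
resolves it to half the threshold (0.5%) for sensitivity analysis. `"nd"`
is always 0. The zero policy reproduces the published DU column of the
reference dataset, which is why it is the default. SD tokens printed as
`"< 0.1"` are stored as the bound (0.1) with a flag so files round-trip;
using the upper bound makes downstream Welch tests conservative rather than
anticonservative.

## Degree of unsaturation

DU = Σᵢ kᵢ·wᵢ/100 over the profile's acids, where kᵢ is the double-bond
count of acid i and wᵢ its policy-resolved percentage. Percentages enter as
printed — no renormalization — because they are already fractions of total
peak area and the undetected remainder is small by construction. DU is
linear in composition (moving x points from a saturated acid to a triene
changes DU by exactly 3x/100) and lies in [0, 3] for profiles containing
only acids with ≤ 3 double bonds.

## Weighted average melting temperature

WAMT = Σᵢ wᵢ·T_m,i / Σᵢ wᵢ over the acids with a melting point in the
table, i.e. weights are renormalized over covered acids; the covered
fraction of total resolved mass is reported as `wamt_coverage`. Whether the
original WAMT convention renormalizes is not documented anywhere we could
verify; renormalization is this package's explicit choice because it keeps
WAMT a proper weighted mean (bounded by the covered acids' melting points)
regardless of table coverage. On the packaged dataset coverage is 1.0
everywhere, so the choice does not affect the shipped numbers.

The default melting-point table covers the ten acids of the reference
dataset with pure-compound values from standard physical-chemistry
references (per-entry provenance notes in
`src/fametrics/data/melting_points_default.tsv`). Literature melting points
for the unsaturated acids vary by 1–2 °C between sources, and the
3-hydroxystearic entry is flagged low-confidence (it can be excluded via
`MeltingPointTable.without_hydroxy_acids`). Consequently absolute WAMT
values are not expected to match any particular published column exactly;
orderings and condition differences are robust to table choice, and those
are what the tests assert (rank correlation 0.96 against the published
column; the published values were evidently computed from a table a few
degrees offset from ours). A validity check enforces the physical ordering:
within a chain length, melting point strictly decreases with double-bond
count.

Display rounding follows the field's convention: DU to 2 decimals, WAMT to
1; all internal computation is at full precision.

## Condition contrasts

`delta_matrix` subtracts mean percentages (zero censoring policy) between
two conditions, organisms × acids, positive = more abundant under the first
condition. A cell is *not applicable* (NaN, grey in heatmaps) exactly when
the acid is undetected or censored in **both** conditions; a
trace-to-quantified transition is a real change and keeps the cell
applicable with the trace side resolved to 0. Columns are ordered by chain
length, then double-bond count. `normalize_deltas` divides each organism's
row by its maximum absolute applicable delta (sign-preserving, row-
comparable: every non-degenerate row peaks at ±1); this max-abs choice is
the package's own, made because it keeps within-organism sign structure
readable across organisms of very different effect magnitude; a per-row
z-score variant is available. All-zero rows are left unchanged, which makes
the max-abs normalization idempotent.

`replicate_test` is Welch's two-sided unequal-variance t-test computed from
summary statistics (mean, sd, n per group) via
`scipy.stats.ttest_ind_from_stats`; n ≥ 2 per group is required and two
zero-sd groups are rejected as degenerate. Per-acid p-values in
`adaptation_summary` are uncorrected by default — matching the per-acid
"p < 0.05" reporting convention of FAME studies — with an optional
per-organism Benjamini–Hochberg adjustment.

`adaptation_summary` classifies each organism's WAMT change as
*fluidization* (ΔWAMT < −tol), *solidification* (> +tol) or *unchanged*,
with tol = 0.05 °C by default. Note the default tolerance is a numerical
guard against ties, not a noise floor: with 3 replicates and realistic
replicate scatter the null distribution of ΔWAMT has a standard deviation
near 1 °C, so under the null most organisms will be classified as changed
unless the tolerance is raised to the scale of the replicate noise. Users
wanting a noise-aware "unchanged" call should set `tolerance` to ~2× the
expected null sd of ΔWAMT.

## Synthetic data generator

The generator emulates the reference study design: for each organism,
condition means are baseline + a signed, zero-sum effect vector (CO₂
condition: mass moves from oleic and palmitic acid into linoleic/linolenic,
defaults −7/−3 → +4/+6 percentage points; warm condition: the reverse
movement). Replicates are condition mean + independent per-acid Gaussian
noise, clipped at zero (trace acids can vanish, mirroring `nd`), then
re-closed to sum to 100%. Default noise scales with abundance
(0.1 × mean, clipped to the 0.1–8 percentage-point range seen in replicate
FAME tables). Seeding uses one master `SeedSequence` with per-organism
spawned child streams, so enlarging a set never reshuffles existing
organisms.

What the generator does **not** emulate: the closure-induced negative
correlation structure of real compositions beyond the single renormalization
step, replicate-level heteroscedasticity from chromatographic integration,
batch effects, or any mechanistic desaturase response. Passing calibration
tests therefore demonstrate correctness of the statistics under independent
near-Gaussian replicate noise with closure, not robustness to every
property of real GC data.

## Statistical calibration, problem sizes, numerical choices

The type-I calibration check runs 100 organisms × 10 acids = 1000
zero-effect cells at n = 3 and verifies the Welch rejection rate at
α = 0.05 falls inside the binomial 95% CI around 0.05. Welch's test with
the Welch–Satterthwaite df is known to be slightly conservative at very
small n (its true size at n = 3 is ≈ 0.035 under normal equal-variance
sampling), so the measured rate sits near the lower edge of that band. The
power check uses effects ≥ 3× the noise sd at n = 10 (30 organisms), where
sign recovery exceeds 0.9 comfortably. The oracle-equivalence check
compares DU against an independent brute-force sum on 1000 Dirichlet-drawn
compositions at 1e-12 absolute tolerance — DU is an exact linear
functional, so only floating-point noise separates the two routes.

Degenerate inputs are errors, not silent values: empty profiles, zero
melting-table coverage, both-sd-zero tests, n < 2 groups, malformed labels
(position count ≠ declared bond count, positions ≥ chain length), decimal
commas in data files. Absence of a melting-point entry is a value (`None`),
not an error, so callers control renormalization.

## Known limitations

* Published WAMT values cannot be reproduced exactly without the original
  melting-point table; all WAMT claims are ordering/sign-based.
* Four published DU cells of the reference dataset (one organism's CO₂ row
  and all three rows of another) disagree with recomputation from their own
  published compositions by 0.1–0.3; they are flagged `du_discrepant` in
  the packaged reference and excluded from exact-agreement checks rather
  than forced.
* Welch tests from summary statistics cannot model replicate pairing or
  non-normality; with n = 3 they are low-powered and slightly conservative.
* The wide-format reader treats an empty cell as "not detected"; the
  distinction between "not measured" and "not detected" is not
  representable.
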