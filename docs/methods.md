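# Methods

## Scope and data model

The pipeline starts at the identified-compound table: a compound × sample
matrix of relative abundances in percent of total chromatographic peak area,
with replicate structure stored as (mean, sd, n) and a boolean
detection mask. Raw instrument output (mzML/CDF), spectral library matching
and peak integration are upstream of this package. A cell parsed as 0 is
treated as not-detected by default (configurable), because an undetected
compound must carry odor activity exactly 0; not-detected cells store
abundance exactly 0. Per-sample sums of detected abundances may fall below
100% (the identified fraction of a normalized chromatogram) but never exceed
it beyond floating tolerance.

Compound names are matched between the composition table and the threshold
table by exact comparison after Unicode NFC normalization, case-sensitively.
No fuzzy matching is offered: a silently mismatched name corrupts every
downstream odor-activity value, which is strictly worse than a visible
exclusion.

## Threshold resolution

Odor thresholds arrive as a multimap: several reports per compound, each
tagged with its medium. Resolution applies, in order:

1. medium priority — air-medium thresholds (mg/m³) are used when any exist;
   water-medium values (mg/kg) are the fallback;
2. averaging — the arithmetic mean of the reports in the selected medium.

The medium filter is applied *before* averaging (the alternative — averaging
across media — mixes units and was rejected). Threshold magnitudes are used
in their source units and never converted between media; the ROAV ratio
below therefore mixes mg/m³ and mg/kg denominators exactly as the source
threshold compilations do. This is deliberate: it reproduces the arithmetic
convention of published ROAV tables, and because ROAV is self-normalized
within a sample, a consistent choice of units per compound is what matters.
Compounds with no threshold report at all are excluded from ROAV and listed
per profile (`excluded`), mirroring the reality that public threshold
compilations cover roughly half of a typical terpenoid-rich volatilome.

## ROAV and classification

For sample *s*, let r_i = C_i / T_i over detected, thresholded compounds.
The reference is argmax_i r_i (ties broken lexicographically on compound id,
so output is deterministic), and ROAV_i = r_i / r_ref × 100. The published
alternative of taking the highest-*concentration* compound as reference is
available behind `reference_rule="conc-max"`; it is not the default because
on the bundled dataset only the C/T-argmax rule reproduces the published
ROAV-100 assignments (humulene for F023 rather than the far more abundant
but less potent β-caryophyllene).

ROAV is computed on replicate means, matching the single printed value per
cultivar in published tables. Classification reads the inequalities
literally: key if ROAV ≥ 1.0, modifier if 0.1 ≤ ROAV < 1.0, negligible in
(0, 0.1), absent at exactly 0. Cross-sample flags: *universal-key* (key in
every sample), *sample-specific-key* (key in exactly one),
*chemotaxonomic-marker* (detected in exactly one sample and key there).

Properties guaranteed by construction and verified by test: ROAV ∈ [0, 100];
the reference scores exactly 100; rescaling all abundances in a sample by a
common factor changes nothing; raising a non-reference compound's abundance
never lowers its ROAV.

## Detection sets and composition

"Shared" means detected in every sample; "unique" means detected in exactly
one. The terpenoid filter covers mono- and sesquiterpene hydrocarbons plus
their oxygenated forms — the oxygenated forms are required, e.g. an
accession-specific C15H26O alcohol counts toward a cultivar's unique
terpenoids. Chemical classes come from the input file's class column; the
bundled dataset assigns them by molecular formula (C10H16/C10H14 →
monoterpene hydrocarbon, C15H24 → sesquiterpene hydrocarbon, C10H18O →
oxygenated monoterpene, C15H24O/C15H26O → oxygenated sesquiterpene, plus
the aliphatic classes and the lactone). Inconsistencies between a census
claim and the table itself (the bundled dataset's F054 column has 8 unique
compounds where the accompanying census text claims 7) are surfaced as
warnings-level diagnostics, never silently corrected.

## Sensory statistics

Panel scores are pooled over assessors and sessions as independent
observations (plain one-way layout). A mixed model with an assessor random
effect would be defensible but is out of scope; with a trained,
ISO-screened panel the assessor effect mostly shifts all samples equally and
cancels from the contrasts of interest. Aggregation reports mean, sd (n−1)
and n per sample × attribute cell.

Per attribute, a one-way fixed-effects ANOVA tests sample differences; the
degenerate case of zero within-group variance with unequal means is reported
as (F = ∞, p = 0) rather than an error. Post hoc options:

* **Tukey HSD** (default, α = 0.05) — studentized-range test on all pairs;
* **Duncan's multiple-range test** — stepwise: means are ordered, a pair
  spanning p ordered means is tested at the protection level
  1−(1−α)^(p−1) with the studentized range on p means, harmonic-mean n for
  unequal groups, and a range nested inside a non-significant range is
  itself non-significant.

Pairwise decisions are rendered as a compact letter display via
insert-and-absorb: start with one letter column holding all samples; each
significant pair splits every column containing both members; columns that
become subsets are absorbed. Letters are ordered so "a" attaches to the
highest mean. The display is exact: two samples share a letter iff their
comparison is non-significant (verified against brute-force significance
graphs for up to five groups).

## Multivariate integration

PCA is computed by explicit eigendecomposition of the covariance
(`preprocessing="center"`) or correlation (`"zscore"`) matrix — the matrices
here are tiny (≤ tens of variables), and an explicit solve removes the
convergence nondeterminism of iterative SVD. Components are ordered by
decreasing variance; each loading column's largest-magnitude element is made
positive (published loading plots define no sign convention, so one is
imposed for reproducibility). Constant variables under Z-scoring are set to
zero and flagged.

The joint sensory–chemical PCA column-concatenates the sample × attribute
means and the sample × compound means, Z-scores every variable across
samples (making the two blocks commensurable), and decomposes the result;
each variable carries a block label. By default only key odorants (tier key
in at least one sample) enter the compound block and the cluster heatmap.

Co-localization of a (compound, attribute) pair reports:

* **θ** — the angle between the two variables' loading-plot vectors in the
  leading component plane (default 2 components). Vectors are eigenvector
  entries scaled by √(component variance): the variable-correlation plot
  geometry, chosen because under it the angle between arrows encodes the
  inter-variable correlation exactly when the retained components carry the
  full variance (with 3 samples and 2 components they always do). Angles
  between unscaled eigenvector rows do not have that property — they are
  stretched by the anisotropy of the component variances.
* **r** — the Pearson correlation of the two variables' raw values across
  samples, with a `small_n` caveat flag below 5 samples (3 cultivar means
  give r one degree of freedom; the flag is the honest qualifier).

A pair is co-localized when θ < θ_max (default 10°) and r > r_min (default
0.9). Cluster heatmaps Z-score each compound row (constant rows become zero
and are flagged) and order rows and columns by agglomerative clustering,
Euclidean distance with average linkage by default — the published analyses
name no metric, and this pairing is the common default for metabolite
heatmaps.

## Synthetic data generator

The generator emulates the statistical shape of a three-cultivar fruit
volatilome study: 49 compounds whose class mixture matches a
terpene-dominated profile; 19 compounds shared by all cultivars, (1, 7, 4)
cultivar-unique blocks, the remainder detected in two of three; log-normal
base abundances (median ≈ 0.6% with log-sd 1.3, spanning roughly 0.04–34%
after normalization) with cultivar-level log-normal jitter (sd 0.4);
triplicate measurements with a configurable replicate CV (default 0.10)
normalized to percent within each replicate; thresholds log-uniform over
0.005–40 with 50% coverage, a 20% water-medium fraction and occasional
multiple entries; and a 12-assessor × 3-session × 7-attribute panel with
per-assessor bias (sd 0.5) and residual noise (sd 0.8) on a 0–10 scale,
truncated to the scale bounds. Default per-cultivar attribute means encode
three chemotypes (woody-pungent, sweet-aromatic, fresh-herbaceous) with the
dominant intensities near 8 and the recessive ones near 3.

Planted structure, all recorded in a `GroundTruth` object:

* **tier markers** — a compound in a cultivar's unique block receives a
  threshold solved analytically from the pre-noise abundances so its ROAV
  lands mid-tier (e.g. 4.0 for a key marker), at least a factor 2 from the
  tier boundaries; infeasible placements raise before any sampling.
* **linked pairs** — a shared compound's expected abundance is set to
  slope × attribute mean per cultivar (default slope 0.4% per intensity
  unit, with optional multiplicative link jitter). Expected per-cultivar
  totals are then equalized by rescaling the non-linked compounds, because
  closure to percent divides by a cultivar-dependent total and would
  otherwise bend the planted linear relation even at zero noise.
* **letter patterns** — derived from the attribute means with a separation
  threshold (default 0.75 intensity units) between "truly different" and
  "tied" cultivars; meaningful when the means are designed with gaps that
  are either zero or comfortably larger than the threshold.

Every draw comes from a single `numpy.random.default_rng(seed)` stream, so
output files are byte-identical across runs and platforms.

`recovery_report` scores pipeline output against the truth: reference-match
rate, tier accuracy (overall and key-tier), letter-pattern match, and
co-localization precision/recall over the evaluated pair list. Because
chance r > 0.9 across three samples is common, precision is only meaningful
when the evaluated pairs include designated null controls; the test suite
evaluates planted pairs plus an equal number of unlinked shared compounds.

**What passing these tests shows — and does not.** The generator plants
clean structure: log-normal abundances, exactly linear compound–attribute
links, Gaussian panel noise, no retention-time drift, no co-elution, no
identification errors, no assessor drift or scale-use differences. Recovery
there validates the *computations* (threshold resolution, normalization
arithmetic, test statistics, letter assembly, loading geometry); it does not
certify performance on real chromatograms, whose failure modes are upstream
of this package's inputs.

## Numerical and testing choices

* ROAV equals an independent brute-force oracle to 1e-12 on random profiles;
  the bundled dataset's 24 × 3 published ROAV values reproduce within 0.05
  absolute (printed inputs are rounded to two decimals; observed residuals
  are ≤ 0.03).
* Sums-of-squares, PCA reconstruction, variance conservation and Z-score
  identities are asserted at 1e-9; loading orthonormality at 1e-8; angles
  against the arccos oracle at 1e-9 degrees (1e-5 at the 0°/180°
  degeneracies, where arccos loses precision).
* Stochastic recovery studies are seeded and sized for a desk machine:
  200 runs for the letter-pattern study (three groups, n = 36, sd 0.7),
  100 seeded datasets for co-localization recovery at 15% replicate CV.
* Writers emit a fixed column order and shortest-round-trip decimal floats,
  so write∘read is the exact identity and repeated runs are byte-stable
  (hashes recorded in the pipeline manifest).

## Known limitations

* Pearson r across three cultivar means is fragile; the small-n flag is
  reported but no inference is attached to r.
* Duncan's test is implemented for parity with common practice in food
  science; Tukey HSD remains the default and the statistically safer
  choice.
* The ROAV model ignores odorant interactions (synergy, masking) and uses
  thresholds whose media are mixed by convention; rankings are
  within-sample prioritizations, not perceptual predictions.
* No rotation (varimax etc.) is applied to PCA solutions; loading-plane
  angles therefore depend on the unrotated solution.
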