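# Methods

## Screen model and scoring

The screen compares each deletion strain's drug response to the
wild-type response on the same batch of plates. For a spot grown at
concentration *c* in replicate *rep*, the scorer forms the relative
growth ratio

    r = (g_strain(c, rep) / g_strain(0, rep)) / (g_wt(c, rep) / g_wt(0, rep))

Normalising by the strain's own untreated growth removes constitutive
growth-rate differences between deletion strains (slow growers are not
penalised); normalising by the wild-type removes the concentration's
overall potency. r = 1 means the strain responds exactly like
wild-type.

The ratio is graded onto the screen's ordinal scale with the default
bins

| r | score |
|---|---|
| ≤ 0.10 | 3 |
| ≤ 0.35 | 2 |
| ≤ 0.60 | 1 |
| (0.60, 1.30) | 0 |
| [1.30, 1.75) | −1 |
| ≥ 1.75 | −2 |

Edges on the sensitive side are inclusive (a ratio exactly on a
boundary takes the stronger sensitivity grade); the wild-type bin is
open at 1.30 so that boundary belongs to the resistant side. The
original screen graded spots visually, so the bin positions are this
package's quantitative calibration, chosen so that wild-type-like
growth scores 0 and near-total growth loss scores 3; all boundaries are
config-exposed.

Spot scores are summed over concentrations and replicates into the
final score (range [−12, 18] for the 3 × 2 design); final score ≥ 3 ⇒
sensitive, ≤ −2 ⇒ resistant. Unscoreable spots (strain failed to grow
untreated, or a failed reference) are dropped, not zeroed, and a strain
with fewer than half its designed spots scored is reported "no-data"
so a single surviving replicate cannot impersonate a full screen.

**Wild-type reference.** The scorer defaults to the *batch-pooled*
wild-type reference: the mean of the per-plate wild-type control spots
within each concentration × replicate batch. With a single wild-type
well per plate, noise in that one spot would propagate into the ratio
of all ~94 strains on the plate; pooling ~50 plate controls makes the
reference essentially noise-free while plate QC still polices each
plate's own controls. `wt_reference="plate"` restores strict same-plate
normalisation (with batch fallback when the plate control failed).

**Plate QC.** A plate/replicate passes when its wild-type control
grades 0 at the lowest concentration (no overdose/artifact) and its
spt3Δ-like sensitive control grades ≥ 1 at the highest concentration
(drug active). Failing plate/replicates are excluded from aggregation.

## Liquid validation (NTGV)

NTGV = (OD_strain,T / OD_wt,T) / (OD_strain,U / OD_wt,U) from endpoint
OD600 after 20 h; ≤ 0.7 sensitive, ≥ 1.2 resistant (both inclusive).
Replicate ODs are averaged on the OD scale before the double ratio is
formed; a `per_replicate_ratios` flag switches to mean-of-ratios (the
two readings were not distinguishable from the original description;
mean-of-ODs is the default because it is the lower-variance estimator
for multiplicative noise). The pre-reading 1:2 dilution cancels in all
ratios and is not modelled. Fraction-of-control (treated/untreated, no
wild-type term) is reported as mean ± sample SD over replicates.

## Enrichment

Upper-tail hypergeometric probability P(X ≥ k) per term (k hits among
the K universe members of the term, n hits, N universe), evaluated via
the log survival function; BH step-up adjustment jointly across all
retained terms. The universe is explicit (all screened strains present
in ≥ 1 annotation set by default, configurable); term sizes outside
[3, 500] after universe intersection are dropped. Only
over-representation is tested. Published enrichment tables from
DAVID-style tools depend on that tool's own background universe, so
numeric p-value comparisons across tools are not meaningful; the
machinery here is validated against exhaustive enumeration and Fisher's
exact test instead.

## Cytometry

**G0/G1 gating.** A two-component Gaussian mixture is fitted to log DNA
content (deterministic: three k-means initialisations, fixed state);
the gate is the midpoint of the fitted 1C and 2C log-centres, making
the fraction invariant to global rescaling of the fluorescence axis.
S-phase events are split by the gate rather than modelled — adequate
for arrest phenotypes, not for S-phase kinetics. If the two modes are
not resolvable (fitted centres closer than twice the larger fitted SD)
the sample is unevaluable unless the instrument's 1C position is
supplied, which handles fully arrested single-peak populations.

**Cell death.** PI-positivity threshold = 99.5th percentile of the
matched untreated control's PI intensities, so the gate has an
intrinsic ≈0.5% false-positive tail (visible when gating a control
against itself). Controls need ≥ 200 events.

**Budding index** = budded / (budded + unbudded).

**Group comparisons.** One-way ANOVA (scipy `f_oneway`) with
Tukey–Kramer pairwise post test (scipy `tukey_hsd`: studentized-range
distribution with the harmonic-mean correction for unequal group
sizes), two-sided, α = 0.05. For two groups the Tukey p equals the
pooled-variance t-test p (q = √2·|t|); for k ≥ 3 the adjusted p is
never below the unadjusted pooled-t p — both are test invariants.

## Synthetic data generator

The generator emulates the study design: 4852 library strains arrayed
on 96-well plates (wild-type at A1, sensitive spt3Δ-like control at
H12 — positions are a package convention, configurable), spotted at
0/55/67.5/72.5 µM in 2 biological replicates (~39.6k growth values).

Growth is Hill-type inhibition g = g0 / (1 + (c/IC50)^h) with h = 6 and
class IC50s 45 µM (sensitive), 78 µM (wild-type/unaffected), 200 µM
(resistant), chosen so that at the screen concentrations the noise-free
ratios fall inside the intended score bins: a sensitive strain grades
2/2–3/3 across the three concentrations (final score ≈ 14, matching
the top observed grades of real screens), a resistant strain grades
0/−1/−1 (final ≈ −4), an unaffected strain 0 everywhere. Untreated
baselines vary strain-to-strain (lognormal, CV 0.15) to exercise the
self-normalisation; each spot then takes independent multiplicative
lognormal noise of CV `noise_cv` (default 0.1). Liquid culture follows
logistic growth to 20 h with the growth rate scaled by the same Hill
factor (OD0 = 0.005, K = 1.0, r0 = 0.5/h — an untreated culture reaches
stationary phase by the endpoint). The wild-type reference in a liquid
batch gets a full column of 12 replicate wells because its noise enters
every strain's NTGV; with triplicate wild-type wells only, the shared
reference draw alone would move the batch's NTGVs by ±8% (CV·√(2/3)).
DNA content is a 1C/2C normal mixture (peak CV 8%, optional uniform
S-phase bridge, default weight 0 in the generator signature, 5% in the
time-course driver); PI uptake is Bernoulli with a separated lognormal
positive mode.

What the generator does **not** emulate: plate spatial gradients,
colony-morphology differences, drug instability over incubation,
carry-over between spots, cytometer spillover/debris, or any coupling
between agar and liquid phenotypes beyond the shared IC50. Passing
recovery tests therefore demonstrates the pipeline's correctness under
the stated noise model, not robustness to those real-data artifacts.

## Numerical and design notes

- All stochastic operations take explicit seeds (`numpy.default_rng`);
  identical configs reproduce outputs byte-for-byte, asserted via
  SHA-256 digests in the pipeline manifest.
- Resistant calls are intrinsically noisier than sensitive calls: the
  0-bin's resistant edge (1.30) sits ~2.6 lognormal SDs from r = 1 at
  spot-noise CV 0.1 (two noisy measurements per ratio with the pooled
  reference), so a few percent of unaffected strains cross it in ≥ 2 of
  6 spots and the called-resistant list carries a substantial
  false-discovery fraction at full screen scale. The sensitive side has
  three grades and a farther boundary, so sensitive calls are clean.
  This asymmetry is a property of the ordinal design itself.
- Problem sizes in the test suite and acceptance script (500-strain
  benchmark screens, 10k-event cytometry samples, 1000 null ANOVA
  simulations) are chosen to give sampling error comfortably below the
  asserted tolerances.
- The hit-count and validation-rate checks against the study's own
  deposited tables require those supplementary files under
  `data/published/` (schemas documented in `tests/test_acceptance.py`);
  the package does not redistribute them.
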