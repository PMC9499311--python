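# Methods

## The repair model

A genomic region's lesions are assumed to disappear by an irreversible
two-state (damaged → repaired) transition proceeding independently in every
cell of the population.  Treating the repair events at a locus as a Poisson
point process with a power-law cumulative rate, the probability that a
competent cell has repaired by time t is `1 − exp[−(t/τ)^m]`; allowing that
only a fraction θ of cells ever repair the lesion gives the repaired
fraction

    f(t) = θ · (1 − exp[−(t/τ)^m]),

the KJMA form.  Equivalently, repair times of competent cells follow a
Weibull distribution with shape m and scale τ — the unique law consistent
with f — which is what the simulator draws from.  The instantaneous repair
rate is the analytic derivative

    f'(t) = m θ t^(m−1) τ^(−m) exp[−(t/τ)^m],

which integrates back to θ and is the quantity compared with excision-type
(ongoing-repair) data.

Assumptions worth keeping in mind: one repair mechanism per region (the
mixture of fast transcription-coupled and slow global repair is visible
only when averaging regions, not inside one fit); spatially constant
kinetics within a region; no new lesion formation after irradiation ends;
independence between cells.

## Fitting

For a fixed θ the model linearizes by a double logarithm,
`ln(−ln(1 − f/θ)) = m ln t − m ln τ`, so each candidate θ costs one
ordinary least-squares line through as few as three points.  θ is searched
on a grid from a floor (0.5 for transcribed/TCR regions, 0.4 otherwise —
transcribed regions are known to repair more completely, and the floor
keeps the search out of a regime where θ trades off against m) to 1.0 in
steps of 0.01, and the fit with the highest adjusted R² is kept.

Numerical conventions, chosen where the procedure itself leaves freedom:

- **Adjusted R²** is computed in the linearized space with one predictor:
  `1 − (1 − R²)(n − 1)/(n − 2)`.  The regression actually solved lives in
  that space and n can be 3.  The original-space R² of the back-transformed
  curve is reported alongside for transparency.
- **Zero-repair points** have no double logarithm and are dropped; the
  number of points actually used is recorded and a course with fewer than
  two usable points is marked unfittable rather than extrapolated.
- **Infeasible θ** (θ not strictly above every observed fraction) is
  skipped; at the grid endpoint θ = 1, fully repaired points (value = 1)
  are dropped like zero points.
- **Ties** in adjusted R² (within 1e−12) resolve to the smallest θ, making
  the search deterministic.
- **Two-point fits** interpolate exactly; they are flagged degenerate and
  retained, since the downstream parameter filter usually removes them.
- **Parameter filter**: fits outside m ∈ [0.5, 5] or τ ∈ [20, 200] minutes
  are excluded from association analyses (configurable bounds).
- Strand-merged regions may either pool both strands' counts before the
  repair transform (the pipeline default — the transform's ratio makes
  depth cancel) or pool both strands' (t, value) points into one
  regression via `pool_time_courses`; the fit is invariant to duplicating
  points, so the two agree on symmetric strands.

## Signal processing

Counts are normalised by the number of available dipyrimidine sites
(TT/TC/CT/CC on the respective strand, N-containing pairs excluded).  The
repair transform `R(t) = (ΣS(0) − ΣS(t))/ΣS(0)` cancels region length,
sequencing depth and the normalisation itself, so the normalisation only
matters for comparing intermediate outputs across regions.  When two
experimental courses with separate 0-minute references exist (e.g. {0, 60}
and {0, 20, 120} minutes), each course is converted with its own reference
before the fractions are merged, removing course-specific depth.
Rectification clips the first fraction at 0 and each later one at its
predecessor (no new lesions form), and is idempotent.  The data-only rate
surrogate is the forward finite difference of the rectified course with
R(0) = 0 prepended, so the first interval is (0, 20]; for comparison with
excision samples, the (0, 20] rate is matched to the 5- and 20-minute
samples and (20, 60] to the 60-minute one.

## Segmentation

A transcription unit is called TCR-supported when its transcribed strand
shows more than 20% repair (rectified) within the first 20 minutes — the
threshold is a parameter.  TCR TUs contribute six stranded subregions
(TS/NTS × start/centre/end, thirds in transcription orientation, remainder
nucleotides to the centre); everything else, including non-TCR TUs, merges
across strands into non-TCR blocks.  The alternative "gene" mode partitions
into whole-TU TS/NTS plus intergenic blocks.  Coordinates are 0-based
half-open throughout; the TS is taken as the template strand (opposite the
TU's annotated strand).  Same-strand overlapping TUs are resolved by
keeping the longer one (logged); regions shorter than 9 nt are flagged
fit-ineligible.  The centromere/telomere covariate is
`2·min(|x−c|, |x−t|)/|c−t|` with x the region midpoint, 1 at the point
equidistant from both landmarks.

## Association testing

Distance correlation is implemented as the biased V-statistic: pairwise
absolute-difference matrices are double-centered and the normalised mean
elementwise product taken; it is non-negative by construction, 1 for exact
linear dependence, and 0 by convention for constant input.  Model
predictions enter as the square root of the rate, damping the variance
growth of large derivatives.

The feature-association procedure: trim the feature to its lower 95th
percentile (skewed genomic covariates carry heavy right tails; disabled
for approximately normal features such as nucleosome density), median-split
into balanced high/low classes with ties at the median alternating between
classes, z-score the (m, β, θ) triples column-wise, and then for each
k ∈ {5, 10, 20, 50, 100} and each of 100 repeats draw a stratified 80/20
train/test split and score a kNN classifier trained on true labels against
one trained on labels shuffled within the training set.  A k passes when a
one-sided Welch t-test (true < random) beats α = 1e−7 — the unpaired
variant over the two samples of repeat errors — and at least 90% of the
true errors are below 0.5; an association needs 3 passing k of the 5.
kNN determinism: Euclidean distance, equal-distance neighbours ordered by
training-row index, tied votes fall back to the nearest neighbour's class.
The 80/20 split fraction, the unpaired t-test and α are configurable; the
procedure is exactly reproducible from one integer seed.  No correction is
applied across features beyond the 3-of-5 rule.

## The simulator

Each region is an independent cells × positions grid: a position carries a
lesion with probability `damage_prob`, a lesion is repair-competent with
probability θ, and competent lesions draw Weibull(m, τ) repair times.
Damage counts at a sample time are the unrepaired lesions per position;
excision counts are the repair events inside a window (default 10 minutes)
around each excision sample time; optional Poisson resampling emulates
sequencing-depth noise and is off by default so analytic checks stay
exact.  Reference conditions are 2,000 cells × 200 positions per region,
CPD samples at 0/20/60/120 min and excision samples at 5/20/60 min, and
`damage_prob = 0.05` — sparse lesions, roughly 20,000 per region, putting
the per-time-point sampling error on the repair fraction near 0.004.  The
dataset writer places lesions on actual dipyrimidine sites of a generated
random chromosome and gives alternating TUs fast TCR-like transcribed-
strand kinetics (m ∈ [0.9, 1.4], τ ∈ [25, 60] min, θ ∈ [0.75, 0.95])
against slow GGR-like kinetics elsewhere (m ∈ [1.5, 3], τ ∈ [60, 150],
θ ∈ [0.5, 0.8]), so segmentation and classification have structure to
recover.

What the simulator does *not* emulate: read-level noise and mappability,
lesion-formation sequence bias beyond dipyrimidine placement, neighbouring-
region crosstalk, chromatin state, replication or transcription shutdown,
and any coupling between cells.  Passing tests therefore demonstrate that
the estimation and testing machinery is correct and well-calibrated under
the model's own assumptions — not that real repair obeys those assumptions.

## Problem sizes and verification

The test suite verifies parameter recovery at the reference scale (200
regions × 2,000 cells × 200 positions; median errors ≤ 0.15 on m, ≤ 10% on
τ, ≤ 0.05 on θ), exact noiseless round trips (100 random triples to 1e−3
relative error), derivative/quadrature consistency (1e−6), agreement of the
distance correlation with an explicit-loop oracle (1e−10), power and
specificity of the significance procedure at reduced settings (20 repeats,
k ∈ {5, 10, 20}, 20 procedure replicates), the early (<20 min) vs late
(20–60 min) group-mean rate-peak ordering of TCR-like vs GGR-like
simulated regions, and the requirement that the model's sqrt-rate
out-correlates the finite-difference surrogate against excision-like
tracks in ≥90% of noisy replicates.  `scripts/acceptance.py` recomputes all
of these quantities from fresh seeded simulations; smaller grids in the
examples and end-to-end tests (tens of TUs, hundreds of cells) keep the
whole suite fast while the acceptance-scale runs use the full reference
conditions.

## Known limitations

- With only three positive time points, θ and (m, τ) are weakly identified
  for slow regions (f(120) far from θ); the grid floor and the parameter
  filter mitigate but cannot remove this.
- The TCR threshold (20% at 20 minutes) is a heuristic on rectified
  fractions; borderline TUs can flip classification under noise.
- The excision-window surrogate compares counts, not depth-normalised
  signal; cross-region comparisons inherit lesion-count differences.
- The biased V-statistic distance correlation is positively biased at
  small n; null values near 0.1–0.2 at n ≈ 200 are expected and are why
  orderings, not absolute values, are tested.
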