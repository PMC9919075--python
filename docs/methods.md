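# Methods

This note documents the models, parameter choices and numerical
decisions behind the package, and what the synthetic benchmark does and
does not demonstrate.

## Fingerprint processing

Peak matching assigns each reference peak the nearest sample peak within
a retention-time window (default **0.2 min**), greedily over candidate
pairs in ascending |Δrt| with ties broken toward the earlier retention
time; each sample peak is used at most once.  Greedy nearest assignment
can differ from the global minimum-cost assignment only when two
reference peaks compete for overlapping candidates, which the matcher
flags whenever two reference peaks lie closer than twice the window; a
brute-force assignment oracle bounds the gap on small instances in the
test suite.  When no reference grid is supplied, one is built from the
data: an anchor sample's peaks seed a first match of every sample, the
per-peak median of matched retention times becomes the grid, and one
re-matching pass follows.  This is a robust stand-in for the multipoint
calibration of commercial fingerprint software, whose exact algorithm is
not public.

Undetected peaks are floored at a small positive area (default
**0.01**, applied before normalization) so that every extract
contributes a full composition vector; rows are then normalized to the
total characteristic-peak area, making each row sum to 1.  Normalizing
to a caller-supplied full-chromatogram total is available instead
(`denominator="supplied_total"`), since the characteristic peaks
typically carry >90% but not all of the total area.  Replicate precision
uses the n−1 relative standard deviation per peak with a **5%** pass
threshold, taking the worst case across samples.

## Bioassay reduction

The enzyme inhibition rate is `[1 − (Asa − Asc)/(Aea − Aec)] × 100`,
with the four absorbances measuring sample, sample-blank, enzyme and
substrate-blank wells.  The rate is affine-invariant in the absorbances
and deliberately not clamped: sugar-rich extracts can push it negative
through colour interference, and that information is kept.

IC50 comes from a four-parameter logistic fit,
`r = bottom + (top − bottom)/(1 + (IC50/c)^hill)`, by least squares with
IC50 and hill on the log scale (positivity without constraints) and a
multi-start grid (hill ∈ {0.5, 1, 2, 4} × IC50 at the 25/50/75%
concentration quantiles) refined by trust-region least squares.  The
reported IC50 is the curve midpoint.  A fit is declared degenerate when
fewer than 3 rates exceed 10% inhibition — a flat or
interference-dominated curve has no meaningful midpoint — and a panel
with no converged replicate is reported missing, mirroring the "-"
entries such panels produce in practice.  Replicates can be fitted
per-replicate and summarized as mean ± n−1 sd (the tabulated
presentation) or pooled into a single fit (the more precise estimate;
used by the recovery benchmark).

MIC is read from a strictly decreasing two-fold dilution series
(**3.12 … 0.0125 mg/mL**, shipped as a constant because the printed
series is a rounded two-fold ladder whose rounding rule is not
recomputable) as the lowest concentration with growth fully suppressed;
all-growth and all-clear plates are censored as ">max" / "<min", and
non-monotone growth patterns or control failures are errors rather than
readouts.

## Gray relational analysis

Deng's relational degree with resolution coefficient **ρ = 0.5** (the
conventional default, configurable) and **mean normalization** by
default (each sequence divided by its mean, making degrees invariant to
positive rescaling of any sequence; initial-value and no normalization
are selectable).  Characteristic sequences are the zone diameters as-is
and the **reciprocal** of IC50 endpoints, so larger always means more
active.  Samples missing an endpoint are dropped from that endpoint's
sequence rather than imputed, because Δmin/Δmax are global statistics
over all sequences and imputation would distort them.  Ties in the
degree ranking break by ascending peak index for determinism.  When all
sequences coincide after normalization (Δmax = 0) every degree is 1 and
a warning is raised.

## PLS regression, VIP and Q²

Single-response NIPALS with unit-variance autoscaling by default
(Pareto and centering-only are available); one model per endpoint.
Endpoints tagged lower-is-active (IC50) are negated before fitting so a
positive coefficient always reads "more of the peak, more activity".
Weight vectors are sign-fixed (largest-magnitude element positive) for
reproducible output; predictions are sign-invariant.  Coefficients are
reported on both the scaled and raw scales.  VIP follows the standard
definition and satisfies Σ VIP² = p exactly; VIP > 1 is the importance
cut.  Q² uses leave-one-out cross-validation — deterministic at n = 10,
unlike randomized 7-fold schemes — with scaling re-estimated inside
every fold and PRESS referenced to the full-sample response variance.
Component count defaults to 2 in the screening pipeline; an automatic
rule (`q2_gain`, threshold 0.0975, plus `max_q2` and `fixed`) is
provided.

## Consensus screening

Per peak and endpoint, three flags: GRA evidence high (degree > **0.8**
OR rank ≤ **6** — the two published phrasings of the same filter,
OR-combined and both configurable), VIP > **1**, and positive
coefficient.  The consensus score counts endpoints where all three hold;
a peak is called active when the score reaches `min_endpoints` (default:
every endpoint screened).  Tightening any threshold can only shrink the
active set.

## Network statistics

All database-dependent inputs (predicted target lists, disease-gene
lists, interaction edges, term memberships) are delimited-text inputs,
never live queries — versioned web resources are not reproducible.
Enrichment is the upper-tail hypergeometric probability
P(X ≥ k | N, K, n) with Benjamini–Hochberg adjustment over all tested
terms, filtered at α = 0.05 on the adjusted p by default (raw-p
filtering selectable).  The component–target–pathway–disease network
keeps targets with interaction degree strictly above the average degree
and the top 20 enriched pathways by ascending p.

## The synthetic benchmark

`make_fingerprint_truth` emulates a 10-extract × 20-peak polarity
fractionation.  Peak areas are log-normal (median 1, log-sd **0.8**),
the heavy-tailed shape of real peak-area tables.  The planted active
peaks (default **3**) are modeled as chemically related constituents of
one compound class, so their areas co-vary: each is a shared class-
abundance profile (log-sd 0.8) times an independent log-normal wiggle
(log-sd **0.3**).  This co-variation is deliberate and load-bearing: the
spectrum–effect strategy assumes the active constituents' abundances
track the bioactivity across extracts, and a panel of mutually
independent actives at n = 10 carries too little per-peak signal for
*any* linear screen — with independent actives the full-recovery rate of
the consensus rule collapses to ~10–20%.

Latent potency is `u = Σ w_j · x_j` over the normalized active-peak
areas (unit weights) plus Gaussian noise, quoted as a fraction of the
potency sd.  Links: zone diameter = **6 mm** (the disk itself, the floor
of a disk-diffusion readout) + **40 mm** × u; IC50 = **50/(u + 0.05)**
μg/mL, so the reciprocal used by GRA is exactly linear in potency while
the raw IC50 is the convex, heavy-tailed quantity real assays produce.
The default screening study has one zone endpoint and two IC50
endpoints, landing in the ranges typical of extract panels (zones ~6–30
mm, IC50 ~10²  μg/mL).  Dose–response fixtures default to a ten-step
two-fold series (3.125–1600) in triplicate, the usual 96-well layout;
narrower single-replicate designs leave IC50 statistically
under-determined at realistic noise (a 7-point single curve at 2% noise
has a ~9% median IC50 error floor even with oracle initialization).

What passing benchmarks show: the pipeline's algebra is correct against
independent oracles, and the screen recovers planted actives under the
stated noise when the generator's assumptions (linear potency, co-varying
actives, independent Gaussian endpoint noise) hold.  What they do not
show: robustness to peak misidentification across chemically divergent
samples, matrix effects and detector nonlinearity, correlated assay
error, or actives whose abundance does not track activity — real-data
hazards outside the generator's scope.

## Benchmark problem sizes

The shipped benchmark uses 100 seeds for screening recovery and GRA
oracle equivalence, 50 instances for the PLS reference cross-check and
the Q² null, 200 simulations for IC50 recovery, and exhaustive
enumeration up to universe 20 for enrichment — sizes at which every
Monte-Carlo margin in the suite is stable across seeds while the whole
suite stays fast on a single CPU.
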