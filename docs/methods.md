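# Methods

This note documents the models, parameter choices and known limitations of
`gapatlas`. Units: positions, widths, shifts and overlaps are percent egg
length (%EL), 0% at the anterior pole; intensities are dimensionless in
[0, ~1.2]; developmental time is the ordered label set C10–C13, T1–T8
(T1–T8 subdividing cleavage cycle 14A).

## Profile extraction

The A–P axis of an embryo is the principal eigenvector of its binary
mask's coordinate covariance; masks with an aspect ratio below 1.2 are
rejected as axis-ambiguous. The dorso-ventral midline is the locus of
local D–V mask midpoints at 1-pixel A–P stations. The extraction strip
covers a fixed *fraction of the local mask extent* (default 0.10) centred
on the midline — a fraction rather than a fixed pixel height because the
embryo tapers towards the poles; at the pole tips, where the mask narrows
to a point, the strip is clamped to the single midline row, and the
geometry is rejected outright if the requested strip is thinner than one
pixel over most of the embryo.

Strip pixels are averaged into equal-width A–P bins (default 100 bins of
1 %EL, centres 0.5…99.5, matching the percent-position granularity used
for reporting); isolated empty interior bins are linearly interpolated
and a profile with more than 10% empty bins is an error. Bright-field
images of dark colorimetric stains are inverted (flagged in metadata) so
that larger values always mean more expression. Normalisation is
percentile-based — 5th percentile as background, 95th as full scale —
because percentiles are robust to stain speckle; boundary positions
downstream are invariant under affine intensity transforms by
construction.

Measured equivariances on synthetic renders: rotating an embryo by 30°
changes the extracted profile by < 0.03 intensity units and the recovered
axis angle by < 0.01°; the profile is independent of the strip fraction
on D–V-constant patterns to < 0.01. The residual render→extract intensity
error (~0.02–0.03 at domain edges) is dominated by mask-tip registration
— the extreme mask pixels do not sit exactly at the continuous ellipse
tips — and displaces recovered boundary positions by well under 0.1 %EL.

## Boundary model

A domain edge is modelled as a single monotone cubic Hermite segment with
zero slope clamped at both ends ("clamped spline"): the minimal smooth
monotone curve determined by two plateau levels and two window ends. The
free parameters are the two levels and the window placement (ends
adjustable by ±2 %EL around the detected window); outside the segment the
curve continues as the constant plateaus. The boundary position is the
half-maximal crossing of the fitted segment, which for this symmetric
cubic is exactly the segment midpoint. Half-max is taken relative to the
*local* plateau pair, not the global profile maximum, so domains of
different amplitude (including down-regulated ones) are localised
consistently; fits with amplitude in [0.1, 0.2) are kept but flagged
`low_amplitude`, and fits with RMS residual above 0.15 are flagged rather
than discarded.

Candidate windows come from extrema of the derivative of a lightly
smoothed profile (Gaussian, σ = 1 %EL), expanded to 10% of the peak
slope, subject to a minimum level change (0.2) and minimum flanking
plateau (3 %EL) — both configurable. Because the least-squares objective
in (window start, window width) can hold shallow local minima on noisy,
gently sloped edges, the fit is run from five window placements and the
lowest-cost solution kept. Edges at the profile ends where expression
abuts a pole produce open-at-pole markers during domain assembly; domain
identities are assigned from a configurable per-gene layout (e.g. *gt*:
anterior, posterior) in A–P order. An optional manual-override mechanism
is intentionally *not* automated away: windows can be supplied directly
to `fit_clamped_edge` to reproduce interactive boundary placement.

As an independent cross-check the package carries a deliberately simple
estimator — heavy smoothing (σ = 3 %EL) followed by a grid scan for the
half-level crossing — sharing no code with the spline fit. On 1,000
random logistic edges (steepness 0.5–3 %EL, noise 0–0.05) the two agree
within 0.5 %EL in ≈ 99% of cases; noiseless recovery of the true midpoint
is within 0.03 %EL. The ≈ 99% agreement rate is a property of honest
estimator noise at the upper end of that noise range, not of a removable
defect: both estimators carry ~0.15 %EL of positional noise there.

## Aggregation

Atlas cells are medians over embryos per (gene, domain edge, time class),
with variability 1.5 × MAD. The multiplier is 1.5 *exactly* — not the
normal-consistency constant 1.4826 — accepting ~1.2% inflation relative
to σ; on 10⁴ normal draws the ratio variability/σ measures ≈ 1.01. Cells
with a single embryo report variability 0 and are flagged; cells with no
observations are omitted, never zero-filled; a cell in which more than
half the embryos lack the domain is marked absent (threshold
configurable). One profile per embryo is assumed — no pooling of repeated
strips. No temporal smoothing is applied across time classes: the atlas
reports per-class statistics only.

## Synthetic embryos

The generator emulates lateral-view blastoderm embryos bearing staggered
domains with sigmoidal edges. Intensity is
`baseline + Σ A·σ((x−a)/s)·σ((p−x)/s)` with logistic σ, Gaussian noise,
clipped to [0, 1.2]; steepness defaults to 1 %EL. Images are elliptical
masks whose interior follows the profile along the A–P axis, optionally
modulated along D–V and rotated in the image plane. Wild-type dynamics
are a *phenomenological table*, not a rate law: per edge and time class a
median position and a between-embryo s.d. (default 1 %EL), anchored at
the printed reference positions for the *M. abdita* trunk genes (e.g.
central *Kr* 40–63% at C12 narrowing to 37–51% at T8) with linear
interpolation across unanchored classes, flagged as interpolated. Edges
pinned at a pole carry s.d. 0.

Knock-downs draw one efficacy per embryo (default Beta(2,2) — any
continuous family on [0,1] is configurable; the Beta default is a
modelling convenience) and scale their effects by it: graded
displacements/expansions, all-or-none domain loss or pole-retraction
failure above an efficacy threshold, and onset delays. This reproduces
the allelic-series character of RNAi cohorts. The packaged study scenario
encodes strong posterior-to-anterior repressions (kni⊣Kr, gt⊣kni, hb⊣gt),
strong complementary repression kni⊣hb and Kr⊣hb, terminal activation
tll→hb, no anterior-to-posterior repression, and an effect-free *hkb*
knock-down as negative control. Strong effects displace boundaries by
15 %EL at full efficacy, mid-range of the 10–20 %EL displacements that
characterise pronounced knock-down phenotypes, so the generated strong
class sits clearly inside the strong-severity regime.

What the generator does **not** emulate: nuclear texture and counterstain
channels, D–V patterning, staining batch effects, non-Gaussian stain
noise (the Gaussian choice is a convenience, not inferred from data),
embryo-to-embryo size and shape variation, and segmentation errors (the
mask is exact). Passing tests therefore validate the measurement chain's
geometry, estimation and bookkeeping — not robustness to raw-micrograph
artefacts.

## RNAi scoring and network inference

The wild-type envelope is median ± k·variability with k = 2. Per embryo,
each edge outside its envelope receives a directional label; expansion
vs displacement is separated by whether the domain widened or moved as a
whole, both-edges-inward is reduction, a missing domain is absent, and a
domain persisting within 5 %EL of the posterior pole past the wild-type
retraction class is a retraction failure (partial when residual pole
intensity is in [0.25, 0.5)). "Affected" is any-label-based; severity is
the maximum absolute edge displacement (for an absent domain, the
wild-type width). Penetrance percentages are rounded half away from
zero. Note that three published penetrance integers for this system are
inconsistent with their own printed counts under any single rounding
rule; the fixture stores the printed integers verbatim and the tests
document the three discrepant cells.

Interaction edges require penetrance ≥ 25%. Sign: repression when the
dominant evidence is expansion, retraction failure, or displacement
*toward* the regulator's nearest domain; activation for reduction,
absence, or displacement away. Strength: strong at median severity
≥ 5 %EL with penetrance ≥ 50%; weak at severity in [2, 5) %EL or
penetrance in [25, 50)%; otherwise none. These cut-offs operationalise
qualitative strong/weak calls and are all config-exposed. Indirect-effect
discounting is deliberately not automated — edges can be annotated
manually. The posterior bias statistic scores repression strength
(strong 2, weak 1) from posterior onto anterior neighbours minus the
reverse over the overlapping pairs (Kr, kni), (kni, gt), (gt, hb).

With a 20-embryo-per-cell wild-type atlas, MAD-estimation noise drags
per-edge envelope coverage from the ideal ~95% to ~92%, so null
knock-down/stained pairs accumulate spurious *weak* edges with ~2 %EL
severities at 25–45% penetrance; spurious *strong* edges do not occur
because they require both high penetrance and ≥ 5 %EL median severity.
This is an inherent small-sample property of robust envelopes, shared by
any analysis of cohorts this size.

## Statistical limits of atlas recovery

The sample median of n = 20 draws from N(μ, 1 %EL) has a standard error
of ≈ 0.27 %EL, so any single atlas cell misses the generating value by
more than 0.5 %EL with probability ≈ 6.6%; across the ~100 free cells of
a 4-gene × 10-class experiment, a handful of cells (typically 5–9)
always exceed 0.5 %EL, and the sampling spread of 1.5 × MAD at n = 20
(± ~0.17σ) likewise places a few cells below 0.6. Mean recovery error is
≈ 0.19 %EL and ~92% of cells land within 0.5 %EL. Guaranteeing every
cell within 0.5 %EL would require roughly 3× the sample size.

## Problem sizes and determinism

Default validation sizes: 1,000 random edges for the estimator-agreement
suite; 20 embryos per gene per class over ten classes (C12–T8) for the
wild-type atlas; 10 embryos per class over three classes (T2, T4, T6)
per knock-down, six knock-downs, for the perturbation study. All
randomness flows through `numpy.random.default_rng` seeds; fixed seed and
config give byte-identical TSV/JSON outputs, and every written table
carries a provenance header (version, config hash, seed). Degenerate
inputs fail loudly: near-circular masks, constant profiles, non-monotone
edge windows, duplicate embryo rows, perturbations of genes absent from
the dynamics table, and empty manifests all raise with specific messages.
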