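# Methods

This note documents the measurement model, the statistical model, the
synthetic-data generators and the numerical choices behind `cryptscore`.

## Hemicrypt scoring

**Unit of analysis.** A hemicrypt: one half of a longitudinally bisected
colorectal crypt, traced as a simple polygon whose vertex list carries two
marked edges — the basal edge (muscularis mucosae side) and the apical
(luminal) edge.  Eligibility of a hemicrypt for scoring is a judgement made
at tracing time and is the caller's responsibility; the library validates
geometry only (simple polygon, positive area, disjoint non-empty base and
apex edges).

**Axial coordinate.** The original scoring software is proprietary and its
axis construction is not published, so the package uses the simplest
reproducible definition: the crypt axis is the polyline of midpoints of the
two lateral borders, sampled at equal normalized arc length (256 samples per
border), running from the base-edge midpoint to the apex-edge midpoint.
Each interior pixel's coordinate t ∈ [0, 1) is the arc length of its nearest
axis point divided by the total axis length.  Pixels are interior when their
centers fall inside the polygon (0-based coordinates, origin top-left,
x = column).

**Segments.** Segment k (1-based, 1 = base) collects pixels with
t ∈ [(k−1)/n, k/n), default n = 50 — roughly one colonocyte width per
segment.  A t exactly on a boundary belongs to the higher-index segment; the
binning adds a forward tolerance of 1e-8 segment widths so this tie rule is
stable against the ~1 ulp rounding of arc-length computation.  The partition
is a disjoint cover of the interior by construction (one label per pixel).

**Optical density.** Per-pixel OD = −log10(I / I_bg) (Beer–Lambert
densitometry), with I clamped below at 1 count so saturated-dark pixels map
to a large finite OD rather than raising, and negative OD (pixels lighter
than background) clipped to 0 at scoring time.  I_bg is an explicit value or
the median of an annotated blank-field region.  Segment values are *sums* of
per-pixel OD (integrated OD), not means, so zone values are additive
(whole = upper40 + lower60) and the group-level φ_h is consistent with the
ratio of the group's zone summaries.  Whether the original instrument
integrated or averaged per segment is not published; integration is this
package's declared convention.

## Zones, aggregation, reliability

Zone reduction: upper40 = Σ segments 31–50, lower60 = Σ segments 1–30,
whole = their sum, φ_h = upper40 / whole (NaN when whole = 0).  The split
fraction is configurable but must land on a segment boundary.

Hemicrypts (target: 32 per participant-visit) are aggregated by the
arithmetic mean of each zone variable; φ_h is recomputed from the aggregated
values.  The natural-log transform is applied only afterwards, at the
participant level, so group summaries are geometric means.  Whether the
source study averaged per biopsy first is unstated; a single-stage mean over
all hemicrypts is used.  Marker ratios (bax/bcl-2, bax/mib-1, p21/mib-1) are
computed per participant-visit, zone by zone; zero denominators produce NaN
with a logged warning.  Because the ratios are per-participant, the group
geometric mean of a ratio equals the ratio of the group geometric means over
the same participants — the identity the reference-table checks rely on.
Participant summaries of 0 cannot enter the log-scale analysis and are
dropped with a count (`n_dropped_nonpositive`).

Scoring reliability uses the two-way mixed-effects, consistency,
single-measurement intraclass correlation, ICC(3,1) (computed via pingouin,
cross-checked in the tests against the closed-form two-way ANOVA ratio).
The form is fixed here by choice; systematic shifts between scoring passes
do not reduce it.  Exact agreement short-circuits to 1.0 rather than
returning the ANOVA ratio's roundoff.

## Treatment-effect model

Contrasts (intention-to-treat, by assigned arm): vitamin D {D, CaD, CaD2arm}
vs no vitamin D {P, Ca, Ca2arm}; calcium {Ca, CaD} vs no calcium {P, D} with
all 2-arm participants excluded (they received calcium without being
randomized to it); calcium + vitamin D {CaD, CaD2arm} vs calcium alone
{Ca, Ca2arm}.

The model is ln(y) ~ visit + group + visit×group (+ covariates) with a
participant random intercept, fit by REML (statsmodels MixedLM).  Two visits
per participant make the random intercept the identifiable default
covariance structure.  The relative effect is exp of the interaction
coefficient with a normal-based Wald interval exp(β ± z·SE) and a two-sided
Wald p-value; no small-sample degrees-of-freedom correction is applied.  The
absolute effect is the difference-in-differences of the four group×visit
geometric means.  On complete data (every participant contributing both
visits) the fixed-effect cell means of this saturated 2×2 structure equal
the observed cell means under any participant-block covariance, so
exp(interaction) coincides with the closed-form ratio of ratios; the
acceptance suite asserts this to 1e-6.  Missing visits are handled by the
mixed model (all available rows contribute); there is no imputation.

Covariates enter as fixed effects, z-scored internally (invariant for the
interaction; keeps kcal-scale columns well conditioned).  The optimizer
tries lbfgs, then bfgs, then Powell — lbfgs can step through a singular
point when the random-intercept variance sits on the boundary.  The
confounder screen refits with each candidate (and the full set) and retains
candidates whose inclusion changes the relative effect by ≥ 10%
proportionally.  Note that on complete two-visit data a participant-constant
covariate cannot move the interaction at all; only time-varying covariates
or missingness make the screen bind.

Reported precision follows the source tables: relative effects to 2
decimals, absolute effects to 1 decimal.  Group summaries are geometric
means with t-based CIs on the log scale.

## Synthetic crypt images

The image generator renders an axis-aligned elongated hemicrypt (rounded
rectangle: basal edge at the image bottom, luminal corners chamfered) inside
a blank field of intensity `background_intensity`, with a 2 px margin.  The
crypt geometry of real slides is not specified anywhere; this shape is the
simplest that exercises the axial partition.  The planted axial OD density
is uniform, basal (w(t) = 2(1−t), mib-1-like) or apical (w(t) = 2t,
p21-like).  Each of the 50 segments receives `total_od` times the analytic
integral of the density over its t-interval — so the uniform profile plants
exactly total_od/50 per segment and planted segment ODs always sum to
total_od (1e-9) — spread evenly over the segment's pixels.  The
transmitted-light image is I_bg·10^(−od_px), plus optional additive Gaussian
noise clipped to [0, I_bg] (the simplest model that stresses the OD
back-transformation).  All randomness flows from the explicit seed; equal
parameters give bit-identical output.  Noiseless round trips through the
scorer recover the planted profile to better than 1e-6 per segment; with
noise, the clipping at OD 0 and the convexity of −log10 bias recovered OD
slightly upward, visible in the README example.

Not emulated: staining chemistry, DAB/hematoxylin colour (images are single
channel, as the slides were not counterstained), slide batch effects,
irregular crypt shapes, out-of-focus blur.  Passing recovery tests therefore
demonstrates correctness of the partition and densitometry arithmetic, not
robustness to histological artefacts.

## Synthetic trials

The trial generator emulates the participant-level table of the source
design: four-arm factorial (placebo 12, calcium 16, vitamin D 17, both 17)
plus the women-only 2-arm sub-randomization on background calcium (23, 19);
two visits; lognormal biomarker values.  Log-scale model: baseline mean by
marker × zone + participant intercept N(0, σ_b²) + at follow-up ln(drift) +
ln(effect_arm) + residual N(0, σ_w²/m), where m = 32 emulates averaging that
many hemicrypt scores; hemicrypt-level variability is collapsed into this
attenuation (the image module covers hemicrypt realism), which keeps
simulation fast.  Optional energy-intake columns support confounding
constructions.

The source study reports no variance components, so the defaults are
illustrative, chosen once to be realistic for the published summary tables:
σ_b = 0.35 and per-hemicrypt σ_w = 1.1 give a total log-SD ≈ 0.40, matching
the width of the published baseline CIs for n ≈ 51 groups; placebo drift
1.05 reflects the upward drift visible in several reference groups.
Baseline log-means are set near the published baseline geometric means.

Calibration of the full loop (simulate at study arm sizes → mixed model) is
checked at 500 replicates: with a planted relative effect of 1.30 the mean
estimate matches within Monte-Carlo error and 95% CI coverage lies in
[0.92, 0.97]; under the null the rejection rate at α = 0.05 stays inside the
3-σ binomial band.  These replicate counts keep the default test run within
a desk-scale budget while leaving Monte-Carlo error well below the
tolerances asserted.

## Known limitations

- The axial coordinate is a midline approximation; for strongly curved or
  branching crypts the nearest-axis-point projection can fold near concave
  borders.  Right-angle rotations are exactly equivariant; arbitrary-angle
  equivariance holds only approximately through the raster.
- The Wald z interval is mildly anti-conservative at the study's sample
  size compared to degrees-of-freedom-corrected intervals.
- Published summary tables are printed at 3 significant figures; closed-form
  effects recomputed from them carry up to one unit of rounding in the last
  printed digit, which is the precision at which agreement is asserted.
- The reference table covers the group summaries; the source's
  energy-adjusted p-values cannot be recomputed from summaries and are
  covered by property-based calibration tests instead.
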