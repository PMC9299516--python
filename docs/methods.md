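# Methods

This note documents the models, estimators and numerical conventions behind
`nocicalc`, the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real recordings.

## The reactivity endpoint

**ΔF operator.** For each cell and stimulus, ΔF is the maximum of the raw
fluorescence trace over the stimulus response window minus the mean over the
baseline window, in un-normalised intensity units.  We deliberately do not
compute ΔF/F: the threshold rule carries an absolute cap (18 intensity
units), which is only meaningful on the raw scale.  A mean-over-window
response statistic (`response_stat="mean"`) and a median baseline
(`baseline_stat="median"`) are available as options; the mean-over-window
variant makes ΔF Gaussian for Gaussian noise and is used wherever exact
3-SD tail calibration matters.

**Windows.** Time windows are half-open `[start, end)`; a frame belongs to a
window by its timestamp; pixel coordinates are 0-based.  For the second and
later stimuli of a multi-stimulus protocol the baseline is re-anchored to the
`rebaseline_length` seconds (default 5 s) immediately before that stimulus, so
a sustained plateau evoked by an earlier stimulus does not inflate the later
ΔF.

**Baseline-window calibration.** The default analysis protocol uses the final
5 s of the pre-stimulus period as the first baseline — the same length as the
re-anchored baselines — rather than the full 10 s.  This is a calibration
choice, not a recording choice: ΔF is a window statistic minus a baseline
mean, so its noise variance depends on both window lengths.  If the control
ΔF sample is computed with a longer baseline than the test ΔF, the estimated
mean + 3·SD threshold is systematically too low and the false-positive rate
roughly doubles (measured ~2% instead of ~0.1–1% on pure-noise wells).
Matching the windows frame-for-frame restores the nominal calibration.

**Threshold.** T = min(mean + 3·SD, cap) over the control-stimulation ΔF
sample, with the sample (n − 1) standard deviation — the conventional
estimator for the small control samples of a single well — and cap default
18.  The cap is exposed as a parameter because its value is tied to the
detector scaling of the raw signal.  At least two control values are
required; fewer raise an error rather than silently producing SD = 0.

**Control source.** The control ΔF sample comes from the same well's HBSS
(negative-control) stimulus window when the protocol contains one, otherwise
from the pooled ΔF of the control wells on the same plate
(`well_thresholds`).  Both modes are implemented; the same-well mode is
preferred because it captures well-specific noise (focus, cell density,
indicator loading).

**Calls and fractions.** A cell is reactive iff ΔF > T, strictly; ties are
non-reactive.  The well summary is the exact count ratio.  Note one inherent
property of the peak-based ΔF: the maximum over a k-frame window of Gaussian
noise is extreme-value distributed, whose mean + 3·SD exceedance probability
is ≈ 1–2% rather than the Gaussian 0.13%.  The threshold is estimated from
the same distribution, so calls remain internally consistent, but users who
need the literal 3-SD tail should use the mean-over-window ΔF variant.

**Replicates and comparisons.** Wells (technical replicates) are averaged
within a biological replicate (independent differentiation) before
cross-replicate statistics; SEM = SD/√n over biological replicates and is
reported as undefined (NaN), never as 0, for a single replicate.  Two
conditions are compared by a two-sample t-test (paired on request); three or
more by Dunnett's many-to-one procedure against the reference condition
(all-pairs Tukey HSD optional), α = 0.05.  Identical zero-variance samples
are reported as p = 1 rather than NaN.

## Double-stimulation overlap

Two sequential stimuli on the same cells yield two binary calls per cell;
`double_stim_overlap` cross-tabulates them into both / A-only / B-only /
neither fractions summing to 1.  With a fast-inactivating first response and
a 5-s re-anchored baseline, carry-over into the second stimulus is bounded by
the residual template amplitude (< 3% of peak for the default kinetics).

## Dose–response

The fitted response is the *fraction of reactive cells* (not an amplitude).
The model is the four-parameter logistic in log₁₀ concentration,
f(c) = bottom + (top − bottom)/(1 + 10^((log₁₀ mid − log₁₀ c)·h)); h > 0 in
agonist mode (mid = EC50), h < 0 in antagonist mode (mid = IC50).  Fitting is
unweighted least squares (`scipy.optimize.curve_fit`) by default, with
optional 1/SEM² weights; a zero-concentration control point is excluded from
the log axis and can anchor the bottom plateau in fixed-bottom mode (which
also lowers the minimum point count from 4 to 3).  Degenerate inputs — flat
responses, runaway midpoints outside [min conc/10, max conc × 10], optimizer
failure — set `converged=False` on the result instead of raising.  The fit is
a convenience summary; the measured per-concentration fractions are always
carried alongside it.

## Transcriptome activation scores

**Chain.** counts → CPM (count/sample total × 10⁶) → per-time-point
statistics vs a baseline time point (default: the earliest) → BH adjustment
across genes within each time point → DEG filter: adjusted p < 0.05 AND
|log₂FC| ≥ 1 (linear fold change 2) → hypergeometric over-representation of
gene sets among the DEGs, BH across sets, over-represented at adjusted
p < 0.05 (optionally restricted to the n lowest-p sets) → activation scores →
superordinate-group trajectories.

**Fold changes and tests.** log₂FC = log₂((mean CPM_t + pc)/(mean CPM_0 +
pc)) with pseudocount 1.  The per-gene test is a two-sample t-test on
log₂(CPM + 1) with empirical-Bayes variance moderation: each gene's pooled
variance is shrunk toward the genome-wide mean with a prior weight of 10
degrees of freedom, and the statistic gains those df.  With 2–3 replicates
per group an unmoderated per-gene test is hopelessly underpowered after
multiplicity adjustment (sensitivity ~0.2 at planted |log₂FC| 1.5–3 in our
simulations, vs ≥ 0.9 moderated at observed FDR ≤ 0.1); variance moderation
is the standard remedy for this design.  A plain Welch test
(`moderation_df=None`) and externally computed p-values (e.g. from a
negative-binomial GLM) are both supported — this module is a deliberately
simple stand-in for a full count-model framework, not a re-implementation of
one.

**Activation score.** For one set at one time point,
score = pct_significant × mean_fold_change, where pct_significant is the
percentage of *measured* set members that are DEGs and mean_fold_change the
mean |log₂FC| over those DEG members.  Two open readings were settled as
follows: (i) the denominator counts members measured in the data, not the
full annotated set, because targeted panels never cover whole GO terms;
(ii) the fold-change factor uses the absolute log₂ fold change, treating up-
and down-regulation symmetrically and keeping the score scale-stable; the
signed-log₂ and linear-FC variants remain available via `fc_mode`.  A set
with no DEG members scores exactly 0; a set with no measured members has no
defined score and raises an error.

**Trajectories.** Per superordinate group and time point: mean ± SEM over
member-set scores, and a paired t-test (pairing by set id) of the member
scores at that time point against the reference time point.  Zero-variance
differences are mapped to p = 1 (identical) or p = 0 (constant nonzero
shift).  PCA for overview plots takes the 500 most variable genes of
log₂(CPM + 1), centres genes, and decomposes by SVD.

## Synthetic-data generator

**Wells.** A well is a mixture of four responder classes — none, A-only,
B-only, both — drawn i.i.d. from configurable class probabilities (default
0.25/0.40/0.10/0.25, the co-expression pattern typical of nociceptor-enriched
cultures probed with a P2X3 agonist and capsaicin).  Each cell's trace is

baseline · e^(−bleach·t) + Σ_s amplitude_s · template_s(t − t_s) + N(0, noise_sd²)

sampled at `frame_rate` (default 2 frames/s — the acquisition rate is a
config default, not part of any algorithm) over 45 s with stimuli from 10 s
on.  Kinetic templates are unit-peak piecewise curves — linear rise, then
exponential decay toward a plateau fraction — with plateau ≈ 0 for
fast-inactivating (P2X3-like) and ≈ 1 for sustained (TRPV1-like) responses;
the published recordings show shapes, not equations, so a minimal parametric
family suffices for testing classification and all parameters are exposed.
Photobleaching is a single exponential applied to the baseline only,
reproducing the mild negative drift of control traces without coupling to
response amplitude.  Responder amplitudes are Normal(30, 5²) clipped at 0 —
comfortably above realistic thresholds, so classification errors reflect the
pipeline, not amplitude ambiguity.  The HBSS control stimulus evokes
amplitude 0 by default; setting `control_amplitude_mean > 0` models
mechanical hypersensitivity after drug pre-treatment.

**Rendering.** Wells can be rendered as 16-bit multi-frame TIFF stacks: a
flat background plus one isotropic 2-D Gaussian spot per cell whose peak (and
hence integrated intensity) equals the cell's trace value.  Cells are placed
on a jittered grid with pairwise separation ≥ twice the spot radius; the grid
expands beyond the configured frame if needed, and rendering then requires a
correspondingly larger frame.  Quantization to uint16 is the only loss.

**Counts.** Gene abundances are lognormal(0, 1.5²) relative weights;
counts are gamma-Poisson (negative binomial) with one shared dispersion
(default 0.1; per-gene dispersions are out of scope), reducing to Poisson
below dispersion 10⁻⁸.  A `deg_fraction` of genes receives a signed log₂
fold change drawn uniformly from `effect_log2fc_range`, applied at every
non-baseline time point (`"constant"`, default) or growing linearly to its
full value at the last time point (`"ramp"`, emulating a maturation
gradient).  Compositional renormalisation after planting mirrors the fact
that sequencing measures proportions.  Library sizes are lognormal around
`library_size_mean` with configurable CV (default 5%).

**What the generator does not emulate.** Spatially correlated noise, cell
movement, focus drift, overlapping somata, indicator saturation, spontaneous
Ca²⁺ transients, per-gene dispersions, batch effects.  Passing tests
demonstrate that the estimators recover known parameters under the stated
noise model — they do not validate segmentation or thresholding on real
microscopy data.

## Test and validation sizes

Parameter-recovery checks use 1000-cell wells over 100 seeds (responder
fraction), 2000-cell wells over 10 seeds (overlap mixture, asserted at the
95%-of-seeds level because the multinomial draw alone leaves the 3·SE band in
a few percent of seeds), 500-cell pure-noise wells over 10 seeds
(false-positive control), and 1000 simulated null repetitions with 2 × 3
replicate wells of 100 cells (type-I error of the condition comparison).
These sizes put Monte-Carlo error well below each criterion's tolerance while
keeping the default test run fast.

## Known limitations

- Segmentation is a deterministic stand-in (maximum projection, Gaussian
  smoothing, local maxima, fixed-radius disks); cells closer than the minimum
  separation merge into one ROI by design.  The published assay used a
  dedicated external tool whose exact ΔF and segmentation definitions are not
  part of this package; the defaults here are declared stand-ins.
- AVI ingestion is not implemented; TIFF is the canonical stack container.
- The DEG machinery is a moderated t-test on log-CPM, not a count GLM; for
  publication-grade differential expression supply external p-values.
- Dunnett vs Bonferroni as the post-hoc procedure is a convention choice
  (comparison-against-control is the default analysis design).
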