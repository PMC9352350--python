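# Methods

## The measurement model

The package analyses glomerulus × odorant response matrices (ΔF/F) recorded
from the dorsal olfactory bulb while a large odorant panel is delivered at
perithreshold concentrations.  One *glomerulus type* corresponds to one
odorant receptor channel; the same type can be located in every imaged OB,
with positional jitter, and its response spectrum across the panel is the
functional fingerprint used to match it across animals.  All analyses treat
the matrices as the primary data; image processing (ΔF maps, ROI detection,
trace extraction, noise thresholding) is provided for completeness but every
downstream stage accepts matrices directly.

## Synthetic data generator

`synthetic_data` draws a ground truth first and realizes per-OB matrices
from it.  The generator's defaults are the study conditions the analyses
assume:

| parameter | default | unit | rationale |
|---|---|---|---|
| `n_mice` × `obs_per_mouse` | 4 × 2 | – | bilateral imaging in four animals |
| `n_odorants`, `n_classes` | 185, 16 | – | panel size and nominal structural classes |
| `n_glomeruli_per_ob` | (100, 142) | – | observed responsive-glomerulus range; with `presence_prob` this sets ~134 glomerulus types |
| `ln_amp_mean`, `ln_amp_sd` | 1.48, 1.03 | ln(ΔF/F %) | lognormal amplitude distribution; exp(1.48) ≈ 4.4% ΔF/F |
| `sparsity` | 2 | glomeruli/odorant | target median responsive glomeruli per *effective* odorant |
| `single_odorant_fraction` | 0.29 | – | fraction of types responding to exactly one odorant |
| `n_diagnostic` | 26 | – | types planted with an exclusive, singularly-activating odorant |
| `presence_prob` | 0.9 | – | per-OB detection probability of a type; not quantified experimentally, chosen so reliable odorants respond in ≥6 of 8 OBs |
| `position_jitter_sd` | 100 | µm | cross-animal positional jitter, within the observed 32–180 µm range |
| `class_dispersion_um` | 150 | µm | spatial spread of a structural class around its center |
| `detection_noise_sd` | 0 | ΔF/F % | additive per-OB noise; 0 gives spectra conserved exactly across OBs |

Tuning breadth is 1 with probability `single_odorant_fraction` and otherwise
2 + Poisson, with the Poisson rate calibrated so the expected number of
responsive types per odorant matches the sparsity target.  Co-tuned odorants
are drawn class-first: a binomial share (`same_class_cotuning`, default 0.8)
of a type's odorants come from its own structural class without constraint,
and cross-class odorants are restricted to concentrations above the class
members' minimum, so the *primary* odorant — the minimum-threshold
(lowest-concentration) effective odorant — always carries the type's class.
Diagnostic types instead keep their exclusive odorant as the minimum so the
planted diagnostic is also the primary.

Per OB, present types inherit the type's base amplitudes unchanged
(plus optional additive noise) and the type's home position plus Gaussian
jitter; row order is shuffled per OB so no algorithm can exploit row
alignment.  Conserving amplitudes across OBs is what makes noise-free
parameter recovery exact (cross-OB spectrum correlation 1, error ratio 0);
its cost is that amplitudes pooled across OBs repeat each draw up to 8×, so
distribution tests on pooled amplitudes must deduplicate first.

What the generator does *not* emulate: concentration–response curves (each
odorant is simulated at a single delivered concentration), inhalation
dynamics and adaptation, correlated optical noise and signal spread between
neighboring glomeruli, and inter-animal differences in overall gain.
Passing recovery tests therefore demonstrate correctness of the analysis
chain under the stated statistical structure, not robustness to every
artifact of real imaging data.

Planted diagnostics are exclusive to their type, but nothing prevents other
odorants from *genuinely* satisfying the diagnostic criteria (in sparse
noise-free data many do, just as far more odorants pass the experimental
screen than end up tagging unique glomeruli).  Recovery is therefore
asserted as: every planted diagnostic odorant is identified, and the planted
odorants map to exactly `n_diagnostic` distinct glomeruli.

## Concentration estimates

Delivered vapor-phase concentrations follow Raoult's law for an ideal
mixture: partial pressure = liquid mole fraction × pure-compound vapor
pressure (Pa at 25 °C), giving a headspace molarity of x·vp/(RT), scaled by
a single configurable olfactometer dilution factor (default 1.0 in the
estimator; the synthetic panel uses 0.01).  The dilution calibration of a
real olfactometer is not published as a number, so estimated concentrations
are configurable estimates; they are reported to one significant digit.
ppb is mole fraction × 10⁹ in the vapor phase at the stated T and P.

## Statistical measures

* **Sparseness** uses the normalized selectivity form
  S = (1 − (Σr/n)²/(Σr²/n))/(1 − 1/n); all-zero vectors are undefined (NaN,
  logged), never silently 0.  Results are clipped to [0, 1] because float
  cancellation can push uniform vectors a few ulp outside the range.
* **PCA / effective dimensionality**: each glomerulus's spectrum is
  normalized to its maximal response; glomeruli are the variables and
  odorants the observations (the possible number of PCs is therefore bounded
  by the number of responsive glomeruli); columns are mean-centered before
  eigendecomposition (centering is the package's choice; it is the standard
  convention).  ED is the participation ratio (Σλ)²/Σλ² of the covariance
  eigenvalues — the count of equal-variance dimensions with the same
  eigenvalue concentration.
* **Error ratio** uses *ordered* OB pairs by default (the match relation —
  "does OB i's winner find OB j's winner by correlation?" — is asymmetric);
  unordered pairs are available via a flag.  OBs where the odorant evokes no
  response are excluded from both the error ratio and the median ORS
  correlation.
* **Grouping of diagnostics into unique glomeruli**: two accepted odorants
  tag the same glomerulus when their per-OB maximally-activated glomeruli
  coincide in a majority of the OBs responsive to both; groups are connected
  components of this match relation.  The consensus spectrum is the
  per-odorant median of max-normalized spectra across OBs, renormalized to
  max 1.

## Chemical spaces and the performance metric

Continuous descriptor matrices are consumed as input (their values are never
computed here), z-scored per descriptor with zero-variance columns dropped
and logged, and compared by cosine distance; binary keysets by 1 − Dice;
PC-reduced spaces by Euclidean distance on the first 20 PCs (clipped to the
library rank, with a warning).  The SMARTS42 keyset ships as a plain-text
file (one pattern per line, tab-separated label) so substitute keysets can
be dropped in; every pattern is validated at load time.

The performance metric excludes the query odorant, ranks the remaining
odorants by increasing distance with ties broken by panel order (stable
sort, logged when distances are completely degenerate), anchors the
cumulative-response curve at (0, 0), and integrates by trapezoid over rank
fraction ∈ [0, 1].  In binarized mode the curve accumulates responder
counts; in amplitude mode, summed amplitudes.  Under a uniformly random
ranking the expected model AUC is exactly ½, so E[P] = 1/AUC_response − 1 —
about 0.005 for 2 responders among 185 odorants, i.e. 0 at the one-decimal
precision at which chance performance is quoted.  Whole-dataset summaries
threshold each glomerulus at strictly greater than 10% of its maximal
response, binarize, keep glomeruli with ≥ 2 effective odorants, compute P
with every effective odorant as query, and report the per-glomerulus median.

## Co-tuning matrices and network

Spearman correlations are computed per OB between odorant response columns
(pandas' rank-then-Pearson; pairs involving a zero-variance column are NaN
for that OB and excluded from the cross-OB average rather than zero-filled).
Co-tuning probability divides the per-OB count of glomeruli responsive to
both odorants by the OB's responsive-glomerulus count; co-tuning counts are
averaged unnormalized.  "Responsive" means nonzero after whatever upstream
thresholding produced the matrices — co-tuning inherits that zeroing.  The
network keeps edges with mean count ≥ 0.875 (the boundary passes: one
co-tuned glomerulus per OB in at least 7 of 8 OBs), orders nodes by panel
class for circular layout export, and color-keys cross-class edges to the
endpoint class with more connected members.

## Spatial clustering

Ripley's K uses the rectangular bounding box of the OB's full glomerular
array as the window and isotropic (Ripley) edge correction — each pair is
weighted by the reciprocal fraction of the circle through the neighbor that
lies inside the window, with corner overlaps handled analytically; the
correction is exact for radii up to half the window's shorter side, which
covers the default 0–400 µm grid (512 uniform steps, derived from the data
extent rather than hard-coded).  An uncorrected mode exists for enumeration
checks.  The Monte-Carlo null resamples the group's size without replacement
from the full array; p-values use the (1 + #{K_sim ≥ K_obs})/(1 + n_iter)
estimator to avoid zero p, and the upper tail only (clustering, not
dispersion, is tested).  The *persistent radius* is the smallest grid radius
from which p < α (default 0.01) holds at every larger grid radius, guarding
against isolated spurious significances; it is NaN when no radius persists.
Glomeruli whose primary odorant has a MIXED structural classification are
excluded from class grouping, and groups need ≥ 3 glomeruli.

## Problem sizes and determinism

Test and demonstration runs use the full study geometry (8 OBs, ~134
glomerulus types, 185 odorants), which the pipeline processes in seconds;
Monte-Carlo cluster tests in the test suite use 299–999 iterations and
64–128 radius steps, and the random-ranking baseline in the acceptance
script uses 10,000 iterations.  Every stochastic component draws from a
caller-supplied seed or `numpy` Generator; seeded runs are bit-reproducible,
and the CLI writes a manifest (version, seed, parameters, input checksums)
sufficient to reproduce a run.

## Known limitations

* ROI detection is a deliberately simple threshold/connected-components/
  circularity rule; real widefield data with overlapping or dim glomeruli
  needs the threshold and diameter range tuned, and merged foci are only
  logged, not split.
* The automated replacement for visual response attribution
  (`zero_misattributed`) zeroes an entry when the local ΔF peak falls
  outside the ROI; it approximates, but is stricter than, expert inspection.
* Descriptor matrices must be computed externally; only their processing is
  in scope.
* The error-ratio/grouping machinery assumes the odorant panel is identical
  across OBs; partially overlapping panels are not supported.
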