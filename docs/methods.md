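# Methods

`richnet` implements a longitudinal (pre/post, two-group) analysis of
rich-club organisation in functional brain connectivity networks, together
with a synthetic cohort generator used to validate every stage. This note
documents the models, the parameter choices that matter, and the limits of
what the synthetic validation shows.

## Network construction

Each scan is a `(timepoints x regions)` ROI time-series matrix, assumed
already nuisance-cleaned and band-limited (preprocessing is out of scope).
Functional connectivity is the Pearson correlation `r_ij` between regional
time courses; edge p-values use the t transform
`t = r sqrt((n-2)/(1-r^2))` on `n-2` degrees of freedom, two-sided, which is
the standard choice at resting-state sample sizes (n ~ 10^2). Family-wise
error control across the `E = n(n-1)/2` edges is Bonferroni by default
(`p < alpha/E`, alpha = .05); Holm's step-down variant is available. Which
FWE procedure to use is a genuinely open design point — Bonferroni was chosen
as the strictest assumption-free convention. Negative correlations are
excluded (their interpretation in FC networks is unsettled), and surviving
edges keep the raw `r` as weight; no Fisher transform, no binarisation,
because downstream "connectivity" quantities are sums of edge strengths.

With the default conditions (T = 139, 90 nodes, E = 4005) the Bonferroni
cutoff corresponds to |r| ≈ 0.37, so a periphery at r ≈ 0.1 is essentially
never retained while a core at r ≈ 0.35–0.50 largely survives — thresholded
networks are sparse (tens to a few hundred edges).

## Graph metrics

All metrics run in `weighted` (default; edge length `1/w`) or `binary` mode;
which mode a given reference toolbox used is often unstated, so both are
provided.

- overall strength: sum of all edge weights (each undirected edge once);
- global efficiency: mean inverse shortest-path length over ordered pairs,
  with unreachable pairs contributing zero;
- characteristic path length: mean distance over *reachable* pairs only
  (keeps L finite on disconnected networks);
- nodal degree (edge count — note some literatures call this "nodal
  strength"), weighted strength, nodal efficiency, and raw (unnormalised)
  Brandes betweenness;
- clustering: binary triangle density per node, or the Onnela
  geometric-mean-of-weights form with weights normalised by the network
  maximum;
- small-worldness: sigma = gamma/lambda with gamma = C/<C_null>,
  lambda = L/<L_null> over degree-preserving Maslov–Sneppen rewired nulls.
  Each null performs 10 double-edge-swap attempts per edge and carries edge
  weights through the swaps; 100 nulls per network by default. Swap counts
  and null counts follow common practice; results are seeded and
  reproducible.

Degenerate cases: empty networks give efficiency 0 and undefined (NaN)
sigma; a rewiring request on a network with < 2 edges returns an unchanged
copy with a warning.

## Rich-club decomposition

The rich club is an a-priori 14-region set (bilateral dorsolateral superior
frontal gyrus, insula, hippocampus, precuneus, superior parietal gyrus,
putamen, thalamus in the packaged 90-region AAL table), not a degree-derived
Phi(k) curve: the analysis concerns a fixed hub set validated by prior hub
literature, and a config option accepts any custom set. Edges are classified
rich (both endpoints rich), feeder (exactly one) or local (neither); the
three connectivity values are the weight sums per class, each undirected
edge counted once, so rich + feeder + local = overall strength to machine
precision. This conservation identity is asserted on every pipeline run.

The packaged subnetwork affiliations (DMN, SN, FPN, SMN, SCN, visual,
attention) are a standard-style stand-in assignment used only to label NBS
output; they do not affect any statistic and are fully overridable by a
user TSV.

## Statistics

- **Wilcoxon signed-rank** (two-tailed) for every pre/post contrast. Zero
  differences are dropped (the common convention, not Pratt's), ties get
  midranks, and the statistic is `W = min(W+, W-)`. For m <= 12 informative
  pairs the two-sided p is exact, computed from the full distribution of
  `W+` over all 2^m sign assignments via convolution over doubled ranks
  (doubling keeps midranks integral); beyond that, a normal approximation
  with tie-corrected variance and continuity correction. The exact path is
  verified against brute-force enumeration in the tests.
- **Spearman** correlation of changes (post minus pre) of rich-club
  connectivity against changes of each symptom scale: Pearson correlation
  of midranks, exact permutation p for n <= 8, t-transform p otherwise.
- **FDR**: Benjamini–Hochberg step-up at q = .05 across the 90 nodes,
  applied per nodal metric (not pooled across metrics — each metric is its
  own 90-test family, the more common reading). Global and rich-club tests
  use uncorrected p < .05.

## Network-based statistic

Edgewise paired t statistics (post minus pre over subjects) are thresholded
at t = 3 (primary threshold), kept edges form a graph whose connected
components are sized by edge count, and the maximal component size is
re-computed under subject-level sign flips of the difference matrices —
exact exchangeability for a paired design, each subject flipped
independently with probability 1/2 — for 5000 permutations. Each observed
component gets `p = (1 + #{null max >= size}) / (P + 1)`; the +1 smoothing
avoids p = 0 and the >= tie rule is conservative. The default direction is
positive (`t > 3`), i.e. connections strengthened after treatment;
`negative` and `two_sided` are flags. NBS runs on the raw (unthresholded,
negative-retaining) correlation matrices by default, since the edgewise test
concerns every connection, not only FWE survivors; a config switch tests the
thresholded weights instead. Zero-variance edges get t = 0 with a warning.

A structural note: with a strong constant planted effect, near-unanimous
sign-flip patterns reproduce the effect's component, so the component
p-value sits slightly above the theoretical floor `1/(P+1)`; this is a
property of sign-flip exchangeability, not an implementation artifact.

## Synthetic cohorts

The generator emulates what the downstream analysis assumes about cleaned
BOLD: stationary multivariate Gaussian series with a block-structured target
correlation matrix — off-diagonal periphery at `base_corr_periphery` = 0.1,
a densely connected 14-node core at `base_corr_core` = 0.35, and, for the
treatment group's post session only, core–core entries raised by
`treatment_delta` = 0.15. Targets are repaired to positive semidefiniteness
by eigenvalue clipping and rescaling to unit diagonal (rarely triggered for
these levels), sampled through an eigen square-root factor, passed through
an AR(1) filter with phi = 0.4 (the same filter per region, approximating
band-limited temporal smoothness without altering cross-correlations) and
re-standardised. Defaults: 90 regions, T = 139 timepoints (6 min at
TR 2.5 s minus 5 discarded volumes), 14 treatment and 15 no-treatment
subjects — the dimensions of the study design this package addresses.

Symptom scores are planted on the *realised* (sample) core-block mean
correlation change, not the target, so that rank-correlation recovery is a
genuine estimation problem: for a treatment subject,
`post = pre + slope * change + noise`; controls get `pre + noise`. The
MADRS-like scale draws pre ~ N(28.7, 2.6^2) with slope −87 and noise
sd 1.5: slope x the planted +0.15 change gives the ~13-point mean drop
typical of a responding group, and the noise level makes the planted
monotone link strong (|rho| ~ 0.9), comparable to what severity scales show
in small responder cohorts. The MC-SDS-like scale (10.6 ± 1.7, slope −10,
noise 0.8) carries a deliberately weaker link.

What the generator does **not** emulate: motion and physiological artifacts,
scanner drift, hemodynamic convolution, spatial autocorrelation of the
parcellation, non-Gaussian marginals, heterogeneous per-subject effect
sizes, or missing clinical scores. Passing the planted-effect tests
therefore demonstrates that the pipeline detects the statistical structure
it targets at realistic dimensions — not that real fMRI effects of this size
would be detected at the same rates.

## Problem sizes used in validation

The test suite validates the graph core against brute-force oracles
(Floyd–Warshall, exhaustive path enumeration, direct triple sums) on 200
random networks of up to 8 nodes at 1e-12; conservation on 1000 random
networks; exact Wilcoxon p on 500 random paired samples against 2^m
enumeration; NBS family-wise error on 200 null cohorts (30 regions, 14
pairs, 500 permutations) against the [0.02, 0.10] binomial band; planted
effect and Spearman-link recovery on 100 cohorts at full 90-region
dimensions; and end-to-end determinism (byte-identical reports) at full
study scale with 5000 permutations and 100 nulls. These sizes keep the whole
suite under a few minutes on one CPU while leaving the Monte-Carlo bands
tight enough to be meaningful.

## Known limitations

- Bonferroni over 4005 edge tests is severe; real analyses may prefer Holm
  (provided) or weaker control, which changes network density and all
  downstream sums.
- Edge p-values assume temporally independent samples; AR(1) smoothing makes
  them anticonservative. The NBS permutation inference is unaffected
  (subject-level exchangeability), as are the Wilcoxon/Spearman tests
  (scan-level summaries), but per-edge FWE survival is effectively at a
  slightly higher alpha than nominal.
- Weighted shortest paths use length = 1/w; other monotone transforms are
  defensible and change efficiency values (not orderings within a mode).
- The Spearman analysis uses all treatment subjects; it does not model the
  missing-score patterns of real clinical batteries.
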