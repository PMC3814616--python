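# Methods

## Binding-constant estimation from percent-of-control panels

Competitive kinome panels measure, at each drug concentration c, the
percent of kinase remaining bound to an immobilized probe relative to
vehicle (PC; 100 = no displacement, 0 = complete displacement). The
single-site competitive model with unit Hill slope gives
PC(c) = 100/(1 + c/K_d), inverted pointwise to K_d = c·PC/(100 − PC).
The panel estimate is the **arithmetic mean** of the pointwise values over
the series, with these conventions, each verified against the vendor
estimates shipped in the packaged fixtures (every numeric fixture value
reproduces to 2 decimals):

- **PC ≥ 100 is excluded** from the average: no displacement carries no
  information and the transform is undefined or negative there. Values
  slightly above 100 (assay noise) are accepted on input, flagged on the
  profile, and excluded identically.
- **PC = 0 contributes 0** to the mean (complete displacement at that
  concentration pulls the average down; the fixtures confirm the vendor
  did the same).
- **All points excluded ⇒ censored**: the estimate is reported only as
  exceeding the top tested concentration (rendered `>10,000` for the
  default series).
- Reported values are rounded **half-up to 2 decimals**; full precision
  is kept internally.
- The Hill slope of the pointwise transform is fixed at 1; the fixture
  values are consistent only with slope 1, and the panel's four-point
  design could not identify a free slope anyway.

The pointwise mean weights concentrations equally. Its sampling error is
dominated by points where PC approaches 0 or 100 (the derivative
dK_d/dPC = 100c/(100 − PC)² blows up); users comparing estimates across
kinases should prefer profiles whose PC values straddle 50%.

Affinity categories: `high_affinity` below 50 nM (the cut used to call a
kinase "very tightly bound"), `intermediate` below 1000 nM, `weak`
otherwise, `above_range` when censored. Only the 50 nM cut is anchored
in the source assay interpretation; the 1000 nM cut is a configurable
package convention.

Note on naming: panel vendors label this column an "estimate of IC50"
while the single-site interpretation reads it as a K_d; for a pure
competition readout the two coincide and the package treats them as one
quantity (`kd_nM`).

## Dose-response fitting

`fit_hill` fits the four-parameter logistic in log10-concentration space
with `scipy.optimize.least_squares` (bounded trust-region). Defaults:
bottom fixed at 0, top fixed at 100 (activity as percent of uninhibited
control), slope free in [0.3, 4]. Initialisation: asymptotes from the
data extremes, log-IC50 at the concentration nearest half-maximal
activity, slope 1. Convergence: ftol 1e-8 on the residual sum of
squares, at most 10,000 evaluations. Concentration-zero rows are placed
three decades below the lowest treated dose rather than log-transformed.
Datasets with no activity variation are reported `converged=False` with
a message, never as a silent number. `se_ic50_nM` is the standard
deviation of IC50 over a nonparametric bootstrap that resamples
replicates within each concentration (default 500 resamples, seeded;
identical seeds give identical SEs).

Residual activity at a concentration is evaluated from a fit or from a
bare IC50 with an assumed unit slope. For the unit-slope model the
prediction at 1 µM from IC50s of 187/460/354 nM lands within ~4
percentage points of typical measured residual activities
(18.9/29.6/25.7%); the package treats agreement within 5 points as a
consistency check between the model and measured endpoints, not as an
exact identity, since measured values may be single assay points.

Kd-vs-IC50 concordance uses a 10-fold default window — the conventional
order-of-magnitude correspondence between binding-displacement and
activity-inhibition assays.

## Apoptosis quantification

Events are gated on two channels: apoptotic = Annexin V ≥ threshold AND
TMRE < threshold (phosphatidylserine exposure with loss of mitochondrial
membrane potential). Automatic gate placement fits a two-component
Gaussian mixture to each channel's log10 intensities (floor 1 before
log) and puts the threshold at the mixture-density minimum between the
component means, mimicking manual valley gating; explicit thresholds
override. An optional `viability` (dead-cell dye) channel, when present,
excludes viability-positive events before gating (toggleable).

Suppression of stimulus-induced apoptosis is reported by the
baseline-subtracted formula
100·(1 − (f_drug,stim − f_drug,base)/(f_ctrl,stim − f_ctrl,base)),
because the scientific contrasts compare stimulated conditions against
each arm's unstimulated baseline; a raw-ratio mode (1 − f_drug/f_ctrl)
is provided, the two coincide at zero baselines, and every output names
the formula used. The reference arm is whatever the comparison anchors
to — vehicle, or a drug-treated control line when contrasting genotypes
under drug. Reported values are clamped to [0, 100] with the unclamped
value kept (`raw_pct`; negative = enhancement). A contrast with no
stimulus effect raises rather than returning a number.

Histology densities are counts divided by tumor area (per mm²) or
epidermal length (per mm), with the unit tracked. Group comparisons use
two-sided Student's t-tests (paired on request), significance at 0.05;
zero-variance degenerate cases are resolved explicitly (identical groups
→ p = 1; constant non-zero paired difference → p = 0, flagged).

## Growth-advantage partition

Effects are measured as excess advantage δ = fold − 1, fold being the
ratio of mean colony counts; δ = 0 is no effect, which makes shares of a
total well defined (fold itself would not). Two one-sided contrasts:

- **CRAF contrast** (paradoxical ERK requires intact CRAF):
  erk_share = 100·(δ_WT − δ_KO)/δ_WT under drug.
- **JNK contrast** (genetic JNK-pathway knockdown without drug):
  jnk_share = 100·δ_TKD,untreated/δ_total, where δ_total is by default
  the mean of the SCR and TKD drug-induced excesses (the two arms reach
  similar totals under drug).

Each contrast bounds its mechanism from below, so the shares combine
into complementary ranges — JNK in [jnk, 100 − erk], ERK in
[erk, 100 − jnk] — with the upper bound of one range plus the lower
bound of the other summing to 100 exactly. Shares are clamped to
[0, 100] for reporting with raw values retained; overlapping shares
(jnk > 100 − erk) are flagged inconsistent, not silently adjusted.
Uncertainty: replicate-level bootstrap (default 2000 resamples, seeded)
resampling each of the four count groups independently, percentile 95%
intervals. These formulas are the minimal arithmetic consistent with the
bar-chart contrasts they formalise and are documented as an
interpretation, not a mechanistic model.

## Synthetic-data generators

All generators are deterministic functions of (parameters, seed) via
`numpy.random.default_rng`.

- **Percent-control profiles**: exact single-site curve plus
  multiplicative Gaussian noise with CV `noise_sd`% — readout noise in
  amplification-based competition assays scales with signal, which is
  also why real panels report values as small as 0.05 (under additive
  percentage-point noise such readings would be meaningless). Values are
  truncated to [0, 100] and then rounded the way panel tables print
  them (integers above 10%, one decimal below); `round_to_table=False`
  keeps full precision, under which the zero-noise round trip through
  `estimate_kd` is exact to machine precision, and table rounding
  perturbs it by at most a few percent.
- **Dose-response**: Hill curve over the standard 10-point 0.05–1000 nM
  triplicate design with additive Gaussian replicate noise (percent
  scale, floored at 0).
- **FACS events**: two log-normal components — viable
  (Annexin-low/TMRE-high, log10 means 1.5/3.0) and apoptotic
  (Annexin-high/TMRE-low, 3.0/1.5), common log10 sd 0.25 — mixed at the
  planted apoptotic fraction, with the apoptotic count drawn binomially
  as in a real acquisition. These parameters are configuration, not
  science claims; the default 1.5-decade separation at sd 0.25 yields
  visually bimodal, valley-gateable clouds.
- **Colony counts**: Poisson around base_rate × multiplier per
  genotype×treatment condition; a gamma-Poisson (negative-binomial)
  option models the overdispersion of real soft-agar replicates
  (variance = mean + mean²/k). Poisson is the default so recovery tests
  bound sampling error tightly.

What the generators do **not** emulate: biology (UV dose-response of JNK
activation, kinetics of pathway phosphorylation), plate/batch effects,
FACS compensation or spectral overlap, spatial colony-counting error.
Passing recovery tests therefore demonstrates estimator correctness
under each assay's idealised statistical shape, not robustness to every
real-world artefact.

## Problem sizes and numerical choices

Recovery tests use the assay-scale designs: 4-point binding series,
10-point triplicate dose-response, 20,000-event FACS samples (0.3%
binomial sd at a 30% fraction, hence the 1-point recovery tolerance),
20-replicate colony experiments at base rate 50. Bootstrap sizes are
500 (dose-response) and 2000 (partition) by default, reduced in a few
tests where only determinism, not precision, is under test. Ties and
degenerate inputs fail loudly (censored estimates, unconverged fits,
undefined suppression, zero-variance tests) rather than propagating
NaNs.

## Known limitations

- The pointwise-mean K_d estimator is unweighted; points near PC = 0 or
  100 dominate its error, and no uncertainty is attached to panel
  estimates (the source tables carry none).
- Single-site, non-cooperative binding only; no ATP-competition (Km)
  modelling — activity assays are summarised by IC50 alone.
- The partition is an accounting of marginal contrasts; it assumes the
  two mechanisms act additively on the excess-advantage scale and does
  not model interaction between proliferation and apoptosis suppression.
- Auto-gating assumes a bimodal channel; unimodal or heavily overlapping
  populations need explicit thresholds.
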