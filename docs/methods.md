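# Methods

This note documents the models, estimators, and numerical choices behind
`whisksel`, and what the synthetic-data tests do and do not establish.

## Task and data model

A session is one recording from one mouse: a population of sorted single
units (spike times in seconds from session start) and an ordered trial
table. In the discrimination task each trial presents one of two adjacent
single-whisker stimuli for 1.5 s; outcomes are Hit/Miss for the rewarded
(positive) whisker and CR/FA for the unrewarded (negative) whisker,
depending on licking within the response window. The context label records
whether the water port was reachable (Home) or physically displaced
(Away); Away alternates in blocks of seven positive-stimulus trials. In
the detection task both whiskers are rewarded (whisker1/whisker2 map onto
the positive/negative slots internally).

Invariants are enforced at construction and on ingest — unsorted or
negative spike times, outcome/lick inconsistencies, and outcome/stimulus
mismatches are rejected with the offending unit or trial named, never
repaired silently. Intervals are half-open `[start, end)` so bins
partition time; event-time lists ride inside trial CSV cells
semicolon-delimited to keep one row per trial. No public deposition format
exists for this kind of study, so the tabular schemas are the package's
own invention and are exercised by round-trip tests.

## Rate estimation and z-scoring

Rates are binned per unit against the per-trial first touch with the bin
grid anchored at the event (an edge at 0). The default analysis windows
are baseline `[-1.5, 0)` s, response `[0, 0.3)` s, early `[0, 0.05)` s,
late `[0.07, 0.3)` s, and 10 ms bias bins. Z-scoring is per unit against
the pooled baseline-window bin distribution of *engaged* trials — Home
Hits plus the Home CR trials surviving the disengagement filter — so Miss
and Away comparisons are expressed on the engaged scale. Near-silent
units get their SD floored at 0.1 sp/s and are flagged rather than
dropped, which keeps population histograms complete while marking
unreliable z-values.

The engagement filter removes CR trials inside maximal runs of
consecutive no-lick trials containing ≥ 5 Misses (CRs inside a run count
as members but not toward the 5; the rule sits in one function so
alternative readings are one-line swaps). The filter is applied to Home
trials only: Away trials deny the response by design — the animal still
whisks and is engaged — so they neither count toward consecutive misses
nor enter the engaged pool.

## Stimulus bias

The selectivity statistic is a per-bin d-prime,
`(mu_A − mu_B) / sqrt((var_A + var_B)/2)`, over across-trial moments of
the binned rate, evaluated in non-overlapping 10 ms bins (the simplest
consistent reading of a 10 ms cadence with 10 ms bins; configurable).
Degenerate bins (both variances zero) give 0 when the means agree and a
flagged, capped value of ±10 otherwise, keeping heat maps finite while
marking unreliable bins. Preference is the sign of the mean bias over the
0–300 ms response window, assigned only to units that pass the
responsiveness test (ANOVA + Tukey; only the two baseline-vs-stimulus
contrasts gate the decision, not stimulus-vs-stimulus).

For bias *relative to baseline* (condition B = pre-touch baseline), the
baseline sample pools the individual 10 ms baseline-window bins across
trials rather than per-trial 1.5 s means. With per-trial means the two
conditions live on different variance scales, and zero-count bins of
low-rate units produce d' ≈ −1 artifacts that drag the early population
trace negative; pooled bins keep both sides on the same per-bin scale.

## Facilitation–suppression lag

Units are labeled facilitated or suppressed by a paired two-sided t-test
of the 0–300 ms CR response against the 1.5 s baseline (α = 0.05). Within
a session, every facilitated unit's trial-averaged z-scored CR response
(10 ms bins, 0–300 ms) is cross-correlated with every suppressed unit's.
Correlation uses coefficient normalization (mean-removed traces, zero-lag
autocorrelations = 1) so pairs are comparable before averaging; the lag
grid spans ±300 ms at the trace bin width, exact ties in the minimum
resolve toward the smallest |lag| (negative first). The summary lag is the
unrounded mean of per-pair minimum lags; a suppressed trace equal to a
negated, delayed copy of a facilitated trace recovers minus that delay
exactly, which fixes the sign convention (negative = suppression follows
facilitation).

## Context modulation and occupancy matching

Evoked (`[0, 0.3)` s) and baseline (`[-1.5, 0)` s) rates are contrasted
between reference (Home Hit) and condition (Home Miss, or Away
positive-stimulus) trials: per unit a two-sided Mann–Whitney U on
per-trial z-scored window rates (two-sided because the direction is not
assumed), per population a one-sample t-test on the per-unit delta-z.
Occupancy matching bins trials jointly over behavioral features (8 bins
per feature over the pooled range; joint rather than marginal matching is
the stronger guarantee) and subsamples each condition per cell to the
common minimum without replacement; statistics are computed per
permutation and averaged over 20 permutations. Trials after a Home↔Away
switch are not specially excluded.

## Reaction-time coupling

Lick latency is the first lick strictly after the first touch. Per unit,
the per-Hit-trial baseline rate is correlated with latency (Pearson by
default for population histograms; Spearman exposed — the source analyses
name both and the discrepancy is left unresolved), trials without a
latency excluded pairwise. A population one-sample t-test over per-unit r
values asks whether spontaneous rate predicts reaction time.

## Kinematics

Tracking is 500 fps, 4 labels per whisker, image coordinates (y down).
The whisker angle of a label is the signed angle of the face-point→label
vector against the image vertical, protraction-positive (the sign is a
convention and configurable; the tracked side determines it in practice).
Whisker bending is the Menger curvature `4·area/(d12·d23·d31)` —
reciprocal circumradius, zero for collinear points — averaged over all
C(4,3) label triples. Touch onsets: whisk cycles are delimited by
protraction peaks (minimum prominence 5°, minimum period 40 ms, spanning
a 10–25 Hz whisking envelope); the first outside→inside ROI transition of
the tip label within a cycle is an onset, at most one per cycle,
retraction-phase contacts flagged for the caller to exclude.

## Synthetic sessions

The generator draws spike trains from an inhomogeneous Poisson process by
thinning at 1 ms: homogeneous candidates at the peak rate are kept with
probability rate/peak, which leaves exactly the target process (constant
rates give exponential inter-spike intervals, verified by KS test). One
RNG stream per session, consumed in documented order, makes sessions
bit-reproducible.

The rate model per unit: a log-normal baseline (median 4 sp/s, log-SD
1.1 — covering the <1 to ≥10 sp/s range real populations span), plus a
peak-normalized alpha-like kernel `exp(−t/τ_decay) − exp(−t/τ_rise)`
(onset 5 ms, rise 8 ms, decay 40 ms) per touch with peak amplitude
`2·baseline + 3` sp/s for the preferred stimulus and 10% of that for the
non-preferred one. Touches arrive at 5 Hz through the 1.5 s stimulus;
touches after the first adapt to 10% amplitude (facilitation) — strong
adaptation is what first-touch-aligned averages of real sessions show.
On negative-stimulus trials, positive-preferring units with baseline
≥ 4 sp/s additionally receive a *suppression* kernel — the same shape,
delayed by the facilitation-to-suppression offset (60 ms SC-like, 10 ms
S1-like), with trough depth equal to the baseline rate (rates clip at 0).
Concentrating suppression in higher-rate units mirrors the empirical
suppression–baseline-rate interaction and keeps the suppressed population
detectable above the Poisson noise floor of low-rate units. Suppression
adapts less than facilitation (factor 0.3 vs 0.1): it stands in for
sustained inhibitory gating rather than adapting feed-forward excitation,
and it is what keeps the late CR response below baseline through 300 ms.

Behavioral structure: stimuli are drawn 50/50; the context toggles after
every seven positive-stimulus trials (all Home first); Home positive
trials are Misses when a standard-normal per-trial "readiness" latent
falls below the 25th percentile; Away positive trials are Misses by
construction (no lick possible); negative Home trials are FAs with
probability 0.08. Readiness couples the world together: it scales the
baseline rate of positive-preferring units (`exp(0.25·g)`), and it enters
the lick latency (`0.55 − 0.07·g + N(0, 0.12)` s, floored at 0.1 s), so
Miss trials have lower baselines and higher-baseline trials have shorter
latencies — the correlation structure the latency analysis recovers. The
latency intercept/noise place ~94% of Hit latencies above 0.3 s. Miss
trials halve the evoked response (gain 0.5); Away trials scale the evoked
response by 0.6 and, for positive-preferring units, the baseline by 0.7.
Sessions default to 64 units and 512 trials at 6 s spacing (~51 min; real
sessions run ~90 min).

### Calibration

The response-shape defaults above were calibrated once against the
analyses and then frozen: the facilitation/suppression kernel widths are
matched (40 ms decays) so the pairwise correlogram valley is locally
symmetric about the true lag (mismatched widths skew the noise-perturbed
argmin); the non-preferred gain (0.10) keeps the CR response initially
positive so the population-mean baseline-relative CR bias crosses zero
near 70 ms; and the adaptation split (0.1 facilitation / 0.3 suppression)
prevents the adapted-touch rate plateaus of facilitated and suppressed
traces from anticorrelating at small lags. At the default scale (five
sessions, seeds 1–5) the pooled lag recovers −57 ms (SC-like) and −15 ms
(S1-like), the CR bias crossing lands at 65 ms, and 94% of Hit latencies
exceed 0.3 s.

### What the generator does not emulate

Spike trains are Poisson — no refractoriness, bursting, or spike-count
correlations between units; kernels share one shape across units; touch
times are a homogeneous renewal process rather than whisk-locked; there
is no electrode drift, no unit loss, and no slow engagement trends beyond
the readiness AR structure of the covariates. A green recovery test
therefore establishes that the estimators are unbiased at realistic rate,
trial-count, and effect scales under Poisson variability — not that they
are robust to every pathology of real recordings.

## Numerical choices

- SD floor 0.1 sp/s in z-scoring; d-prime cap ±10 on degenerate bins.
- Tukey HSD via `scipy.stats.tukey_hsd`; Mann–Whitney and t-tests via
  scipy; chi-squared tests via `scipy.stats.chisquare`/`chi2_contingency`.
- Behavioral d' uses the log-linear correction `(hits+0.5)/(n+1)` when
  trial counts are known, else clipping at `1/(2n)` with nominal n = 100.
- Baseline-rate groups are half-open with the boundary joining the
  ≥-side group (a bfr of exactly 4.0 falls in the ≥ 4 group).
- Cross-correlogram ties resolve to the smallest |lag|, negative first.
- Floats are written at full `repr` precision; round-trips are exact.

## Known limitations

- The Phy reader ingests spike times and cluster ids only (plus an
  optional `cluster_info.tsv`); quality metrics and waveforms are out of
  scope, as is NWB.
- `condition_modulation` averages Mann–Whitney p-values over occupancy
  permutations, which is conservative but simple; a combination rule
  (e.g., Rüschendorf) could be swapped in.
- Detection-task effect sizes are assumptions of the generator config,
  not literature-derived values.
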