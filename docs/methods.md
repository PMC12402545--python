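# Methods

`stnmer` analyses depth-sequenced microelectrode recordings (MER) from
deep-brain-stimulation surgery of the subthalamic nucleus (STN), and
ships a synthetic-MER generator so the entire chain can be validated
without patient data. This note documents the signal model, the
analysis definitions, the numerical choices, and what the synthetic
validation does and does not establish.

## Recording model and geometry

A *trajectory* is an ordered sequence of recording sites from ~10 mm
above the planned surgical target down through the STN. Depths are
signed millimetres above the target plane and strictly decrease along
the pass. The intraoperative protocol the package assumes: sites every
0.4 mm before STN entry and every 0.1 mm within the nucleus, ~4 s of
analysed signal per site, with the first six sites taken 0.1 mm apart
at the top of the track (typically internal capsule) as the
normalization baseline.

Along the pass four regions occur in fixed order:

* **PRE** — before the STN: low background noise, sparse firing.
* **DLOR** — dorsolateral oscillating region, the STN motor
  subdomain: raised background noise, high-density multi-unit firing,
  elevated beta-band (13–30 Hz) envelope power in the parkinsonian
  state.
* **VMNR** — ventromedial non-oscillating region, the non-motor
  subdomain: the same raised activity without the low-frequency
  oscillation, relatively broad-band (gamma) envelope activity.
* **POST** — below the ventral border: noise back near baseline.

## Per-site features

1. **Spiking band.** Each trace is band-passed to 300–6000 Hz with a
   4-pole Butterworth applied forward–backward (zero phase; the
   effective stop-band attenuation is squared).
2. **RMS / NRMS.** The root mean square of the band-passed trace is
   normalized per trajectory to the mean RMS of the first `n_baseline`
   sites (default 5, the lower end of the five-to-six convention; the
   generator emits six baseline sites so the default always has
   headroom). The mean baseline NRMS is 1 by construction.
3. **Envelope spectrum.** The band-passed trace is full-wave rectified
   (absolute value), polyphase-resampled to a 1 kHz envelope rate
   (the envelope content of interest is < 200 Hz), mean-removed, and
   Welch-estimated with 3 s Hamming windows and 1 s hops — the
   shortest window giving exactly 1/3 Hz bins, with two overlapping
   windows per 4 s site to reduce variance. The spectrum is expressed
   as *fractions of total power*, so it sums to 1 at every site and is
   invariant to raw-voltage scaling.

   Mean removal matters: the rectified signal has a large DC component
   carrying no oscillation information; without removing it the 0 Hz
   bin dominates the normalization and compresses every other
   fraction. This choice changes all fraction values and is therefore
   applied identically everywhere.
4. **Band fractions.** Sums of the normalized spectrum over half-open
   bands [low, high): delta 1–4, theta 4–7, alpha 8–13, beta 13–30,
   gamma 31–100, tremor 6–12 Hz. Only the beta edges are fixed by
   convention in this problem; the others are conventional defaults
   and configurable.
5. **Beta time series.** Where a continuous beta-band envelope signal
   is needed, the mean-removed envelope is filtered with a 4-pole
   (two poles per edge) Butterworth 13–30 Hz band-pass, forward–
   backward.

The vectorized batch path used for whole trajectories computes exactly
the same numbers as the per-site reference functions (asserted in the
test suite); it exists only because per-site calls carry avoidable
overhead. (`sosfiltfilt` is applied row by row: its native n-D path is
dramatically slower in the installed scipy.)

## Border and subdomain detection

The clinical detection cues are: a step-up in background noise and
high-density firing at entry, elevated beta/low-frequency envelope
power marking the DLOR, relatively more broad-band gamma in the VMNR,
and a noise step-down at exit. The detector is a self-contained
left-to-right decoder over three per-site features — NRMS, a
low-frequency envelope fraction (theta+alpha+beta), and the gamma
fraction — with Gaussian state-conditional emissions whose moments are
estimated from the profile itself: PRE moments from the baseline
sites, in-STN moments from robust quantiles (median/MAD) of the
high-NRMS sites, and the DLOR/VMNR spectral split from the median of
the low-frequency fraction among those sites. Transitions are allowed
only forward (PRE → DLOR → VMNR → POST), so the maximum-likelihood
path reduces to an exact change-point optimization, solved in O(n)
with prefix/suffix maxima of cumulative log-likelihoods.

Conventions and guards:

* a boundary belongs to the **first site of the new state**; segments
  are half-open in depth, `[entry, exit)`;
* a detected STN must contain at least 2 DLOR and 1 VMNR site, with at
  least 3 PRE and 1 POST site retained — this avoids spurious
  zero-length motor regions;
* when the NRMS shows no contrast above baseline (fewer than three
  sites exceeding the PRE mean by `nrms_contrast_z` = 2 baseline SDs),
  the profile is flagged *degenerate*, a warning is emitted, and the
  boundary depths are not meaningful;
* emission SDs are floored at 5% of the corresponding location
  estimate so flat features cannot produce infinite likelihoods.

Expert correction is modelled by `apply_manual_segmentation`, which
snaps given depths to the nearest profile site (ties break to the
shallower site) and records `source="manual"`; ground-truth borders
from simulation are applied the same way with `source="ground_truth"`.
Every segmentation records its source so analyses can be run on
detected or corrected borders.

In ET-like passes (no beta modulation) the DLOR and VMNR are
statistically identical by construction, so only the entry and exit
borders are meaningfully recoverable there; that mirrors the clinical
situation, where the subdomain split rests on the oscillatory
signature.

## Trajectory metrics and group profiles

Trajectories are pooled on a normalized depth axis
`x = (entry − depth)/(entry − exit)`, so the STN spans [0, 1] and a
pre-entrance segment equal to **half the recorded STN length** spans
[−0.5, 0). NRMS and every spectral column are linearly interpolated
onto a fixed 151-point grid (Δx = 0.01); points outside a
trajectory's coverage are missing, never extrapolated, and group
averages are pointwise means over available trajectories with per-point
counts retained.

Scalar metrics (defined on sites, not the grid, so they are
independent of grid resolution):

* **beta ratio** — mean DLOR beta fraction divided by the mean beta
  fraction over pre-entrance sites within the half-length segment.
  The half-length segment is used for the denominator so "outside the
  STN" has a consistent extent across trajectories.
* **mean band power** — mean band fraction over the DLOR for beta and
  lower bands; for gamma the default region is the whole STN (its
  broad-band activity characterizes the full nucleus); the region is a
  parameter. Because the per-site spectrum is defined in normalized
  form, "mean beta power" here is the mean *fraction*.
* **NRMS peak / AUC** — maximum NRMS over STN sites, and the
  trapezoidal integral of NRMS over x ∈ [0, 1] (a constant NRMS of c
  across the STN gives an AUC of c).
* **lengths** — recorded STN length `entry − exit`, DLOR length
  `entry − dlor_exit`, and percent DLOR.

## Group statistics

Each sample is tested for normality (Shapiro–Wilk at α = 0.05); if
both groups pass, an unpaired two-sided t-test is used, otherwise a
two-sided Mann–Whitney U. The reported U follows the smaller-U
convention (min of the two one-sided statistics); p-values are exact
for tie-free combined samples of ≤ 20 and use the tie-corrected normal
approximation otherwise. Multi-band comparisons report both raw and
Bonferroni-adjusted significance (adjusted α = α / number of bands,
e.g. 0.05/4 = 0.0125). ANOVA and Kruskal–Wallis are exposed for three
or more groups. Zero-variance t-tests are refused with an explicit
error. Summaries carry mean, SEM, SD and median, labelled, so either
reporting convention can be used.

## Synthetic-MER generator

Each site is Gaussian background noise (SD = `baseline_noise_sd`
outside the STN, multiplied by `stn_noise_gain` inside) plus the sum
of `n_units` Poisson spike trains convolved with a biphasic
difference-of-Gaussians waveform of ~1 ms total width. Inside the
DLOR the firing rate is sinusoidally modulated,
`λ(t) = r (1 + m sin 2πft)`, with `m = beta_mod_depth` at `beta_freq`
(and optionally a tremor-band term); modulation is absent in all other
regions. Spike times are drawn by thinning, and the waveform is
scatter-added per spike. A single seeded `numpy` generator is threaded
through all operations; identical seeds give bit-identical cohorts.

Defaults and why:

* `sampling_rate` 44 kHz — a typical acquisition rate for this class
  of recording system; the true rate is not standardized, so this is a
  configurable default, not a claim. The floor is 12.5 kHz (the 6 kHz
  band edge must stay below Nyquist).
* geometry — PD-like: 6 mm STN (entry +4, exit −2), 57.1% DLOR;
  ET-like: 4.6 mm STN, 55.4% DLOR; these are the reported group means
  for the two conditions. Post-STN segment: 2 mm of PRE-like signal,
  so exit detection has contrast (no substantia-nigra signature is
  simulated).
* `stn_noise_gain` 2.0 (PD-like) vs 1.5 (ET-like) — the noise step-up
  at entry, with the PD-like excess expressing the attenuated regional
  spiking activity observed in ET.
* rates 5 spikes/s per unit outside vs 60 inside, 10 units — sparse
  background versus high-density STN multi-unit firing.
* `spike_amplitude` 2.0 noise-SD units — calibrated so the in-STN
  multi-unit signal is a modest share of total band power. This keeps
  the generator faithful to the clinical pattern it emulates: the
  injected beta line raises the DLOR beta fraction by roughly a factor
  of two (beta ratio ≈ 1.8–2 in PD-like passes, ≈ 1 in ET-like) while
  leaving delta/theta fractions statistically unchanged between
  groups. With a much stronger multi-unit amplitude the beta line
  carries ~10% of total envelope power and, because fractions must sum
  to one, *depresses* every other band's fraction by a detectable
  amount — a normalization coupling that the clinical data do not
  show, and a known caveat when interpreting fraction-based band
  powers anywhere.
* cohort variability — entry/exit jitter uniform ±1 mm (resampled
  within bounded retries if a draw would violate the geometry
  invariants), per-trajectory rate jitter log-normal with 20% CV.
  Between-trajectory variability is reported clinically but its
  distribution is not; these are documented, configurable choices.

What the generator does **not** emulate: tremor cells and
tremor-synchronous firing, movement or stimulation artefacts,
substantia-nigra signatures below the STN, sedation effects,
single-unit waveform realism, or non-stationarity within a site.
Passing the synthetic validation therefore shows that the analysis
recovers the structure it assumes when that structure is present with
realistic noise — not that real recordings contain no further
structure.

## Validation studies and problem sizes

The `validation` module runs the cohort-scale studies used by the test
suite and the reproduction script. Replicate-heavy studies use
`compact_config` trajectories — the minimum sampling rate (12.5 kHz),
3 s sites (the shortest supporting 1/3 Hz bins), a 2 mm STN with
0.2 mm in-STN steps (1.6 mm and 0.4 mm for the null-calibration
study) — which keep the signal model intact while making a trajectory
~20× cheaper than at acquisition scale. Chosen sizes:

* spectral fidelity: 50 single-site simulations at 44 kHz / 4 s;
* border recovery: 50 trajectories at default geometry and contrast
  (12.5 kHz sampling);
* discrimination: replicated 20-vs-20 cohorts (beta modulation 0.8 vs
  0), Mann–Whitney on per-trajectory beta ratios under ground-truth
  borders (border-detection accuracy is assessed separately);
* null calibration: replicated 10-vs-10 ET-like cohorts;
* demo cohort: 20 vs 20 with detected borders, end to end.

## Known limitations

* The 1/3 Hz Welch estimate from one or two 3 s windows has high
  per-bin variance; narrow-band summaries (delta, theta) are
  correspondingly noisy per site, which the per-trajectory averaging
  only partly offsets.
* The fraction normalization couples bands (see above): strong power
  changes in one band shift all other fractions slightly.
* The border detector estimates its emission moments from the profile
  being decoded; profiles with very few in-STN sites (< ~5) or with no
  NRMS contrast are flagged rather than decoded.
* Group labels are inputs; no electrode-coordinate analysis or
  matching logic is implemented.
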