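# Methods

`tugtrap` models and analyzes the force output of opposing microtubule
motors — cytoplasmic dynein (minus-end) and kinesin (plus-end) — on a
membrane-bounded cargo (a latex-bead phagosome, 750 nm) held in an optical
trap. The package has two halves: a quantitative model of *why* the cargo
reverses direction the way it does (occupancy + kinetics + coin-toss
statistics), and a synthesize-then-detect loop that checks the analysis
pipeline can recover those statistics from realistic position-time records.

## The occupancy model

A spherical cargo touching a microtubule can only engage motors anchored in
a small membrane patch facing the filament — the contact zone, area
`A_contact`. For a 750-nm cargo `A_contact = 0.08 um^2`, which is 4.5% of
the surface `4*pi*R^2`; the working success probability is `p = 0.04`
(both values are exposed; the model defaults to 0.04, the figure used in
all downstream numbers, and `contact_fraction()` computes the geometric
value). With motors distributed uniformly, the number of each species in
the zone is binomial:

    N_zone ~ Binomial(N_total, p)

Copy-number totals come from surface-area scaling of published per-vesicle
counts: `3.5 x (750/90)^2 ~ 240` dyneins, and one-sixth as many kinesins,
`Nk = 40` (a cross-check from a different reference cargo gives
`30 x (750/250)^2 = 270`). On average the zone then holds `240 x 0.04 ~ 10`
dyneins and `40 x 0.04 ~ 2` kinesins.

A reversal needs a dynein team able to win a tug-of-war against at least
one 6-pN kinesin — at 1.1 pN per dynein that means >= 6 dyneins — *and* at
least one kinesin. Because the two species are placed independently, the
joint probability is a product of binomial tails:

    P = P(X >= 6 | 240, 0.04) * P(Y >= 1 | 40, 0.04)
      = 0.9204 * 0.8046 = 0.7406

Tails are computed by `scipy.stats.binom.sf` (regularized incomplete beta),
not a normal approximation: at n = 240 the tail must be exact for the 74%
figure to be reproducible. Tests cross-check against brute-force summation
with `math.comb` and, for the joint probability, full enumeration over
occupancy pairs.

Two time-scale side calculations support the model's static-occupancy
assumption: a membrane protein diffusing at `D = 1.4-10 um^2/s` stays in
the zone for only `T ~ A/(4D) = 2-14 ms` (diffusion does not bias the ~1-s
averaged forces), and the cargo's rotational diffusion
(`D_rot = k_B T / (8 pi eta R^3)`) turns it by only ~1 degree during a
sub-millisecond fly-back, so the same contact zone faces the filament
across consecutive stalls.

## Binding kinetics

Each zone motor binds the filament at `k_on` and unbinds at `k_off`
(dynein: 1.6 / 0.27 s^-1; kinesin: 5 / 1 s^-1). The mean bound fraction
obeys `dC/dt = k_on (1 - C) - k_off C`, giving `C_eq = k_on/(k_on+k_off)`
(0.86 dynein, 0.83 kinesin) and characteristic time `1/(k_on+k_off)`
(0.53 s and 0.17 s). The number bound is a birth-death chain with rates
`lambda_k = (n-k) k_on`, `mu_k = k k_off`; team-assembly times are hitting
times from the empty state, computed two ways:

* exactly, by the standard step-up recursion
  `t_k = 1/lambda_k + (mu_k/lambda_k) t_{k-1}` summed to the threshold
  (itself validated in tests against a linear solve of the hitting-time
  system), and
* by event-driven (Gillespie) Monte Carlo — exact sampling, no time step.

For 6 of 10 dyneins the exact mean is 0.5686 s; for 1 of 2 kinesins 0.1 s.
Both teams therefore assemble within ~0.5 s, which is why 0.5 s is the
natural bin width for inactive-time histograms and the rapid-reversal (RR)
cutoff.

## Coin-toss pair statistics

Labeling each stall by its motor class (K or D) turns a trace into a
symbol sequence. Under the null model the labels are i.i.d. draws — a coin
toss, fair when P(K) = 0.5 — so the four consecutive overlapping pair
types occur as `{KK: q^2, KD: q(1-q), DK: (1-q)q, DD: (1-q)^2}`, all 25%
for the fair coin, and the sequence has no lag-1 memory. The module
simulates such sequences (the coin's bias `p_kinesin` is a first-class
parameter, since biasing the coin is the natural regulatory knob for
directional transport), counts overlapping pairs within — never across —
traces, and tests uniformity (chi-square, df 3) and lag-1 independence
(2x2 contingency, Yates-corrected; refused with an explicit marker on
degenerate tables).

## Trace synthesis

The generator is the package's statement of the study conditions, not a
tunable fixture. A trapped bead with no motors engaged is an overdamped
harmonic oscillator: an Ornstein-Uhlenbeck process with relaxation time
`tau = gamma/K_T` and stationary SD `sqrt(k_B T / K_T)`. It is sampled with
the exact discrete update `x' = a x + sqrt(1-a^2) sigma xi`,
`a = exp(-dt/tau)` (no Euler bias at the 0.5-ms sampling period), with
white detector noise (2 nm) added on top. Defaults: trap stiffness
0.02 pN/nm, 2 kHz sampling, 295 K, drag from Stokes' law on a 750-nm
sphere with 3x water viscosity as a crude near-surface assay value
(tau ~ 1 ms); all configurable.

Motor events are layered deterministically on this bath:

* **Stalls** follow the linear force-velocity relation
  `v(F) = v0 (1 - F/F_stall)` — an exponential approach to the plateau
  `F_stall/K_T` with time constant `F_stall/(K_T v0)`, `v0 = 2 um/s` —
  and hold the plateau so the half-max width equals the programmed stall
  duration (0.7-1.4 s). Kinesin events are 1 or 2 motors x 6 pN, split by
  the occupancy model's conditional single/multi probability (0.40/0.60);
  dynein teams are recruited in pairs by default (2-5 pairs x 2.2 pN,
  giving the ~2-pN force periodicity), or as 1-2 single 1.1-pN motors for
  dynein-depleted-like data. Realized forces get 0.25 pN of scatter.
  Fluctuations during motor engagement are halved (the motor linkage
  stiffens the bead-trap system).
* **Fly-backs** return the cargo to center after detachment. Free
  fly-backs are OU relaxations (complete in a few ms). Tug-of-war
  fly-backs are modeled phenomenologically as a slowed exponential whose
  time constant is set so the 2-SD center band is first entered at the
  programmed resist time (20-80 ms) — the detector's measured fly-back
  then equals the programmed value by construction, giving two cleanly
  separable populations without a full motor-state simulation.
* **Inactive gaps** between events are drawn from a two-component
  mixture: with probability `P_rr` (default = the occupancy model's joint
  probability, 0.7406) a rapid-reversal gap (exponential, mean 0.15 s,
  capped at 0.4 s — the cap keeps programmed RRs from straddling the
  0.5-s threshold once the ~20 ms of detection-side crossing offsets are
  added), else a slow gap (0.7 s + exponential mean 1 s). Reversal RRs
  are additionally tug-of-war with probability 0.5 (the fly-back
  populations are roughly balanced), in which case the gap is zero —
  one team engages during the other's fly-back.
* Event identities come from the coin-toss module; optional **premature
  detachments** (off by default) insert a low-force mid-rise excursion
  before a same-direction stall.

Every event is logged in a ground-truth table (times, team size, force,
fly-back kind, gap, RR label), serialized beside the traces.

What the generator deliberately does not emulate: discrete 8-nm stepping,
ATP dependence, load-dependent (catch-bond) detachment, QPD nonlinearity,
instrument drift, or mid-plateau tug-of-war that never produces a
reversal. Passing recovery tests therefore show the pipeline is correct
for traces whose events are cleanly separable at realistic thermal noise —
not that it is robust to every pathology of real records.

## The detection pipeline

Mirrors manual scoring of trap records:

1. **Center calibration.** The quiet (motor-free) stretch is found
   automatically: dwell levels are histogram modes of the 5-ms
   median-filtered position, tried nearest detector-zero first (the QPD is
   zeroed at the trap center; this keeps a long stall plateau from
   impersonating the center). The noise scale is bootstrapped from the
   lowest decile of deviations, capped by the sample-to-sample noise, and
   contracted by iterated median refinement — necessary when low-force
   stalls sit only a few noise widths from center. The first candidate
   with a >= 0.5-s quiet run (10-ms gaps bridged, 20-ms edge guard) gives
   the center position and a robust (MAD) SD.
2. **Segmentation.** Hysteresis on the filtered distance from center:
   events enter at 2 SD and extend down to 1 SD, suppressing chatter.
3. **Measurement.** Force is `K_T x` position. The stall force is the mean
   raw position over the 100 ms ending at motor release (last sample
   within 90% of the filtered extremum): averaging the held plateau is
   unbiased, whereas the raw maximum of ~10^3 noisy samples is biased high
   by ~2.5 noise SDs — enough to break 5% accuracy at 2 pN. `T_stall` is
   the width at half-maximal filtered force.
4. **Acceptance thresholds** per direction: > 3 pN and > 0.5 s by default;
   a low-force profile (0.7 pN / 0.3 s, minus direction) for
   dynein-depleted data where single 1.1-pN dynein stalls must count.
5. **Premature detachments.** Sub-threshold candidates whose velocity in
   the 0.2 s before release exceeds 5x the median full-stall plateau
   speed (with a 150 nm/s noise floor, and requiring a genuine excursion:
   >= 1 pN, >= 20 ms) are flagged and merged into the following
   same-direction stall, so such episodes count as one event.
6. **Pairing.** Consecutive stalls are typed DD/DK/KD/KK; the intervening
   inactive time is the detected center-dwell (or the raw gap, 0 when
   stalls abut — such pairs are RRs by definition); RR means < 0.5 s.
   Detected gaps carry a ~+20 ms systematic from threshold crossings on
   the rise and fly-back; the generator's gap mixture leaves a margin on
   both sides of the 0.5-s cutoff, so RR classification is unaffected.
7. **Fly-backs** are timed from release to first re-entry into the 2-SD
   band; tug-of-war classification uses a 5-ms threshold (the upper bound
   of free fly-backs) or, assumption-free, a 1-D Otsu split of log-times
   (falling back to the threshold below 4 values).
8. **Histograms and fits.** Inactive times in 0.5-s bins per reversal type
   (the first-bin fraction is the empirical joint-occupancy probability);
   stall forces in 0.5-pN bins with optional max-normalization and simple
   peak-picking; two-component Gaussian fits by EM
   (`sklearn.mixture.GaussianMixture`, 5 restarts, `reg_covar 1e-4`) or
   histogram least squares, with a degeneracy flag when the component
   separation is under 1.5x the summed SDs or a weight collapses below
   0.02; group comparisons by unpaired two-tailed t test.
9. **Recovery scoring** against ground truth: events match on > 50%
   overlap of the truth interval; reports recall/precision, per-event
   force error, the 4x4 pair-type confusion and RR agreement.

## Problem sizes and numerical choices

The study-scale recovery run uses 103 traces x 40 events (~2000 reversal
pairs, ~75 s of 2-kHz record per trace), where the binomial 3-sigma band
on the first-bin fraction is ~3%. Monte-Carlo first passage uses 10^4
replicates (SEM ~0.003 s against the 0.5686-s oracle); coin-toss checks
use 10^5 tosses. Smoothing is a 5-ms median filter everywhere a filtered
trace is used; all randomness flows from a single top-level seed through
`SeedSequence(seed, spawn_key=...)` streams, so any dataset is bit-for-bit
reproducible.

## Known limitations

* The contact fraction is an input (0.04 by default), not derived from
  motor geometry; the 0.0453 geometric value is computed but not used in
  the headline numbers, mirroring the discrepancy in the source estimates.
* Binding kinetics ignore load dependence; dynein's catch bond enters only
  qualitatively through long, high-force dynein-team stalls.
* The center calibration assumes the cargo spends >= 10% of the record
  near the trap center and that the detector zero is near the center; a
  record consisting entirely of stalls is rejected rather than guessed.
* Tug-of-war fly-backs are a two-population phenomenology; the pipeline
  only ever uses their separability, not their shape.
* The mean-field/first-passage layer treats motors as independent and
  identical; cooperative dynein pair-recruitment appears only in the force
  taxonomy of the generator, not in the kinetics.
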