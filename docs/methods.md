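# Methods

This note records the models implemented in `vrmotorlab`, their
assumptions, the defaults and why they were chosen, and what the synthetic
generators do and do not emulate.

## Closed-loop difficulty regulation

The regulated game presents blocks of target trials; a block's success rate
is hits / target trials (false positives — struck distractors — are counted
and diagnosed but never enter the denominator). Success-rate bands drive
the verdict: above 75 % too easy, 50–75 % inclusive the desired band, below
50 % too difficult. Both edges belong to the middle band, so ties are never
ambiguous.

The adjustable state has five dimensions, each oriented so higher is
harder: target exposure level (0–10, mapping 2.0 s down to 0.5 s on-screen
time), working-area level (0–10), distractor count (0–23), the
low-salience (target-like) distractor fraction in steps of 0.25, and cue
mode (visual+auditory → spatial-auditory → none). Their sum is the *total
difficulty index* (0–49). The wide index range is deliberate: it leaves
room for a learner to keep improving over a hundred blocks without pinning
the controller at its ceiling.

The update rule is a deterministic decision table:

- **too easy** — one step up the priority ladder (cues first: they are
  explicit help, so the first help withdrawn; target-like distractors last,
  as the subtlest manipulation). Two steps when the block's success rate was
  ≥ 90 %, which shortens the initial too-easy phase after a cold start.
- **too difficult** — relax what the diagnostics implicate: if more than
  half of the omissions were peripheral (|coordinate| > 0.6 of the
  normalised working area), shrink the area one step and restore one cue;
  else if more than half of the false positives struck target-like
  distractors, lower the salience mix; otherwise lengthen the exposure. A
  generic step-down guarantees progress when the implicated dimension is
  already at its floor, so repeated too-difficult verdicts reach the easiest
  state in finitely many blocks.
- **in band** — no net level change; spawn placement is biased centrally
  when peripheral omissions dominate. Spawn bias is excluded from the
  difficulty index.

Block size is 4 + 2·index target trials, clamped to the game's 1–24 range:
a monotone mapping (better players face longer blocks) chosen for its
simplicity; only the range and the performance dependence are externally
constrained.

**Controller behaviour.** For a stationary player the band controller
equilibrates where upward and downward crossing fluxes balance — near the
band midpoint (~62–66 % success), as the reduced-model oracle test
verifies. For a *learning* player the picture changes: skill growth pushes
the success rate up through the hold band until a > 75 % block triggers an
increase, so the operating point rides close to the 75 % edge for as long
as learning continues. This is why a deployment whose users improve across
the whole intervention shows a long-run mean near 75 %.

## Synthetic learners

A learner hits a target with probability
σ((skill(b) − index)/slope), with skill(b) = asymptote − (asymptote −
baseline)(1 − r)^b after b blocks. Peripheral spawns subtract a per-learner
logit handicap; false positives occur per trial with rate
fp_propensity · (distractors/23) · (0.3 + 0.7·salience_mix), and
target-like distractors are twice as likely to draw the strike.

The default population (`PopulationSpec`) is a calibration to the
feasibility course of a real multi-day deployment: baseline skill
5 ± 1.2, asymptote gain 110 ± 15 index units, learning rate 0.005 ± 0.0012
(clipped to 0.002–0.012), slope 2.5. The small learning rate with a high
asymptote keeps the growth term active across a 100-block session — the
regime discussed above — which yields cohort-median band entry within a
handful of blocks, 60–80 % band occupancy above 90 % of blocks 12–55, and a
post-burn-in mean success rate of 72–75 %. The asymptote is a latent
"skill if practised forever" and may exceed the difficulty range; simulated
skill never reaches it within a session.

What the learner model does **not** emulate: fatigue, day boundaries and
consolidation between sessions, attention lapses, strategy switches, or any
direct coupling between game practice and the kinematic assessment tasks
(the orchestration layer imposes that coupling parametrically, see below).
Passing closed-loop tests therefore show that the controller holds a
well-behaved adaptive learner in band — not that it would hold any human.

## Kinematics

Trajectories are 60 Hz, metres, world frame. Processing:

1. **Filter**: Butterworth low-pass, cutoff 10 Hz at 60 Hz sampling,
   4th order, applied forward–backward (`filtfilt`) — the community default
   for movement data; the effective magnitude response is the square of the
   single-pass response, and tests check it against the analytic form.
2. **Speed**: Euclidean norm of the position derivative, central
   differences in the interior, one-sided at the ends. Gaps beyond 1.5×
   the median interval are an error unless resampling is requested.
3. **SAT** = mean speed (cm/s) / RMS deviation (cm). Mean speed is path
   length over duration — a single robust scalar per task (peak speed is a
   plausible alternative; outcome tables need one number). The error floor
   (0.1 cm) guards perfect traces. SAT's absolute scale is arbitrary; no
   attempt is made to match any particular instrument's units.
4. **Error**: for lines, residuals orthogonal to the line are projected
   onto their dominant direction, i.e. the deviation is scored in a 2D
   assessment plane — line drawing in this kind of VR assessment is
   effectively two-dimensional. For circles the full 3D distance to the
   ideal circle is used. A path-length-ratio error is available behind a
   keyword for sensitivity analyses but is not the default.
5. **SPARC**: magnitude spectrum of the speed signal, zero-padded to 4×
   the next power of two, normalised to V̂(0) = 1 (for a non-negative speed
   signal the DC magnitude is also the maximum). The adaptive cutoff keeps
   frequencies up to the last point with V̂ ≥ 0.05 under a 20 Hz cap; the
   arc length of the curve (frequency axis rescaled to [0, 1]) is negated.
   These are the metric's standard published parameters. SPARC is invariant
   to amplitude scaling and time shifts and decreases with submovement
   count — all property-tested against a brute-force DFT/quadrature oracle.

## Synthetic trajectories

The generator traverses an ideal line or circle with a minimum-jerk speed
profile (peak speed 1.875·D/T) split into n overlapping bursts (25 %
overlap, equal displacement shares — a standard submovement decomposition
that gives controllable smoothness), plus an orthogonal sinusoid (4 full
cycles, so its RMS is exactly amplitude/√2) and white positional noise.
`duration_s` is authoritative; when `mean_speed` is supplied the duration
is derived from the shape's path length instead (the pair is otherwise
overdetermined). Circles deviate out of plane, lines within the dominant
orthogonal direction. Real hand paths have autocorrelated tremor,
drift and corner effects that white noise plus one sinusoid do not capture;
the generator's purpose is metric validation, not biomechanics.

## Synthetic cohorts

Per outcome: participant random intercepts with SD √(sd² − noise²), a
standardised shift at T1/T2 expressed in units of the within-participant
change SD (√2·noise SD — so the configured effect is exactly the paired
Cohen d the analysis estimates), and iid measurement noise. Defaults
follow typical older-adult values for the six-outcome battery (SAT and
SPARC for lines and circles, an integer dexterity count with mean 29 ± 13,
and simple reaction time 398 ± 117 ms with zero true effect as the
designated negative control). All effects default to zero, giving a true
null battery for type-I-error testing.

## Statistics

Per outcome, complete cases only (listwise deletion; the dropped count is
reported): Shapiro–Wilk on each time point, all p > α routing to the
parametric branch; one-way repeated-measures ANOVA (F with df (k−1,
(n−1)(k−1)), η² = SS_effect/(SS_effect+SS_error)) or Friedman χ² with
mid-rank ties. Post hoc: paired t per contrast with Bonferroni (3p) and
paired Cohen d with the Hedges small-sample correction (the correction
makes the estimate near-unbiased; both corrected and raw values are
reported), or Nemenyi/Tukey-style q on Friedman mean ranks
(q = |ΔR̄|/√(k(k+1)/(6n)), p from the studentized range with infinite df)
with Cohen r = |z|/√n from the Wilcoxon signed-rank normal approximation.
Post-hoc tests run only when the omnibus is significant at α.

Two conventions are deliberately pinned and echoed in the output because
the literature is inconsistent: ε² = χ²/(n(k−1)) (the Kendall-W-equivalent
form, maximal at 1 for a perfectly consistent ordering), and "adjusted"
Cohen d = Hedges-corrected paired d. Degenerate inputs (all-tied columns)
short-circuit to statistic 0, p 1 rather than propagating NaNs; constant
columns route to the nonparametric branch with a warning.

## Orchestration

`run_full_experiment` simulates 7 days × 10 blocks per participant, maps
each learner's relative skill gain ρ ∈ [0, 1) to improved assessment
trajectories (deviation amplitude, submovement count and duration shrink by
practice_gain·ρ, with a retention factor 0.9 at follow-up), scores them,
and runs the statistics. Setting practice_gain to 0 yields a verified null
pipeline. Seeding is single-process and deterministic: every stream derives
from the master seed via `SeedSequence`, and the manifest (config + hash +
seed + versions) reproduces a run byte for byte.

## Problem sizes and numerical choices

Simulation sizes used in the test-suite and the acceptance script — 20
learners, 55- and 100-block sessions, 100 random SPARC profiles, 500
null-cohort replicates, 200 recovery replicates, 100 power replicates —
were chosen as the smallest sizes at which the Monte-Carlo error of each
check is comfortably below its tolerance. Tolerances: SPARC vs oracle
1e-6; closed forms 1–2 %; filter response 1 %; type-I error within 3
binomial standard errors of α; effect-size recovery within the 95 % CI of
the replicate mean. Ties in ranks use mid-ranks; filter warm-up shorter
than `filtfilt`'s padding raises a parameter error rather than silently
truncating.

## Known limitations

- The decision table is one faithful reading of a band-based regulator;
  real implementations may adjust several parameters at once or use other
  step sizes. The set-point and boundedness properties, not the exact
  ladder, are the tested contract.
- The 2D assessment plane for line error is an assumption; instruments
  that score lines in 3D will report larger errors.
- ε² conventions differ across software; values are comparable only within
  one convention.
- Cohort generation is compound-symmetric; sphericity violations and their
  corrections are not exercised.
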