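# Methods

This note documents the models, conventions and numerical choices behind
`gaitprofile`, in the order the pipeline uses them.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Laboratory frame and angle conventions

All marker data live in a right-handed laboratory frame with **X** along
the direction of walking progression, **Y** to the subject's left and
**Z** up.  Every writer (TRC, MOT, CSV) uses this frame; TRC files default
to millimetres, all internal computation is in metres and radians, and all
angle outputs are degrees.

Clinical sign conventions, applied identically in both engines: flexion +,
adduction +, internal rotation +, dorsiflexion +, anterior pelvic tilt +,
ipsilateral hemipelvis up + (obliquity), ipsilateral side forward +
(pelvic rotation), in-toeing + (foot progression).  The GPS variable
labelled `hip_abduction` therefore carries the adduction-positive sign, as
on clinical ab/adduction plots.  Cardan sequence everywhere: flexion →
ab/adduction → axial rotation (the conventional-gait-model order); the
same sequence relates the pelvis to the laboratory.

## Skeletal model

A simplified lower-limb chain with the joint structure of standard
multibody gait models: 6-DoF pelvis root; per leg a 3-DoF hip, hinge knee,
hinge tibiotalar joint and hinge subtalar joint; the metatarsophalangeal
joint is rigid.  With free subtalar joints the model has 18 generalized
coordinates, 16 when they are locked.  `build_generic_model()` returns the
unlocked model; the pipeline locks the subtalar joints by default because
their axis is collinear with the heel–toe marker pair and hence
unobservable from this marker set — the same reason gait protocols lock
them.

Geometry is a documented constants table (metres), not a mesh: segment
lengths of a ≈1.55 m subject (femur 0.40, tibia 0.38, foot 0.20
heel-to-toe), Plug-in-Gait marker offsets, and hip joint centres from the
**Bell/Brand regression** (19 % of inter-ASIS breadth posterior, 30 %
distal, 36 % lateral of the mid-ASIS point).  The purely proportional
Bell form was chosen over regressions with constant offset terms (Davis,
Harrington) because it is exactly scale-equivariant: anthropometric
scaling is then auditable to machine precision and idempotent.  Thigh and
shank wand markers sit 12 cm and 9 cm lateral of the segment long axis —
wand-mounted, as in KAD-based protocols; the lever arm is what keeps
axial rotations observable under soft-tissue artefact.

`scale_model` scales the pelvis anisotropically (width from inter-ASIS
breadth, depth from mid-ASIS→SACR, height = geometric mean of the two),
femur/tibia linearly by subject hip→knee and knee→ankle joint-centre
distances over the input model's, and the foot by heel→toe distance; the
returned `ScaleSet` records every factor.  `apply_knee_axis_correction`
rotates one knee flexion axis about the femur long axis; positive angle =
internal (medial) rotation of the axis, the same sense as positive hip
internal rotation.  The KAD hardware itself is not modelled: the
transverse-plane angle is accepted as a scalar input.

## Direct-kinematics engine (`dk`)

Per frame: pelvis frame from LASI/RASI/SACR (Y along the ASIS line, X
anterior in the marker plane); hip centres from the Bell/Brand regression
in that frame; knee and ankle centres from the conventional chord
construction (`chord_joint_centre`: the point coplanar with proximal
centre, lateral marker and wand, at half the joint width from the lateral
marker, with the proximal→centre segment perpendicular to the
centre→marker segment); long-bone frames from the centres plus lateral
markers; foot frame from the heel→toe axis.  A thigh rotation offset
(per side, degrees, internal +) can rotate the wand about the hip→knee
chord before the knee construction — the conventional thigh-offset
adjustment; it is never applied silently.  Marker gaps raise an error
naming frame and label; linear interpolation of gaps ≤ 10 frames exists
behind an explicit flag only.

## Multibody engine (`ik`)

Per frame, the free coordinates minimise Σ_m w_m ‖p_m − FK_m(q)‖² by a
damped Gauss–Newton (Levenberg) iteration with analytic marker Jacobians
(∂p/∂q_j = ω_j × (p − o_j) for rotational DoFs).  Defaults: weights 1 for
anatomical markers and 0.5 for the wand markers (largest artefact);
convergence when the coordinate update norm < 1e-6, cap 100 iterations
(flagged); bounds (hip rotations ±60°, knee −10…140°, ankle ±50°, …)
enforced by projection.  Frames are solved sequentially with warm starts;
frame 1 cold-starts from the neutral pose — this chain is the documented
tie-break between multiple minima, no global search is attempted.  The
damping step accepts only cost-decreasing iterates, so the weighted
objective is non-increasing by construction.  Waveform extraction uses
the same Cardan code as the direct engine on the model's segment frames
(foot = calcaneus segment), so engine differences reflect only the
upstream frame estimates.

## Gait metrics

Waveforms are time-normalised to T = 101 points (0–100 % inclusive, linear
interpolation; T is configurable).  GVS/GPS follow the equations in the
README; the per-limb reference is the pointwise mean over the age-matched
TD limbs (both limbs of each TD subject pooled; groups <10 y, <16 y,
≥16 y).  Each engine is scored **against its own engine's reference**, so
systematic frame offsets between engines cancel within each approach.  The
foot progression angle uses the pelvis-centre displacement over the cycle
as the progression vector and the ankle-centre→TOE line as the foot
vector, both projected into the transverse plane; Symmetry Index =
100·(left − right)/(½(left + right)) (Robinson form; isolated in one
function since the literature varies).

## Synthetic gait laboratory

`synth` generates what the analysis needs and no more:

* **Templates.** The nine variables are Fourier series (constant + two
  harmonics, documented in `DEFAULT_TEMPLATES`) with normative-plausible
  shapes and ranges (knee peak ≈ 45° in swing, hip flexion ≈ 33…−12°,
  cadence 112 steps/min, stride 1.15 m).  They are smooth stylisations,
  not digitised published curves.
* **Deviations** are per-variable constant + first-harmonic offsets on the
  templates.  The chain has no tibial-torsion coordinate, so programmed
  in-toeing is realised through hip internal rotation — the femoral-
  anteversion mechanism that derotation surgery corrects; the emergent
  foot-progression offset equals the pelvic-rotation plus hip-rotation
  offsets.  TD subjects draw zero-mean offsets (SD 2° constant, 1°
  harmonic); operated CP limbs add hip internal rotation ≈ N(15°, 3°) and
  knee flexion ≈ N(6°, 2°) pre-surgery.  Responder limbs receive a fixed
  correction (hip rotation −12°, knee flexion −6°) post-surgery,
  non-responders none; both sessions add N(0, 0.2°) natural variability.
  Ground-truth GPS per limb is the closed-form RMS of these offsets, and
  the simulated clinical label flips the programmed label with
  configurable probability (default 0.3) — a knob, not an estimate.
* **Soft-tissue artefact** per marker is a gait-cycle-locked sinusoid
  (random fixed direction and phase per trial) plus an Ornstein–Uhlenbeck
  walk (τ = 0.15 s), split 50/50 in variance; the per-marker amplitude is
  the RMS of the total displacement.  Defaults: thigh wand 1.9 cm (the
  largest, consistent with reported thigh tracking errors), shank wand
  1.1 cm, sacrum 1.1 cm, knee 0.9 cm, ASIS 0.9 cm, ankle 0.6 cm, foot
  0.5 cm.
* **Trials** sample at 200 Hz (≥ 2 frames per percent of the ≈1.07 s
  cycle) and span n_cycles + ½ cycles so both limbs get n complete
  cycles; heel strikes (0 %/50 % phase) and toe-offs (60 %) are emitted
  exactly.  The default study uses one 3-cycle trial per session rather
  than three 1-cycle trials; per-limb waveforms are averaged over cycles
  either way.
* **Cohort** defaults: TD (12, 10, 12) subjects across the three age
  groups with Table-style anthropometric metadata; 13 CP subjects,
  bilateral surgery (26 operated limbs), responder fraction 0.5.  KAD
  knee-axis angles are drawn per limb (TD ≈ N(0°, 3°), CP pre ≈
  N(12°, 4°), responders corrected by ≈ −10° post) and recorded as
  metadata for the group comparison; they are not applied to either
  engine's model by default, keeping the engine-agreement contrasts free
  of a third varying factor.

What the generator does **not** emulate: real soft-tissue artefact
correlation structure between markers, marker occlusions, bony torsion
deformities, step-to-step timing variability, or kinetics.  Passing tests
therefore demonstrate internal consistency and statistical behaviour of
the pipeline under controlled conditions, not clinical validity on real
motion-capture data.  All subjects share the generic geometry (scale
factors 1): per-subject scaling would be invisible to every downstream
contrast while adding regression-dependent joint-centre offsets;
`scale_model` remains fully implemented and tested.

## Outcome statistics

* ΔGPS is post − pre; responder ⇔ ΔGPS ≤ −MCID (boundary inclusive),
  MCID default 1.6°.
* Between-engine waveform similarity: per-variable RMSD and linear-fit R²
  per cycle, aggregated per subject.
* GPS consistency: Spearman ρ and Wilcoxon signed-rank (zeros dropped,
  average ranks) over all limb observations; ΔGPS agreement: Bland–Altman
  (bias ± 1.96 sample SD) and paired t.
* Pointwise waveform comparison: a paired **max-statistic permutation
  test** per variable (random sign flips of subject difference waveforms;
  the maximum-over-time |t| forms the null), Bonferroni-corrected across
  the nine variables (α = 0.05/9 = 0.0056).  This controls the familywise
  error a random-field-theory SPM would control, while being fully
  self-contained and testable; 1000 permutations by default, with an
  explicit resolution error when α is unreachable.
* Knee-axis corrections: Kruskal–Wallis omnibus plus Dunn pairwise z
  tests with tie correction; unadjusted and Bonferroni-adjusted p both
  reported.
* Agreement tabulation runs over operated limbs only and lists discordant
  limbs with their between-engine ΔGPS difference.

## Determinism and problem sizes

Every random draw flows from a single integer seed through
`numpy.random.SeedSequence`; pipeline outputs are byte-identical across
reruns, and each run writes a manifest with the resolved configuration,
its SHA-256 hash and per-file checksums.  The acceptance script and the
heavier tests use a 26-operated-limb CP cohort with an (4, 3, 4) TD
reference and the default artefact model — large enough for stable rates,
small enough to run in minutes on one CPU; the analysis drivers default to
the full (12, 10, 12) TD cohort.

## Known limitations

* The generic geometry is a stylised average; no subject-specific bone
  torsions, so transverse-plane pathology enters only through joint
  offsets.
* The subtalar joint, though modelled, is locked in practice (marker
  observability), and the foot is a single rigid body.
* The permutation test assumes exchangeable paired differences; with
  fewer than ~8 pairs its α resolution is coarse.
* C3D input is out of scope; TRC (OpenSim dialect) is the interchange
  format, with events in sidecar CSV files.
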