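# gaitprofile

Clinical gait analysis summarises a child's walk into joint-angle waveforms
and, increasingly, into a single gait-quality index — the **Gait Profile
Score (GPS)**.  Two different kinematics engines can produce those
waveforms:

* **direct kinematics** (`dk`): the conventional Plug-in-Gait approach that
  builds each segment frame directly from its markers and extracts Cardan
  angles, and
* **multibody-optimisation inverse kinematics** (`ik`): a weighted
  least-squares fit of a constrained skeletal chain to all markers at once,
  the approach used by musculoskeletal modelling tools.

This package asks the question a gait laboratory faces before switching
engines: *do the two approaches agree on whether a surgery helped?*  It
implements both engines over the same lower-limb model, scores every limb
with the GPS against age-matched references, classifies surgical response at
the GPS minimal clinically important difference, and quantifies engine
agreement — all exercised end to end on a built-in synthetic gait
laboratory, so no motion-capture data are required.

## The score

For kinematic variable *i* (of the canonical nine: pelvic tilt/obliquity/
rotation, hip flexion/abduction/rotation, knee flexion, ankle dorsiflexion,
foot progression), the **Gait Variable Score** of a limb is the RMS
deviation of its time-normalised waveform x from the reference mean x̄ref
over the gait cycle (T points):

    GVS_i = sqrt( (1/T) Σ_t ( x_{i,t} − x̄ref_{i,t} )² )

and the **Gait Profile Score** is the RMS over the N = 9 variables:

    GPS = sqrt( (1/N) Σ_i GVS_i² )

A limb *responds* to surgery when ΔGPS = GPS_post − GPS_pre ≤ −1.6°, the
minimal clinically important difference (MCID) for the GPS.

## Worked example

The numbered drivers under `analysis/` run the study step by step
(`--seed` controls everything; each driver recomputes from scratch):

```sh
python analysis/01_simulate_cohort.py      --seed 1 --outdir results/study
python analysis/04_engine_agreement.py     --seed 1 --outdir results/study
python analysis/05_outcome_classification.py --seed 1 --outdir results/study
```

With seed 1 the simulated cohort holds 34 typically-developing (TD)
subjects (12 children / 10 teenagers / 12 young adults) and 13 cerebral-
palsy subjects observed before and after bilateral femoral derotation
surgery — 26 operated limbs, 19 of them programmed to respond.  Driver 04
prints:

```
GPS consistency over 120 limb observations: Spearman rho = 0.900
  (p = 1.9e-44), mean |difference| = 0.69 deg, Wilcoxon p = 2.24e-18
delta-GPS agreement: bias = 0.27 deg, LoA = [-1.14, 1.68] deg
per-variable RMSD between engines, median (IQR) deg:
  ...
  hip_rotation          6.56 (2.44)
  ...
```

Reading: the engines' GPS values are strongly rank-correlated yet
systematically different (the Wilcoxon p), their estimates of surgical
change agree to within ±1.7° (Bland–Altman limits), and hip rotation — the
variable most exposed to thigh soft-tissue artefact — carries by far the
largest between-engine waveform RMSD.  Driver 05 then prints:

```
26 operated limbs
  dk: recovers 92.3 % of programmed responder labels
  ik: recovers 92.3 % of programmed responder labels
  engine-vs-engine concordance: 26/26 (100.0 %)
knee-axis corrections, Kruskal-Wallis H = 56.7, p = 4.9e-13
```

i.e. both engines recover the programmed surgical outcomes and, more
importantly, agree with *each other* on essentially every limb, while the
simulated knee-axis corrections separate the TD, pre- and post-surgery
groups as expected.

The same machinery is available as a library (`import gaitprofile`) and as
a thin CLI (`python -m gaitprofile all --seed 1 --outdir results/study`).

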