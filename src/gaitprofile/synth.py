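"""Synthetic gait-laboratory data generator.

Produces marker-trajectory trials and cohort metadata with the statistical
structure the downstream analysis assumes:

* a typically-developing (TD) reference cohort in three age subgroups
  (children < 10 y, teenagers < 16 y, young adults >= 16 y);
* a cerebral-palsy (CP) cohort with paired pre/post-surgery sessions whose
  operated limbs carry programmable transverse-plane deviations (elevated
  hip internal rotation, hence in-toeing foot progression) and programmable
  surgical corrections;
* per-marker soft-tissue artefact (STA) noise: the sum of a gait-cycle-locked
  sinusoid and an Ornstein-Uhlenbeck smooth random walk, with the thigh wand
  carrying the largest amplitude by default (~1.9 cm RMS).

Deviations are expressed as per-variable constant + first-harmonic offsets
on the joint-angle templates.  The kinematic chain has no tibial-torsion
coordinate, so programmed foot-progression deviations are realised through
hip internal rotation — the mechanism of femoral anteversion that the
modelled surgery (femoral derotation osteotomy) corrects; the emergent FPA
offset is the sum of the pelvic-rotation and hip-rotation offsets.

Waveform templates are built-in normative-shaped curves stored as Fourier
coefficients (documented constants in :data:`DEFAULT_TEMPLATES`), not
digitised from any published figure.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import VARIABLES, age_group_of
from .model import SkeletalModel, forward_kinematics, joint_centres
from .trial import MarkerTrial

# ---------------------------------------------------------------------------
# Gait pattern
# ---------------------------------------------------------------------------

#: Fourier templates (degrees): value(phi) = a0 + sum_k ak*cos(2 pi k phi) + bk*sin(2 pi k phi).
#: Right-limb clinical conventions; phi = 0 at ipsilateral heel strike.
#: Shapes are normative-plausible (stance/swing structure, ranges of motion
#: typical of barefoot walking) and deliberately simple.
DEFAULT_TEMPLATES: dict[str, tuple[float, tuple[tuple[float, float], ...]]] = {
    "pelvic_tilt":        (10.0, ((0.0, 0.0), (1.5, 0.5))),
    "pelvic_obliquity":   (0.0,  ((0.0, 4.0),)),
    "pelvic_rotation":    (0.0,  ((5.0, 0.0),)),
    "hip_flexion":        (12.9, ((20.8, -4.6), (-3.8, -1.5))),
    "hip_abduction":      (0.0,  ((2.0, 3.0),)),
    "hip_rotation":       (0.0,  ((0.0, 3.0),)),
    "knee_flexion":       (18.8, ((-4.3, -13.1), (-9.8, 7.7))),
    "ankle_dorsiflexion": (2.0,  ((-1.5, 7.5), (-4.0, -6.5))),
    # foot progression is emergent: pelvic_rotation + hip_rotation templates
    "foot_progression":   (0.0,  ((5.0, 3.0),)),
}

#: Variables that drive model coordinates directly (all but the emergent FPA).
COORDINATE_VARIABLES = VARIABLES[:8]


def _eval_fourier(coeffs, phase) -> np.ndarray:
    a0, harmonics = coeffs
    phase = np.asarray(phase, float)
    val = np.full(phase.shape, float(a0))
    for k, (ak, bk) in enumerate(harmonics, start=1):
        val = val + ak * np.cos(2 * np.pi * k * phase) + bk * np.sin(2 * np.pi * k * phase)
    return val


@dataclass
class GaitPattern:
    """Nine periodic joint-angle templates plus per-variable deviation offsets.

    ``deviation_offsets[side][var] = (constant_deg, first_harmonic_deg)``;
    the harmonic perturbation is ``amp * sin(2 pi phi)``.  ``cadence`` is in
    steps/min (a gait cycle is two steps); ``stride_length`` in metres.
    """

    templates: dict[str, tuple] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_TEMPLATES))
    deviation_offsets: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {"right": {}, "left": {}})
    cadence: float = 112.0
    stride_length: float = 1.15

    def __post_init__(self) -> None:
        if set(self.templates) != set(VARIABLES):
            raise ValidationError(
                f"pattern must define exactly the nine variables {VARIABLES}")
        if self.cadence <= 0 or self.stride_length <= 0:
            raise ValidationError("cadence and stride length must be positive")
        for var in VARIABLES:
            v0, v1 = _eval_fourier(self.templates[var], np.array([0.0, 1.0]))
            if abs(v0 - v1) > 1e-9:
                raise ValidationError(f"template {var} is not periodic")

    @property
    def cycle_duration(self) -> float:
        """Seconds per gait cycle (two steps)."""
        return 120.0 / self.cadence

    def evaluate(self, var: str, phase: np.ndarray, side: str = "right") -> np.ndarray:
        """Template + this side's offsets at cycle phase(s) in [0, 1)."""
        base = _eval_fourier(self.templates[var], phase)
        const, harm = self.deviation_offsets.get(side, {}).get(var, (0.0, 0.0))
        return base + const + harm * np.sin(2 * np.pi * np.asarray(phase, float))

    def offset_rms(self, var: str, side: str) -> float:
        """RMS of this side's programmed deviation of ``var`` over the cycle
        (the ground-truth Gait Variable Score contribution)."""
        if var == "foot_progression":
            c = sum(self.deviation_offsets.get(side, {}).get(v, (0.0, 0.0))[0]
                    for v in ("pelvic_rotation", "hip_rotation"))
            h = sum(self.deviation_offsets.get(side, {}).get(v, (0.0, 0.0))[1]
                    for v in ("pelvic_rotation", "hip_rotation"))
        else:
            c, h = self.deviation_offsets.get(side, {}).get(var, (0.0, 0.0))
        return float(np.sqrt(c ** 2 + h ** 2 / 2))

    def ground_truth_gps(self) -> dict[str, float]:
        """Programmed GPS per limb: RMS over the nine per-variable offset RMS
        values, i.e. the GPS this limb would score against an offset-free
        reference in the absence of noise."""
        out = {}
        for side in ("right", "left"):
            g = [self.offset_rms(var, side) for var in VARIABLES]
            out[side] = float(np.sqrt(np.mean(np.square(g))))
        return out

    def with_offsets(self, side: str, updates: dict[str, tuple[float, float]]) -> "GaitPattern":
        new = copy.deepcopy(self)
        for var, (c, h) in updates.items():
            c0, h0 = new.deviation_offsets.setdefault(side, {}).get(var, (0.0, 0.0))
            new.deviation_offsets[side][var] = (c0 + c, h0 + h)
        return new


# ---------------------------------------------------------------------------
# Soft-tissue artefact
# ---------------------------------------------------------------------------

#: Default artefact RMS amplitudes (metres) per marker; the thigh wand is
#: largest (~1.9 cm), consistent with reported marker tracking errors.
DEFAULT_STA_AMPLITUDE = {
    "THI": 0.019, "TIB": 0.011, "KNE": 0.009, "ANK": 0.006,
    "HEE": 0.005, "TOE": 0.005, "ASI": 0.009, "SACR": 0.011,
}


def _amplitude_for(label: str, table: dict[str, float]) -> float:
    if label in table:
        return table[label]
    for key, amp in table.items():
        if label.endswith(key):
            return amp
    return 0.0


@dataclass
class STAModel:
    """Soft-tissue artefact: gait-locked sinusoid + Ornstein-Uhlenbeck walk.

    ``amplitude[label]`` is the target RMS of the total displacement vector
    (metres); a fraction ``harmonic_fraction`` of the displacement variance
    is gait-cycle-locked, the rest is an OU process with correlation time
    ``tau`` seconds.  Amplitudes are matched by suffix (e.g. "THI" covers
    LTHI/RTHI).  ``amplitude=None`` uses the documented defaults; pass an
    empty dict (or :meth:`zero`) for noise-free trials.
    """

    amplitude: dict[str, float] | None = None
    tau: float = 0.15
    harmonic_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.amplitude is None:
            self.amplitude = dict(DEFAULT_STA_AMPLITUDE)
        if any(a < 0 for a in self.amplitude.values()):
            raise ValidationError("STA amplitudes must be non-negative")
        if not 0.0 <= self.harmonic_fraction <= 1.0:
            raise ValidationError("harmonic_fraction must be in [0, 1]")
        if self.tau <= 0:
            raise ValidationError("tau must be positive")

    @classmethod
    def zero(cls) -> "STAModel":
        return cls(amplitude={})

    def sample(self, label: str, times: np.ndarray, cycle_duration: float,
               rng: np.random.Generator) -> np.ndarray:
        """Displacement time series (n, 3) for one marker."""
        times = np.asarray(times, float)
        n = times.size
        amp = _amplitude_for(label, self.amplitude)
        if amp == 0.0:
            return np.zeros((n, 3))
        f = self.harmonic_fraction
        # gait-locked component: amp*sqrt(2 f) * sin(2 pi t/Tc + phase) along a fixed direction
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        phase = rng.uniform(0, 2 * np.pi)
        harmonic = (amp * np.sqrt(2 * f)
                    * np.sin(2 * np.pi * times / cycle_duration + phase))[:, None] * direction
        # OU component, stationary sd per axis amp*sqrt((1-f)/3)
        sd = amp * np.sqrt((1 - f) / 3)
        ou = np.empty((n, 3))
        if sd == 0.0:
            ou[:] = 0.0
        else:
            dt = times[1] - times[0]
            rho = np.exp(-dt / self.tau)
            innov_sd = sd * np.sqrt(1 - rho ** 2)
            ou[0] = rng.normal(scale=sd, size=3)
            noise = rng.normal(scale=innov_sd, size=(n - 1, 3))
            for i in range(1, n):
                ou[i] = rho * ou[i - 1] + noise[i - 1]
        return harmonic + ou


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

DEFAULT_RATE = 200.0    # Hz; >= 2 samples per percent of a ~1 s gait cycle


def _coordinate_trajectory(model: SkeletalModel, pattern: GaitPattern,
                           times: np.ndarray) -> np.ndarray:
    """Joint-coordinate trajectory realising the pattern (radians/metres)."""
    names = model.coordinate_names
    q = np.zeros((times.size, len(names)))
    Tc = pattern.cycle_duration
    phase_r = (times / Tc) % 1.0
    phase_l = (times / Tc + 0.5) % 1.0

    # pelvis height so the feet travel just above the floor
    zero_pose = forward_kinematics(model, np.zeros(model.n_coordinates))
    pelvis_z0 = -min(p[2] for p in zero_pose.values()) + 0.01
    speed = pattern.stride_length / Tc

    deg = np.pi / 180.0
    col = {c: i for i, c in enumerate(names)}
    q[:, col["pelvis_tx"]] = speed * times
    q[:, col["pelvis_ty"]] = 0.01 * np.sin(2 * np.pi * times / Tc)
    q[:, col["pelvis_tz"]] = pelvis_z0 + 0.015 * np.sin(4 * np.pi * times / Tc)
    # pelvis coordinates from the right-limb clinical conventions
    q[:, col["pelvis_tilt"]] = pattern.evaluate("pelvic_tilt", phase_r, "right") * deg
    q[:, col["pelvis_list"]] = -pattern.evaluate("pelvic_obliquity", phase_r, "right") * deg
    q[:, col["pelvis_rotation"]] = pattern.evaluate("pelvic_rotation", phase_r, "right") * deg

    per_side = {
        "hip_flexion": "hip_flexion", "hip_abduction": "hip_adduction",
        "hip_rotation": "hip_rotation", "knee_flexion": "knee_flexion",
        "ankle_dorsiflexion": "ankle_dorsiflexion",
    }
    for side, s, phase in (("right", "r", phase_r), ("left", "l", phase_l)):
        for var, coord in per_side.items():
            q[:, col[f"{coord}_{s}"]] = pattern.evaluate(var, phase, side) * deg
    return q


def generate_trial(model: SkeletalModel, pattern: GaitPattern, n_cycles: int,
                   sta: STAModel, seed: int, rate: float = DEFAULT_RATE,
                   meta: dict | None = None) -> MarkerTrial:
    """Synthesise one walking trial.

    Converts the pattern's joint-angle curves into a coordinate trajectory,
    runs forward kinematics, advances the pelvis along the progression axis
    at the pattern's cadence/stride length, adds soft-tissue artefact to
    every skin marker and records exact heel-strike (0 % / 50 % phase) and
    toe-off (60 %) cycle events.  The trial spans ``n_cycles`` complete
    cycles for each limb (duration (n_cycles + 0.5) cycles).
    """
    if n_cycles < 1:
        raise ValidationError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    Tc = pattern.cycle_duration
    duration = (n_cycles + 0.5) * Tc
    n = int(np.floor(duration * rate)) + 1
    times = np.arange(n) / rate

    q = _coordinate_trajectory(model, pattern, times)
    labels = model.marker_labels
    markers = {label: np.empty((n, 3)) for label in labels}
    for i in range(n):
        pos = forward_kinematics(model, q[i])
        for label in labels:
            markers[label][i] = pos[label]
    for label in labels:
        markers[label] += sta.sample(label, times, Tc, rng)

    t_end = times[-1]
    events = {
        "right": {"hs": [k * Tc for k in range(n_cycles + 1) if k * Tc <= t_end + 1e-9],
                  "to": [(k + 0.6) * Tc for k in range(n_cycles + 1)
                         if (k + 0.6) * Tc <= t_end + 1e-9]},
        "left": {"hs": [(k + 0.5) * Tc for k in range(n_cycles + 1)
                        if (k + 0.5) * Tc <= t_end + 1e-9],
                 "to": [(k + 1.1) * Tc for k in range(n_cycles + 1)
                        if (k + 1.1) * Tc <= t_end + 1e-9]},
    }
    meta = dict(meta or {})
    meta.setdefault("seed", seed)
    meta.update(rate=rate, cadence=pattern.cadence, n_cycles=n_cycles)
    trial = MarkerTrial(time=times, markers=markers, events=events, meta=meta)
    trial.ground_truth_q = q          # noiseless coordinates, for oracles/QC
    trial.ground_truth_pattern = pattern
    return trial


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohortSpec:
    """Study-design knobs of the synthetic cohort.

    Defaults emulate the study conditions: TD subgroups of (12, 10, 12)
    subjects (children/teenagers/young adults), a CP cohort observed pre and
    post surgery with both limbs operated, elevated internal hip rotation
    (hence in-toeing) and mild crouch pre-surgery, and a derotation-style
    correction applied to responder limbs post-surgery.  ``surgical_effect``
    / ``non_responder_effect`` are per-variable constant corrections in
    degrees added to the operated limb's deviation offsets after surgery.
    """

    n_td: tuple[int, int, int] = (12, 10, 12)
    n_cp: int = 13
    responder_fraction: float = 0.5
    surgical_effect: dict[str, float] = field(
        default_factory=lambda: {"hip_rotation": -12.0, "knee_flexion": -6.0})
    non_responder_effect: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    # deviation model
    td_offset_sd: tuple[float, float] = (2.0, 1.0)       # (constant, harmonic) deg
    cp_hip_rotation_offset: tuple[float, float] = (15.0, 3.0)   # mean, sd deg
    cp_knee_flexion_offset: tuple[float, float] = (6.0, 2.0)
    session_jitter_sd: float = 0.2
    clinical_disagreement: float = 0.3
    operated_bilateral_fraction: float = 1.0
    # trial structure
    trials_per_session: int = 1
    n_cycles: int = 3
    rate: float = DEFAULT_RATE
    sta: STAModel = field(default_factory=STAModel)
    # KAD knee-axis angles (recorded metadata, deg): TD ~ N(0, kad_td_sd);
    # CP pre ~ N(mean, sd); responders post receive kad_correction on average
    kad_td_sd: float = 3.0
    kad_cp_pre: tuple[float, float] = (12.0, 4.0)
    kad_correction: tuple[float, float] = (-10.0, 2.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValidationError("responder_fraction must be in [0, 1]")
        if not 0.0 <= self.clinical_disagreement <= 1.0:
            raise ValidationError("clinical_disagreement must be in [0, 1]")
        if len(self.n_td) != 3 or any(n < 0 for n in self.n_td):
            raise ValidationError("n_td must be three non-negative counts")


@dataclass
class CohortBundle:
    """Trials plus metadata and ground truth for one synthetic study."""

    trials: list[MarkerTrial]
    metadata: pd.DataFrame          # one row per subject
    ground_truth: pd.DataFrame      # one row per (subject, limb)
    patterns: dict                  # (subject, session) -> GaitPattern
    spec: SyntheticCohortSpec


_AGE_DISTS = {"children": (7.5, 1.4, 4.0, 9.9), "teenagers": (11.8, 1.8, 10.0, 15.9),
              "young_adults": (27.8, 6.2, 16.0, 45.0)}
_MASS_HEIGHT = {"children": (28.4, 1.31), "teenagers": (44.9, 1.52),
                "young_adults": (68.7, 1.75)}


def _draw_td_offsets(rng, sd_const, sd_harm, sides=("right", "left")):
    """Zero-mean subject-level deviation offsets (pelvis shared, limbs free)."""
    offsets = {side: {} for side in sides}
    tilt_c, tilt_h = rng.normal(0, sd_const), rng.normal(0, sd_harm)
    obl_h, rot_h = rng.normal(0, sd_harm), rng.normal(0, sd_harm)
    # The pelvis is shared: its coordinates are driven by the right-limb
    # offsets, and the per-limb sign conventions make the left limb see the
    # same first-harmonic obliquity/rotation deviation and a phase-flipped
    # tilt harmonic.  Constant obliquity/rotation offsets are not drawn
    # because a shared pelvis cannot give both limbs one.
    for side in sides:
        sgn = 1.0 if side == "right" else -1.0
        offsets[side]["pelvic_tilt"] = (tilt_c, sgn * tilt_h)
        offsets[side]["pelvic_obliquity"] = (0.0, obl_h)
        offsets[side]["pelvic_rotation"] = (0.0, rot_h)
        for var in ("hip_flexion", "hip_abduction", "hip_rotation",
                    "knee_flexion", "ankle_dorsiflexion"):
            offsets[side][var] = (rng.normal(0, sd_const), rng.normal(0, sd_harm))
        offsets[side]["foot_progression"] = (0.0, 0.0)   # emergent
    return offsets


def _jitter(offsets, rng, sd):
    out = {side: dict(d) for side, d in offsets.items()}
    for side in out:
        for var, (c, h) in out[side].items():
            if var == "foot_progression":
                continue
            out[side][var] = (c + rng.normal(0, sd), h)
    return out


def generate_cohort(spec: SyntheticCohortSpec, model: SkeletalModel) -> CohortBundle:
    """Generate the full synthetic study: TD reference cohort plus paired
    pre/post CP cohort with ground-truth and simulated clinical labels."""
    rng = np.random.default_rng(spec.seed)
    trial_seeds = iter(np.random.SeedSequence(spec.seed).generate_state(100000) % (2 ** 31))

    trials: list[MarkerTrial] = []
    meta_rows, gt_rows = [], []
    patterns: dict = {}

    def make_trials(subject, session, pattern, group):
        for k in range(spec.trials_per_session):
            trials.append(generate_trial(
                model, pattern, spec.n_cycles, spec.sta, int(next(trial_seeds)),
                rate=spec.rate,
                meta={"subject": subject, "session": session, "trial_id": k, "group": group}))
        patterns[(subject, session)] = pattern

    # --- TD reference cohort ---------------------------------------------
    for group, n in zip(("children", "teenagers", "young_adults"), spec.n_td):
        mu, sd, lo, hi = _AGE_DISTS[group]
        for j in range(n):
            subject = f"td_{group}_{j:02d}"
            age = float(np.clip(rng.normal(mu, sd), lo, hi))
            mass0, height0 = _MASS_HEIGHT[group]
            pattern = GaitPattern()
            pattern.deviation_offsets = _draw_td_offsets(rng, *spec.td_offset_sd)
            make_trials(subject, "control", pattern, "TD")
            meta_rows.append({"subject": subject, "group": "TD", "age_subgroup": group,
                              "age": age, "mass": float(rng.normal(mass0, mass0 * 0.1)),
                              "height": float(rng.normal(height0, height0 * 0.05)),
                              "seed": spec.seed})
            for side in ("right", "left"):
                gt_rows.append({"subject": subject, "side": side, "group": "TD",
                                "operated": False, "responder_true": None,
                                "clinical_label": None,
                                "gt_gps_pre": pattern.ground_truth_gps()[side],
                                "gt_gps_post": None, "gt_delta_gps": None,
                                "kad_angle_pre": float(rng.normal(0, spec.kad_td_sd)),
                                "kad_angle_post": None, "seed": spec.seed})

    # --- CP cohort: paired pre/post --------------------------------------
    for j in range(spec.n_cp):
        subject = f"cp_{j:02d}"
        age = float(np.clip(rng.normal(8.8, 3.0), 4.0, 15.9))
        bilateral = rng.random() < spec.operated_bilateral_fraction
        operated = ("right", "left") if bilateral else (rng.choice(["right", "left"]),)

        pre = GaitPattern()
        pre.deviation_offsets = _draw_td_offsets(rng, *spec.td_offset_sd)
        limb_info = {}
        for side in ("right", "left"):
            if side in operated:
                dev = {
                    "hip_rotation": (rng.normal(*spec.cp_hip_rotation_offset), 0.0),
                    "knee_flexion": (rng.normal(*spec.cp_knee_flexion_offset), 0.0),
                }
                pre = pre.with_offsets(side, dev)
                responder = bool(rng.random() < spec.responder_fraction)
            else:
                responder = None
            limb_info[side] = responder

        post = _jitter(copy.deepcopy(pre).deviation_offsets, rng, spec.session_jitter_sd)
        post_pattern = GaitPattern()
        post_pattern.deviation_offsets = post
        for side in operated:
            effect = spec.surgical_effect if limb_info[side] else spec.non_responder_effect
            post_pattern = post_pattern.with_offsets(
                side, {var: (c, 0.0) for var, c in effect.items()})

        make_trials(subject, "pre", pre, "CP")
        make_trials(subject, "post", post_pattern, "CP")
        meta_rows.append({"subject": subject, "group": "CP",
                          "age_subgroup": age_group_of(age), "age": age,
                          "mass": float(rng.normal(26.1, 9.2)),
                          "height": float(rng.normal(1.26, 0.16)), "seed": spec.seed})

        gps_pre = pre.ground_truth_gps()
        gps_post = post_pattern.ground_truth_gps()
        for side in ("right", "left"):
            responder = limb_info[side]
            clinical = None
            if responder is not None:
                truth = "responder" if responder else "non-responder"
                flip = rng.random() < spec.clinical_disagreement
                clinical = ({"responder": "non-responder",
                             "non-responder": "responder"}[truth] if flip else truth)
            kad_pre = float(rng.normal(*spec.kad_cp_pre))
            kad_post = kad_pre + (float(rng.normal(*spec.kad_correction))
                                  if responder else float(rng.normal(0, 2.0)))
            gt_rows.append({
                "subject": subject, "side": side, "group": "CP",
                "operated": side in operated,
                "responder_true": None if responder is None else
                    ("responder" if responder else "non-responder"),
                "clinical_label": clinical,
                "gt_gps_pre": gps_pre[side], "gt_gps_post": gps_post[side],
                "gt_delta_gps": gps_post[side] - gps_pre[side],
                "kad_angle_pre": kad_pre, "kad_angle_post": kad_post,
                "seed": spec.seed})

    return CohortBundle(trials=trials, metadata=pd.DataFrame(meta_rows),
                        ground_truth=pd.DataFrame(gt_rows), patterns=patterns, spec=spec)
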