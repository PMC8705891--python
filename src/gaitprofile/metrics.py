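"""Gait Profile Score, Gait Variable Score and supporting waveform metrics.

The Gait Variable Score (GVS) of kinematic variable *i* is the root mean
square, over the normalised gait cycle, of the deviation of a limb's
waveform from the mean waveform of a non-pathological reference group:

    GVS_i = sqrt( (1/T) * sum_t (x_{i,t} - xref_{i,t})^2 )

and the Gait Profile Score (GPS) is the RMS of the N per-variable scores:

    GPS = sqrt( (1/N) * sum_i GVS_i^2 )

computed here over the canonical nine variables (degrees).  Sign
conventions: flexion +, adduction +, internal rotation +, dorsiflexion +,
anterior pelvic tilt +, ipsilateral pelvis up + (obliquity), ipsilateral
side forward + (pelvic rotation), in-toeing + (foot progression).
Note that the "hip_abduction" variable therefore carries the clinical
adduction-positive sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ValidationError

#: Canonical variable order (Baker's nine-variable gait vector).
VARIABLES = (
    "pelvic_tilt", "pelvic_obliquity", "pelvic_rotation",
    "hip_flexion", "hip_abduction", "hip_rotation",
    "knee_flexion", "ankle_dorsiflexion", "foot_progression",
)

#: Default normalised-cycle grid: 0..100 % inclusive.
DEFAULT_T = 101

AGE_GROUP_LABELS = ("children", "teenagers", "young_adults")


def age_group_of(age: float, boundaries: tuple[float, float] = (10.0, 16.0)) -> str:
    """Age subgroup assignment: children < boundaries[0] <= teenagers <
    boundaries[1] <= young adults."""
    if age < boundaries[0]:
        return "children"
    if age < boundaries[1]:
        return "teenagers"
    return "young_adults"


@dataclass
class GaitCycleWaveforms:
    """The nine time-normalised kinematic variables for one limb and cycle."""

    values: np.ndarray                      # (9, T) degrees
    side: str
    cycle_id: int = 0
    variables: tuple[str, ...] = VARIABLES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if tuple(self.variables) != VARIABLES:
            raise ValidationError(f"variables must be the canonical nine: {VARIABLES}")
        if self.values.ndim != 2 or self.values.shape[0] != 9 or self.values.shape[1] < 2:
            raise ValidationError(f"values must be (9, T>=2), got {self.values.shape}")

    @property
    def T(self) -> int:
        return int(self.values.shape[1])

    def variable(self, name: str) -> np.ndarray:
        return self.values[self.variables.index(name)]


@dataclass
class ReferenceProfile:
    """Per-variable mean waveform of an age-matched non-pathological group."""

    values: np.ndarray                      # (9, T) degrees
    n_subjects: int
    age_group: str
    variables: tuple[str, ...] = VARIABLES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if tuple(self.variables) != VARIABLES:
            raise ValidationError("reference variables must be the canonical nine")
        if self.values.shape[0] != 9 or self.values.ndim != 2:
            raise ValidationError("reference values must be (9, T)")


@dataclass
class GVSVector:
    scores: np.ndarray                      # (9,) degrees, >= 0
    limb: str
    session: str = ""
    variables: tuple[str, ...] = VARIABLES

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        if (self.scores < 0).any():
            raise ValidationError("GVS scores must be non-negative")


@dataclass
class GPSScore:
    value: float
    N: int
    limb: str
    session: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("GPS must be non-negative")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def time_normalise(raw: np.ndarray, times: np.ndarray, cycle_start: float,
                   cycle_end: float, T: int = DEFAULT_T) -> np.ndarray:
    """Interpolate a per-frame signal onto T evenly spaced points spanning
    [0 %, 100 %] of the cycle (endpoints interpolated at the event times)."""
    raw = np.asarray(raw, float)
    times = np.asarray(times, float)
    if cycle_end <= cycle_start:
        raise ValidationError("cycle_end must exceed cycle_start")
    if cycle_start < times[0] - 1e-9 or cycle_end > times[-1] + 1e-9:
        raise ValidationError("cycle events lie outside the trial time range")
    if int(T) < 2:
        raise ValidationError("T must be >= 2")
    inside = np.count_nonzero((times >= cycle_start) & (times <= cycle_end))
    if inside < 2:
        raise ValidationError("fewer than two samples inside the cycle")
    grid = np.linspace(cycle_start, cycle_end, int(T))
    return np.interp(grid, times, raw)


def average_trials(waveform_sets: list[GaitCycleWaveforms]) -> GaitCycleWaveforms:
    """Pointwise mean waveform across cycles/trials of one limb."""
    if not waveform_sets:
        raise ValidationError("average_trials needs at least one waveform set")
    T = waveform_sets[0].T
    side = waveform_sets[0].side
    for w in waveform_sets:
        if w.T != T:
            raise ValidationError("mismatched time grids in average_trials")
        if w.side != side:
            raise ValidationError("average_trials mixes limbs")
    mean = np.mean([w.values for w in waveform_sets], axis=0)
    return GaitCycleWaveforms(values=mean, side=side, cycle_id=-1,
                              meta=dict(waveform_sets[0].meta, averaged_over=len(waveform_sets)))


def gvs(waveforms: GaitCycleWaveforms, reference: ReferenceProfile) -> GVSVector:
    """Gait Variable Scores: per-variable RMS deviation from the reference."""
    if waveforms.values.shape != reference.values.shape:
        raise ValidationError(
            f"waveform grid {waveforms.values.shape} != reference grid {reference.values.shape}")
    diff = waveforms.values - reference.values
    scores = np.sqrt(np.mean(diff ** 2, axis=1))
    return GVSVector(scores=scores, limb=waveforms.side,
                     session=str(waveforms.meta.get("session", "")))


def gps(gvs_vector: GVSVector) -> GPSScore:
    """Gait Profile Score: RMS of the per-variable GVS values."""
    scores = np.asarray(gvs_vector.scores, float)
    if scores.size == 0:
        raise ValidationError("empty GVS vector")
    value = float(np.sqrt(np.mean(scores ** 2)))
    return GPSScore(value=value, N=int(scores.size), limb=gvs_vector.limb,
                    session=gvs_vector.session)


def foot_progression_angle(pelvis_centre_trajectory: np.ndarray,
                           ankle_jc_trajectory: np.ndarray,
                           toe_trajectory: np.ndarray,
                           times: np.ndarray,
                           cycle_start: float, cycle_end: float,
                           T: int = DEFAULT_T, side: str = "right") -> np.ndarray:
    """Foot progression angle over one gait cycle, degrees, in-toeing +.

    The direction of progression is the vector from the pelvis centre at
    initial heel strike to its position at the end of the cycle; the foot
    vector joins the ankle joint centre to the TOE marker.  The angle
    between the two is taken after projection in the transverse (XY) plane,
    signed so that internal rotation of the foot (in-toeing) is positive
    for either limb.
    """
    times = np.asarray(times, float)
    pelvis = np.asarray(pelvis_centre_trajectory, float)
    ankle = np.asarray(ankle_jc_trajectory, float)
    toe = np.asarray(toe_trajectory, float)

    p0 = np.array([np.interp(cycle_start, times, pelvis[:, k]) for k in range(2)])
    p1 = np.array([np.interp(cycle_end, times, pelvis[:, k]) for k in range(2)])
    prog = p1 - p0
    if np.linalg.norm(prog) < 1e-9:
        raise GeometryError("no net pelvis displacement over the cycle (zero progression vector)")

    foot = (toe - ankle)[:, :2]
    # signed angle from progression to foot about +Z (CCW positive)
    cross = prog[0] * foot[:, 1] - prog[1] * foot[:, 0]
    dot = foot @ prog
    theta = np.degrees(np.arctan2(cross, dot))
    if side not in ("right", "left"):
        raise ValidationError(f"side must be right|left, got {side!r}")
    fpa = theta if side == "right" else -theta
    return time_normalise(fpa, times, cycle_start, cycle_end, T)


def symmetry_index(gps_left: GPSScore, gps_right: GPSScore) -> float:
    """Robinson Symmetry Index on GPS: 100 * (L - R) / (0.5 * (L + R))."""
    left, right = gps_left.value, gps_right.value
    mean = 0.5 * (left + right)
    if mean <= 0:
        raise ValidationError("Symmetry Index undefined: both GPS values are zero")
    return float(100.0 * (left - right) / mean)


def build_reference(td_waveforms: list[GaitCycleWaveforms], ages: list[float],
                    age_groups: tuple[float, float] = (10.0, 16.0)
                    ) -> dict[str, ReferenceProfile]:
    """Age-group reference profiles: pointwise mean across TD limb waveforms.

    Both limbs of each TD subject are pooled; group boundaries default to
    <10 (children), <16 (teenagers), >=16 (young adults) years.
    """
    if len(td_waveforms) != len(ages):
        raise ValidationError("td_waveforms and ages must have equal length")
    buckets: dict[str, list[GaitCycleWaveforms]] = {g: [] for g in AGE_GROUP_LABELS}
    for w, age in zip(td_waveforms, ages):
        buckets[age_group_of(age, age_groups)].append(w)
    out: dict[str, ReferenceProfile] = {}
    for group, members in buckets.items():
        if not members:
            raise ValidationError(f"empty reference age group: {group}")
        T = members[0].T
        if any(m.T != T for m in members):
            raise ValidationError("mismatched grids across reference waveforms")
        out[group] = ReferenceProfile(
            values=np.mean([m.values for m in members], axis=0),
            n_subjects=len({m.meta.get("subject", id(m)) for m in members}),
            age_group=group)
    return out
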