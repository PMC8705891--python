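"""Constrained lower-limb kinematic chain.

The model is a simplified lower-limb skeleton with the joint structure used
by multibody gait models: a 6-DoF pelvis root, a 3-DoF ball hip, a 1-DoF
hinge knee, a 1-DoF tibiotalar (ankle) hinge and a 1-DoF subtalar hinge per
leg; the metatarsophalangeal joint is permanently locked (the foot distal to
the subtalar joint is one rigid body).  Segment geometry is a documented
constants table of published-average segment lengths and Plug-in-Gait marker
offsets — no mesh or inertial content, only kinematic structure.

Laboratory frame convention (documented in every writer):
    X = direction of walking progression, Y = subject's left, Z = up
(right-handed).  At the zero pose every segment frame is aligned with the
laboratory frame, the subject stands upright facing +X, and the left/right
marker clouds are mirror images about the sagittal (XZ) plane.

Angle conventions are encoded in the joint axes so that a positive
generalized coordinate is always the clinically positive direction:
flexion +, adduction +, internal rotation +, dorsiflexion +, anterior
pelvic tilt +.  Pelvis list is + when the left side rises and pelvis
rotation is + when the right side advances; per-limb clinical signs are
applied at waveform extraction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError, GeometryError, ValidationError

# Plug-in-Gait lower-limb labels that every model must carry.
MANDATORY_MARKERS = (
    "LASI", "RASI", "SACR",
    "LTHI", "LKNE", "LTIB", "LANK", "LHEE", "LTOE",
    "RTHI", "RKNE", "RTIB", "RANK", "RHEE", "RTOE",
)

SIDES = ("right", "left")


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise GeometryError("zero-length vector cannot be normalised")
    return v / n


def rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    k = _unit(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0.0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1.0 - np.cos(angle_rad)) * (K @ K)


@dataclass
class Segment:
    """One rigid body of the chain.

    ``joint_axes`` are unit vectors expressed in the *parent* segment frame;
    rotational DoFs compose in list order (intrinsic sequence), translational
    DoFs translate the joint origin along the axis.  ``local_markers`` are in
    the segment's own frame, metres.
    """

    name: str
    parent: str | None
    joint_origin_in_parent: np.ndarray
    joint_axes: list[np.ndarray]
    joint_dof_types: list[str]          # "rot" | "trans"
    coordinate_names: list[str]
    local_markers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.joint_origin_in_parent = np.asarray(self.joint_origin_in_parent, float)
        self.joint_axes = [np.asarray(a, float) for a in self.joint_axes]
        self.local_markers = {k: np.asarray(v, float) for k, v in self.local_markers.items()}
        if len(self.joint_axes) != len(self.joint_dof_types):
            raise ValidationError(f"segment {self.name}: axes/DoF-type length mismatch")
        if len(self.joint_axes) != len(self.coordinate_names):
            raise ValidationError(f"segment {self.name}: axes/coordinate-name length mismatch")
        for a in self.joint_axes:
            if abs(np.linalg.norm(a) - 1.0) > 1e-9:
                raise ValidationError(f"segment {self.name}: joint axis not unit length")
        for t in self.joint_dof_types:
            if t not in ("rot", "trans"):
                raise ValidationError(f"segment {self.name}: bad DoF type {t!r}")


@dataclass
class SkeletalModel:
    """Topologically sorted chain (pelvis first) with named coordinates."""

    segments: list[Segment]
    coordinate_bounds: dict[str, tuple[float, float]]
    knee_axis_correction_deg: dict[str, float] = field(
        default_factory=lambda: {"right": 0.0, "left": 0.0})
    locked_coordinates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        labels: set[str] = set()
        for seg in self.segments:
            if seg.parent is not None and seg.parent not in seen:
                raise ValidationError(
                    f"segment {seg.name}: parent {seg.parent} not defined before child")
            seen.add(seg.name)
            dup = labels & set(seg.local_markers)
            if dup:
                raise ValidationError(f"duplicate marker labels {sorted(dup)}")
            labels |= set(seg.local_markers)

    # -- coordinate bookkeeping -------------------------------------------
    @property
    def all_coordinate_names(self) -> list[str]:
        return [c for seg in self.segments for c in seg.coordinate_names]

    @property
    def coordinate_names(self) -> list[str]:
        """Free (unlocked) coordinates, in chain order."""
        return [c for c in self.all_coordinate_names if c not in self.locked_coordinates]

    @property
    def n_coordinates(self) -> int:
        return len(self.coordinate_names)

    @property
    def marker_labels(self) -> list[str]:
        return [m for seg in self.segments for m in seg.local_markers]

    def segment(self, name: str) -> Segment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def full_q(self, q: np.ndarray) -> dict[str, float]:
        """Map a free-coordinate vector to {coordinate: value}, locked at 0."""
        q = np.asarray(q, float)
        if q.shape != (self.n_coordinates,):
            raise ValidationError(
                f"q has length {q.size}, model has {self.n_coordinates} free coordinates")
        out = dict.fromkeys(self.all_coordinate_names, 0.0)
        out.update(zip(self.coordinate_names, q))
        return out

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.coordinate_bounds[c][0] for c in self.coordinate_names])
        hi = np.array([self.coordinate_bounds[c][1] for c in self.coordinate_names])
        return lo, hi


@dataclass
class Anthropometry:
    """Subject measurements used by scaling and the direct-kinematics engine."""

    leg_length: float
    ASIS_breadth: float
    knee_width: float
    ankle_width: float
    mass: float = 30.0
    height: float = 1.30
    age: float = 10.0

    def __post_init__(self) -> None:
        for name in ("leg_length", "ASIS_breadth", "knee_width", "ankle_width",
                     "mass", "height", "age"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"anthropometry field {name} must be positive")


@dataclass
class ScaleSet:
    """Audit record of the factors applied by :func:`scale_model`."""

    pelvis_factors: np.ndarray            # (depth, width, height) on (x, y, z)
    femur_factor: dict[str, float]
    tibia_factor: dict[str, float]
    foot_factor: dict[str, float]

    def __post_init__(self) -> None:
        self.pelvis_factors = np.asarray(self.pelvis_factors, float)
        if not (self.pelvis_factors > 0).all():
            raise ValidationError("pelvis scale factors must be positive")
        for d in (self.femur_factor, self.tibia_factor, self.foot_factor):
            if not all(v > 0 for v in d.values()):
                raise ValidationError("scale factors must be positive")


# ---------------------------------------------------------------------------
# Generic geometry constants (metres).  Published-average lower-limb segment
# lengths for a ~1.55 m subject with Plug-in-Gait marker placements; the
# pelvis origin is the mid-ASIS point and hip joint centres follow the
# Bell/Brand regression evaluated on this same pelvis geometry, so the two
# kinematic engines share identical joint centres at the zero pose.
# ---------------------------------------------------------------------------
GENERIC_GEOMETRY = {
    "asis_half_breadth": 0.12,
    "sacr_offset": np.array([-0.15, 0.0, 0.0]),
    "femur_length": 0.40,
    "tibia_length": 0.38,
    "knee_half_width": 0.05,
    "ankle_half_width": 0.04,
    # wand markers stand well off the segment surface (mounted on wands), so
    # their lever arm about the long axis keeps axial rotations observable
    "thigh_wand": np.array([0.0, 0.12, -0.22]),     # lateral offset sign set per side
    "shank_wand": np.array([0.0, 0.09, -0.18]),
    "subtalar_origin_in_talus": np.array([-0.02, 0.0, -0.03]),
    "heel_in_calcn": np.array([-0.04, 0.0, 0.0]),
    "toe_in_calcn": np.array([0.16, 0.0, 0.0]),
}

#: Bell/Brand hip-joint-centre regression: fractions of inter-ASIS breadth.
#: In the pelvis frame (origin mid-ASIS, X anterior, Y left, Z up) the hip
#: centre lies 19 % of the breadth posterior, 30 % distal and 36 % lateral
#: of the mid-ASIS point.  The purely proportional form is exactly
#: scale-equivariant, which keeps anthropometric scaling auditable.
BELL_FRACTIONS = {"ap": -0.19, "vert": -0.30, "lat": 0.36}


def hip_centre_regression(asis_breadth: float, side: str) -> np.ndarray:
    """Hip joint centre in the pelvis frame from the Bell/Brand regression."""
    if asis_breadth <= 0:
        raise GeometryError("ASIS breadth must be positive for HJC regression")
    lat = BELL_FRACTIONS["lat"] * asis_breadth
    return np.array([BELL_FRACTIONS["ap"] * asis_breadth,
                     -lat if side == "right" else lat,
                     BELL_FRACTIONS["vert"] * asis_breadth])


_DEG = np.pi / 180.0

DEFAULT_BOUNDS = {
    "pelvis_tx": (-50.0, 50.0), "pelvis_ty": (-50.0, 50.0), "pelvis_tz": (-2.0, 3.0),
    "pelvis_tilt": (-45 * _DEG, 45 * _DEG),
    "pelvis_list": (-45 * _DEG, 45 * _DEG),
    "pelvis_rotation": (-45 * _DEG, 45 * _DEG),
}
for _s in ("r", "l"):
    DEFAULT_BOUNDS.update({
        f"hip_flexion_{_s}": (-45 * _DEG, 120 * _DEG),
        f"hip_adduction_{_s}": (-60 * _DEG, 60 * _DEG),
        f"hip_rotation_{_s}": (-60 * _DEG, 60 * _DEG),
        f"knee_flexion_{_s}": (-10 * _DEG, 140 * _DEG),
        f"ankle_dorsiflexion_{_s}": (-50 * _DEG, 50 * _DEG),
        f"subtalar_{_s}": (-30 * _DEG, 30 * _DEG),
    })


def build_generic_model(marker_set_spec: list[str] | None = None,
                        subtalar_locked: bool = False) -> SkeletalModel:
    """Build the generic lower-limb model.

    ``marker_set_spec`` lists the marker labels the laboratory uses; it must
    cover the mandatory Plug-in-Gait lower-limb set.  With the subtalar
    joints free the model has 6 + 2*(3+1+1+1) = 18 generalized coordinates;
    ``subtalar_locked=True`` removes the two subtalar hinges (16 free).
    """
    spec = list(marker_set_spec) if marker_set_spec is not None else list(MANDATORY_MARKERS)
    missing = [m for m in MANDATORY_MARKERS if m not in spec]
    if missing:
        raise ConfigurationError(f"marker set is missing mandatory label(s): {missing}")

    g = GENERIC_GEOMETRY
    pw = 2 * g["asis_half_breadth"]
    pd = float(np.linalg.norm(g["sacr_offset"]))

    segments = [Segment(
        name="pelvis", parent=None,
        joint_origin_in_parent=np.zeros(3),
        joint_axes=[np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]),
                    np.array([0, 1.0, 0]), np.array([1.0, 0, 0]), np.array([0, 0, 1.0])],
        joint_dof_types=["trans", "trans", "trans", "rot", "rot", "rot"],
        coordinate_names=["pelvis_tx", "pelvis_ty", "pelvis_tz",
                          "pelvis_tilt", "pelvis_list", "pelvis_rotation"],
        local_markers={
            "LASI": np.array([0.0, g["asis_half_breadth"], 0.0]),
            "RASI": np.array([0.0, -g["asis_half_breadth"], 0.0]),
            "SACR": g["sacr_offset"].copy(),
        },
    )]

    for side, s, ysgn in (("right", "r", -1.0), ("left", "l", 1.0)):
        hip = hip_centre_regression(pw, side)
        mirror = np.array([1.0, ysgn, 1.0])
        # axis sign for adduction / internal rotation flips across the midline
        axsgn = -ysgn  # +1 right, -1 left
        segments.append(Segment(
            name=f"femur_{s}", parent="pelvis",
            joint_origin_in_parent=hip,
            joint_axes=[np.array([0.0, -1.0, 0.0]),          # flexion +
                        np.array([axsgn, 0.0, 0.0]),         # adduction +
                        np.array([0.0, 0.0, axsgn])],        # internal rotation +
            joint_dof_types=["rot"] * 3,
            coordinate_names=[f"hip_flexion_{s}", f"hip_adduction_{s}", f"hip_rotation_{s}"],
            local_markers={
                f"{s.upper()}THI": g["thigh_wand"] * mirror,
                f"{s.upper()}KNE": np.array([0.0, ysgn * g["knee_half_width"],
                                             -g["femur_length"]]),
            },
        ))
        segments.append(Segment(
            name=f"tibia_{s}", parent=f"femur_{s}",
            joint_origin_in_parent=np.array([0.0, 0.0, -g["femur_length"]]),
            joint_axes=[np.array([0.0, 1.0, 0.0])],          # knee flexion +
            joint_dof_types=["rot"],
            coordinate_names=[f"knee_flexion_{s}"],
            local_markers={
                f"{s.upper()}TIB": g["shank_wand"] * mirror,
                f"{s.upper()}ANK": np.array([0.0, ysgn * g["ankle_half_width"],
                                             -g["tibia_length"]]),
            },
        ))
        segments.append(Segment(
            name=f"talus_{s}", parent=f"tibia_{s}",
            joint_origin_in_parent=np.array([0.0, 0.0, -g["tibia_length"]]),
            joint_axes=[np.array([0.0, -1.0, 0.0])],         # dorsiflexion +
            joint_dof_types=["rot"],
            coordinate_names=[f"ankle_dorsiflexion_{s}"],
        ))
        segments.append(Segment(
            name=f"calcn_{s}", parent=f"talus_{s}",
            joint_origin_in_parent=g["subtalar_origin_in_talus"] * mirror,
            joint_axes=[np.array([axsgn, 0.0, 0.0])],        # inversion +
            joint_dof_types=["rot"],
            coordinate_names=[f"subtalar_{s}"],
            local_markers={
                f"{s.upper()}HEE": g["heel_in_calcn"] * mirror,
                f"{s.upper()}TOE": g["toe_in_calcn"] * mirror,
            },
        ))

    locked = ("subtalar_r", "subtalar_l") if subtalar_locked else ()
    return SkeletalModel(segments=segments, coordinate_bounds=dict(DEFAULT_BOUNDS),
                         locked_coordinates=locked)


def lock_subtalar(model: SkeletalModel, locked: bool = True) -> SkeletalModel:
    """Return a copy with the subtalar hinges locked at 0 (or freed)."""
    out = copy.deepcopy(model)
    out.locked_coordinates = ("subtalar_r", "subtalar_l") if locked else ()
    return out


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------

def segment_frames(model: SkeletalModel, q: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-segment world (rotation, origin) for coordinate vector ``q``.

    Rotational DoFs compose in list order as an intrinsic sequence; axes are
    expressed in the parent frame.
    """
    qmap = model.full_q(q)
    frames: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for seg in model.segments:
        if seg.parent is None:
            Rp, op = np.eye(3), np.zeros(3)
        else:
            Rp, op = frames[seg.parent]
        origin = op + Rp @ seg.joint_origin_in_parent
        Rj = np.eye(3)
        for axis, dof, cname in zip(seg.joint_axes, seg.joint_dof_types, seg.coordinate_names):
            val = qmap[cname]
            if dof == "trans":
                origin = origin + Rp @ (axis * val)
            else:
                Rj = Rj @ rotation_about(axis, val)
        frames[seg.name] = (Rp @ Rj, origin)
    return frames


def forward_kinematics(model: SkeletalModel, q: np.ndarray) -> dict[str, np.ndarray]:
    """Global marker positions for coordinate vector ``q`` (metres)."""
    frames = segment_frames(model, q)
    out: dict[str, np.ndarray] = {}
    for seg in model.segments:
        R, o = frames[seg.name]
        for label, local in seg.local_markers.items():
            out[label] = o + R @ local
    return out


def joint_centres(model: SkeletalModel, q: np.ndarray) -> dict[str, np.ndarray]:
    """World positions of the joint origins (hip/knee/ankle/subtalar) plus
    the pelvis origin — used by the synthetic generator and QC."""
    frames = segment_frames(model, q)
    out = {"pelvis_origin": frames["pelvis"][1]}
    names = {"femur": "hip", "tibia": "knee", "talus": "ankle", "calcn": "subtalar"}
    for seg in model.segments:
        if seg.parent is None:
            continue
        Rp, op = frames[seg.parent]
        base = seg.name.rsplit("_", 1)
        out[f"{names[base[0]]}_{base[1]}"] = op + Rp @ seg.joint_origin_in_parent
    return out


# ---------------------------------------------------------------------------
# Knee-axis correction and scaling
# ---------------------------------------------------------------------------

def apply_knee_axis_correction(model: SkeletalModel, side: str,
                               kad_axis_angle_deg: float) -> SkeletalModel:
    """Rotate one knee flexion axis in the femur transverse plane.

    ``kad_axis_angle_deg`` is the KAD-derived transverse-plane angle; the
    sign convention is positive = internal (medial) rotation of the flexion
    axis, i.e. the same sense as positive hip internal rotation of that side.
    The rotation is about the femur's vertical (long) axis; all other axes
    are untouched.
    """
    if side not in SIDES:
        raise ValidationError(f"side must be one of {SIDES}, got {side!r}")
    if not abs(kad_axis_angle_deg) < 90:
        raise ValidationError("knee axis correction must satisfy |angle| < 90 deg")
    out = copy.deepcopy(model)
    s = "r" if side == "right" else "l"
    sgn = 1.0 if side == "right" else -1.0
    tibia = out.segment(f"tibia_{s}")
    R = rotation_about(np.array([0.0, 0.0, 1.0]), sgn * kad_axis_angle_deg * _DEG)
    tibia.joint_axes[0] = R @ tibia.joint_axes[0]
    out.knee_axis_correction_deg = dict(out.knee_axis_correction_deg)
    out.knee_axis_correction_deg[side] = out.knee_axis_correction_deg.get(side, 0.0) \
        + kad_axis_angle_deg
    return out


def _static_positions(static_markers) -> dict[str, np.ndarray]:
    """Time-average marker positions of a quasi-static trial (or accept a
    plain {label: xyz} mapping)."""
    if isinstance(static_markers, dict):
        return {k: np.asarray(v, float) for k, v in static_markers.items()}
    return {label: np.asarray(static_markers.markers[label], float).reshape(-1, 3).mean(axis=0)
            for label in static_markers.markers}


def scale_model(model: SkeletalModel, static_markers,
                anthropometry: Anthropometry) -> tuple[SkeletalModel, ScaleSet]:
    """Scale the generic model to a subject from a static pose.

    The pelvis is scaled anisotropically (depth from mid-ASIS→SACR, width
    from inter-ASIS breadth, height = geometric mean of the two); femur and
    tibia linearly by the subject hip→knee and knee→ankle joint-centre
    distances over the generic ones; the foot by heel→toe distance.  Joint
    centres of the subject are computed from the static markers exactly as
    the direct-kinematics engine computes them (Bell/Brand hip regression,
    chord knee/ankle construction), making the procedure auditable and
    idempotent.
    """
    from .directkin import chord_joint_centre, pelvis_frame_from_markers

    pos = _static_positions(static_markers)
    missing = [m for m in MANDATORY_MARKERS if m not in pos]
    if missing:
        raise ConfigurationError(f"static trial is missing marker(s): {missing}")

    width = float(np.linalg.norm(pos["LASI"] - pos["RASI"]))
    if width < 1e-6:
        raise GeometryError("zero inter-ASIS breadth in static trial")
    mid_asis = 0.5 * (pos["LASI"] + pos["RASI"])
    depth = float(np.linalg.norm(mid_asis - pos["SACR"]))
    if depth < 1e-6:
        raise GeometryError("zero ASIS-sacrum depth in static trial")

    R_pelvis, origin = pelvis_frame_from_markers(pos["LASI"], pos["RASI"], pos["SACR"])

    # reference lengths come from the *input* model (not the generic
    # constants), which makes the procedure idempotent on scaled models
    pelvis_markers = model.segment("pelvis").local_markers
    gen_width = float(np.linalg.norm(pelvis_markers["LASI"] - pelvis_markers["RASI"]))
    gen_depth = float(np.linalg.norm(
        0.5 * (pelvis_markers["LASI"] + pelvis_markers["RASI"]) - pelvis_markers["SACR"]))
    wf, df = width / gen_width, depth / gen_depth
    pelvis_factors = np.array([df, wf, float(np.sqrt(wf * df))])

    femur_f, tibia_f, foot_f = {}, {}, {}
    for side, s in (("right", "r"), ("left", "l")):
        S = s.upper()
        gen_femur = float(np.linalg.norm(model.segment(f"tibia_{s}").joint_origin_in_parent))
        gen_tibia = float(np.linalg.norm(model.segment(f"talus_{s}").joint_origin_in_parent))
        calcn = model.segment(f"calcn_{s}").local_markers
        gen_foot = float(np.linalg.norm(calcn[f"{S}TOE"] - calcn[f"{S}HEE"]))
        hjc = origin + R_pelvis @ hip_centre_regression(width, side)
        kjc = chord_joint_centre(hjc, pos[f"{S}KNE"], pos[f"{S}THI"],
                                 anthropometry.knee_width / 2)
        ajc = chord_joint_centre(kjc, pos[f"{S}ANK"], pos[f"{S}TIB"],
                                 anthropometry.ankle_width / 2)
        femur_f[side] = float(np.linalg.norm(kjc - hjc)) / gen_femur
        tibia_f[side] = float(np.linalg.norm(ajc - kjc)) / gen_tibia
        foot_f[side] = float(np.linalg.norm(pos[f"{S}TOE"] - pos[f"{S}HEE"])) / gen_foot

    out = copy.deepcopy(model)
    pelvis = out.segment("pelvis")
    for label in pelvis.local_markers:
        pelvis.local_markers[label] = pelvis.local_markers[label] * pelvis_factors
    for side, s in (("right", "r"), ("left", "l")):
        femur = out.segment(f"femur_{s}")
        femur.joint_origin_in_parent = femur.joint_origin_in_parent * pelvis_factors
        for label in femur.local_markers:
            femur.local_markers[label] = femur.local_markers[label] * femur_f[side]
        tibia = out.segment(f"tibia_{s}")
        tibia.joint_origin_in_parent = tibia.joint_origin_in_parent * femur_f[side]
        for label in tibia.local_markers:
            tibia.local_markers[label] = tibia.local_markers[label] * tibia_f[side]
        talus = out.segment(f"talus_{s}")
        talus.joint_origin_in_parent = talus.joint_origin_in_parent * tibia_f[side]
        calcn = out.segment(f"calcn_{s}")
        calcn.joint_origin_in_parent = calcn.joint_origin_in_parent * foot_f[side]
        for label in calcn.local_markers:
            calcn.local_markers[label] = calcn.local_markers[label] * foot_f[side]

    scales = ScaleSet(pelvis_factors=pelvis_factors, femur_factor=femur_f,
                      tibia_factor=tibia_f, foot_factor=foot_f)
    return out, scales


def anthropometry_of(model: SkeletalModel, mass: float = 30.0, height: float = 1.30,
                     age: float = 10.0) -> Anthropometry:
    """Anthropometric measurements consistent with a model's zero pose."""
    q0 = np.zeros(model.n_coordinates)
    pos = forward_kinematics(model, q0)
    jc = joint_centres(model, q0)
    return Anthropometry(
        leg_length=float(np.linalg.norm(pos["RASI"] - jc["ankle_r"])),
        ASIS_breadth=float(np.linalg.norm(pos["LASI"] - pos["RASI"])),
        knee_width=2 * float(np.linalg.norm(pos["RKNE"] - jc["knee_r"])),
        ankle_width=2 * float(np.linalg.norm(pos["RANK"] - jc["ankle_r"])),
        mass=mass, height=height, age=age,
    )


# ---------------------------------------------------------------------------
# Serialization (human-readable YAML; loss-free round trip)
# ---------------------------------------------------------------------------

def model_to_dict(model: SkeletalModel) -> dict:
    return {
        "frame_convention": "X=progression, Y=left, Z=up (right-handed)",
        "segments": [{
            "name": seg.name,
            "parent": seg.parent,
            "joint_origin_in_parent": seg.joint_origin_in_parent.tolist(),
            "joint_axes": [a.tolist() for a in seg.joint_axes],
            "joint_dof_types": list(seg.joint_dof_types),
            "coordinate_names": list(seg.coordinate_names),
            "local_markers": {k: v.tolist() for k, v in seg.local_markers.items()},
        } for seg in model.segments],
        "coordinate_bounds": {k: list(v) for k, v in model.coordinate_bounds.items()},
        "knee_axis_correction_deg": dict(model.knee_axis_correction_deg),
        "locked_coordinates": list(model.locked_coordinates),
    }


def model_from_dict(d: dict) -> SkeletalModel:
    segments = [Segment(
        name=s["name"], parent=s["parent"],
        joint_origin_in_parent=np.array(s["joint_origin_in_parent"]),
        joint_axes=[np.array(a) for a in s["joint_axes"]],
        joint_dof_types=list(s["joint_dof_types"]),
        coordinate_names=list(s["coordinate_names"]),
        local_markers={k: np.array(v) for k, v in s["local_markers"].items()},
    ) for s in d["segments"]]
    return SkeletalModel(
        segments=segments,
        coordinate_bounds={k: tuple(v) for k, v in d["coordinate_bounds"].items()},
        knee_axis_correction_deg=dict(d["knee_axis_correction_deg"]),
        locked_coordinates=tuple(d["locked_coordinates"]),
    )


def save_model(model: SkeletalModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> SkeletalModel:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))
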