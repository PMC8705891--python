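"""Direct (Plug-in-Gait-style) kinematics engine.

Builds segment frames directly from marker triads frame by frame — pelvis
from LASI/RASI/SACR, hip joint centres from the Bell/Brand regression, knee
and ankle centres from the conventional-gait-model chord construction — and
extracts Cardan joint angles in the clinical sequence
flexion -> ab/adduction -> internal/external rotation ("yxz" in the
laboratory axis naming of this package).

Marker gaps (NaN samples) raise :class:`~gaitprofile.errors.GapError` by
default; optional linear interpolation of gaps up to 10 frames sits behind
an explicit flag because silent gap filling corrupts downstream RMSD
comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GapError, GeometryError, ValidationError
from .metrics import (DEFAULT_T, VARIABLES, GaitCycleWaveforms,
                      foot_progression_angle, time_normalise)
from .model import Anthropometry, hip_centre_regression, rotation_about
from .trial import MarkerTrial

MAX_GAP_FRAMES = 10


@dataclass
class SegmentFrames:
    """Per-frame orthonormal rotations and origins per segment, plus the
    joint-centre trajectories used for scaling audit and FPA."""

    rotations: dict[str, np.ndarray]       # name -> (n, 3, 3)
    origins: dict[str, np.ndarray]         # name -> (n, 3)
    joint_centres: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, R in self.rotations.items():
            RtR = np.einsum("nij,nik->njk", R, R)
            if not np.allclose(RtR, np.eye(3), atol=1e-9):
                raise ValidationError(f"segment {name}: rotations not orthonormal")
            if not np.allclose(np.linalg.det(R), 1.0, atol=1e-9):
                raise ValidationError(f"segment {name}: rotation determinant != +1")


# ---------------------------------------------------------------------------
# Geometric primitives
# ---------------------------------------------------------------------------

def chord_joint_centre(proximal_jc: np.ndarray, lateral_marker: np.ndarray,
                       wand_marker: np.ndarray, offset: float) -> np.ndarray:
    """Conventional-gait-model chord construction.

    Returns the point J in the plane of the three inputs with
    |J - lateral_marker| = offset and (J - proximal_jc) perpendicular to
    (lateral_marker - J).  Of the two in-plane solutions the one on the
    opposite side of the proximal->lateral chord from the wand is taken
    (the wand sits lateral/anterior, the joint centre medial).

    Vectorised over a leading frame axis: inputs may be (3,) or (n, 3).
    """
    P = np.atleast_2d(np.asarray(proximal_jc, float))
    L = np.atleast_2d(np.asarray(lateral_marker, float))
    W = np.atleast_2d(np.asarray(wand_marker, float))
    if offset <= 0:
        raise ValidationError("chord offset must be positive")
    u_raw = P - L
    D = np.linalg.norm(u_raw, axis=1)
    if np.any(D <= offset):
        raise GeometryError(
            "chord construction infeasible: offset >= proximal-to-lateral distance")
    u = u_raw / D[:, None]
    n_raw = np.cross(u_raw, W - L)
    n_norm = np.linalg.norm(n_raw, axis=1)
    if np.any(n_norm < 1e-9 * np.maximum(D, 1.0)):
        raise GeometryError("chord construction degenerate: collinear input points")
    n = n_raw / n_norm[:, None]
    v = np.cross(n, u)
    a = offset ** 2 / D
    b = np.sqrt(offset ** 2 - a ** 2)
    J = L + a[:, None] * u - b[:, None] * v
    return J[0] if np.asarray(proximal_jc).ndim == 1 else J


def pelvis_frame_from_markers(lasi: np.ndarray, rasi: np.ndarray,
                              sacr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pelvis frame: origin mid-ASIS; Y along RASI->LASI; X anterior in the
    marker plane (mid-ASIS minus SACR); Z completes right-handed frame.

    Vectorised over a leading frame axis ((n,3) inputs -> (n,3,3), (n,3)).
    """
    single = np.asarray(lasi).ndim == 1
    lasi = np.atleast_2d(np.asarray(lasi, float))
    rasi = np.atleast_2d(np.asarray(rasi, float))
    sacr = np.atleast_2d(np.asarray(sacr, float))
    y_raw = lasi - rasi
    ny = np.linalg.norm(y_raw, axis=1)
    if np.any(ny < 1e-9):
        raise GeometryError("coincident ASIS markers")
    y = y_raw / ny[:, None]
    origin = 0.5 * (lasi + rasi)
    x_prov = origin - sacr
    z_raw = np.cross(x_prov, y)
    nz = np.linalg.norm(z_raw, axis=1)
    if np.any(nz < 1e-9):
        raise GeometryError("collinear pelvis markers")
    z = z_raw / nz[:, None]
    x = np.cross(y, z)
    R = np.stack([x, y, z], axis=2)        # columns are the axes
    if single:
        return R[0], origin[0]
    return R, origin


def cardan_angles(parent_R: np.ndarray, child_R: np.ndarray,
                  sequence: str = "yxz", signs: tuple[int, int, int] = (1, 1, 1),
                  gimbal_tol_deg: float = 0.5, warn_gimbal: bool = True) -> np.ndarray:
    """Cardan decomposition of parent_R^T @ child_R, degrees.

    ``sequence`` names the intrinsic rotation order; the clinical gait
    sequence flexion -> ab/adduction -> axial rotation corresponds to "yxz"
    in this package's segment axes.  ``signs`` maps the raw axis rotations
    onto clinically signed angles (e.g. (-1, 1, 1) when the flexion axis of
    the joint is -Y).  Poses with the middle angle within ``gimbal_tol_deg``
    of +/-90 deg are flagged with a warning.
    """
    parent_R = np.asarray(parent_R, float)
    child_R = np.asarray(child_R, float)
    for name, R in (("parent", parent_R), ("child", child_R)):
        if R.shape[-2:] != (3, 3) or not np.allclose(
                np.swapaxes(R, -1, -2) @ R, np.eye(3), atol=1e-6):
            raise ValidationError(f"{name} rotation is not orthonormal")
    if sequence.lower() != "yxz":
        raise ValidationError(f"unsupported Cardan sequence {sequence!r}")
    M = np.swapaxes(parent_R, -1, -2) @ child_R
    single = M.ndim == 2
    M = M.reshape(-1, 3, 3)
    beta = np.arcsin(np.clip(-M[:, 1, 2], -1.0, 1.0))
    alpha = np.arctan2(M[:, 0, 2], M[:, 2, 2])
    gamma = np.arctan2(M[:, 1, 0], M[:, 1, 1])
    ang = np.degrees(np.stack([alpha, beta, gamma], axis=1)) * np.asarray(signs, float)
    if warn_gimbal and np.any(np.abs(np.abs(np.degrees(beta)) - 90.0) < gimbal_tol_deg):
        warnings.warn("Cardan decomposition near gimbal lock (middle angle ~ +/-90 deg)",
                      stacklevel=2)
    return ang[0] if single else ang


def recompose_cardan(angles_deg: np.ndarray, sequence: str = "yxz",
                     signs: tuple[int, int, int] = (1, 1, 1)) -> np.ndarray:
    """Inverse of :func:`cardan_angles` (test oracle and sanity tool)."""
    if sequence.lower() != "yxz":
        raise ValidationError(f"unsupported Cardan sequence {sequence!r}")
    a, b, c = (np.radians(np.asarray(angles_deg, float)) * np.asarray(signs, float))
    axes = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}
    return (rotation_about(axes["y"], a) @ rotation_about(axes["x"], b)
            @ rotation_about(axes["z"], c))


# ---------------------------------------------------------------------------
# Gap handling
# ---------------------------------------------------------------------------

def _check_gaps(trial: MarkerTrial, interpolate_gaps: bool) -> dict[str, np.ndarray]:
    markers = {}
    for label, arr in trial.markers.items():
        bad = np.isnan(arr).any(axis=1)
        if not bad.any():
            markers[label] = arr
            continue
        if not interpolate_gaps:
            frame = int(np.argmax(bad))
            raise GapError(f"marker {label} missing at frame {frame} "
                           "(enable interpolate_gaps to fill gaps <= "
                           f"{MAX_GAP_FRAMES} frames)")
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0])))[::2]
        if bad[0] or bad[-1] or (runs > MAX_GAP_FRAMES).any():
            frame = int(np.argmax(bad))
            raise GapError(f"marker {label}: gap at frame {frame} too long or at "
                           "trial boundary; cannot interpolate")
        filled = arr.copy()
        good = ~bad
        for k in range(3):
            filled[bad, k] = np.interp(trial.time[bad], trial.time[good], arr[good, k])
        markers[label] = filled
    return markers


# ---------------------------------------------------------------------------
# Frame construction
# ---------------------------------------------------------------------------

def _limb_frame(proximal_jc, distal_jc, lateral_marker, side) -> np.ndarray:
    """Long-bone frame: Z along distal->proximal, Y toward the subject's
    left, X anterior; identity at the model zero pose."""
    z = proximal_jc - distal_jc
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    if side == "right":
        y_prov = distal_jc - lateral_marker
    else:
        y_prov = lateral_marker - distal_jc
    x_raw = np.cross(y_prov, z)
    nx = np.linalg.norm(x_raw, axis=1)
    if np.any(nx < 1e-9):
        raise GeometryError("degenerate limb frame (lateral marker on the long axis)")
    x = x_raw / nx[:, None]
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=2)


def build_pig_frames(trial: MarkerTrial, anthropometry: Anthropometry,
                     thigh_offset_deg: dict[str, float] | None = None,
                     interpolate_gaps: bool = False) -> SegmentFrames:
    """Build pelvis/femur/tibia/foot frames from markers for every frame.

    ``thigh_offset_deg`` rotates each thigh wand about the hip->KNE chord
    (internal rotation positive) before the knee-centre construction, the
    conventional thigh-rotation-offset adjustment; it affects knee and ankle
    centres but never the hip centres.
    """
    thigh_offset_deg = thigh_offset_deg or {"right": 0.0, "left": 0.0}
    pos = _check_gaps(trial, interpolate_gaps)

    R_pelvis, origin = pelvis_frame_from_markers(pos["LASI"], pos["RASI"], pos["SACR"])
    width = float(np.mean(np.linalg.norm(pos["LASI"] - pos["RASI"], axis=1)))
    depth = float(np.mean(np.linalg.norm(
        0.5 * (pos["LASI"] + pos["RASI"]) - pos["SACR"], axis=1)))

    rotations = {"pelvis": R_pelvis}
    origins = {"pelvis": origin}
    jcs: dict[str, np.ndarray] = {}

    for side, s in (("right", "r"), ("left", "l")):
        S = s.upper()
        hjc_local = hip_centre_regression(width, side)
        hjc = origin + np.einsum("nij,j->ni", R_pelvis, hjc_local)

        thi = pos[f"{S}THI"]
        off = float(thigh_offset_deg.get(side, 0.0))
        if off != 0.0:
            axis = pos[f"{S}KNE"] - hjc
            axis = axis / np.linalg.norm(axis, axis=1, keepdims=True)
            sgn = 1.0 if side == "right" else -1.0
            thi = np.stack([
                hjc[i] + rotation_about(axis[i], sgn * np.radians(off)) @ (thi[i] - hjc[i])
                for i in range(thi.shape[0])])

        kjc = chord_joint_centre(hjc, pos[f"{S}KNE"], thi, anthropometry.knee_width / 2)
        ajc = chord_joint_centre(kjc, pos[f"{S}ANK"], pos[f"{S}TIB"],
                                 anthropometry.ankle_width / 2)

        R_femur = _limb_frame(hjc, kjc, pos[f"{S}KNE"], side)
        R_tibia = _limb_frame(kjc, ajc, pos[f"{S}ANK"], side)

        x_f = pos[f"{S}TOE"] - pos[f"{S}HEE"]
        x_f = x_f / np.linalg.norm(x_f, axis=1, keepdims=True)
        y_tib = R_tibia[:, :, 1]
        z_raw = np.cross(x_f, y_tib)
        nz = np.linalg.norm(z_raw, axis=1)
        if np.any(nz < 1e-9):
            raise GeometryError("degenerate foot frame (foot axis parallel to knee axis)")
        z_f = z_raw / nz[:, None]
        y_f = np.cross(z_f, x_f)
        R_foot = np.stack([x_f, y_f, z_f], axis=2)

        rotations[f"femur_{s}"] = R_femur
        rotations[f"tibia_{s}"] = R_tibia
        rotations[f"foot_{s}"] = R_foot
        origins[f"femur_{s}"] = kjc
        origins[f"tibia_{s}"] = ajc
        origins[f"foot_{s}"] = pos[f"{S}HEE"]
        jcs[f"hip_{s}"] = hjc
        jcs[f"knee_{s}"] = kjc
        jcs[f"ankle_{s}"] = ajc
        jcs[f"toe_{s}"] = pos[f"{S}TOE"]

    return SegmentFrames(rotations=rotations, origins=origins, joint_centres=jcs)


# ---------------------------------------------------------------------------
# Waveform extraction (shared by both engines)
# ---------------------------------------------------------------------------

def waveforms_from_frames(frames: SegmentFrames, pelvis_centre: np.ndarray,
                          trial: MarkerTrial, T: int = DEFAULT_T,
                          engine: str = "dk") -> list[GaitCycleWaveforms]:
    """Extract the nine per-cycle variables from segment frames.

    Used by the direct-kinematics engine (marker-built frames) and by the
    multibody engine (model frames from body kinematics): the variable
    definitions and Cardan sequences are identical, so any waveform
    difference between engines reflects the upstream frame estimates only.
    """
    out: list[GaitCycleWaveforms] = []
    n = trial.n_frames
    lab = np.broadcast_to(np.eye(3), (n, 3, 3))
    pelvis_angles = cardan_angles(lab, frames.rotations["pelvis"], "yxz", (1, 1, 1))

    for side, s in (("right", "r"), ("left", "l")):
        axsgn = 1 if side == "right" else -1
        hip = cardan_angles(frames.rotations["pelvis"], frames.rotations[f"femur_{s}"],
                            "yxz", (-1, axsgn, axsgn))
        knee = cardan_angles(frames.rotations[f"femur_{s}"], frames.rotations[f"tibia_{s}"],
                             "yxz", (1, axsgn, axsgn))
        ankle = cardan_angles(frames.rotations[f"tibia_{s}"], frames.rotations[f"foot_{s}"],
                              "yxz", (-1, axsgn, axsgn))
        tilt = pelvis_angles[:, 0]
        obliquity = -axsgn * pelvis_angles[:, 1]
        rotation = axsgn * pelvis_angles[:, 2]

        cycles = trial.cycles(side)
        if not cycles:
            warnings.warn(f"no complete {side} gait cycle in trial "
                          f"{trial.meta.get('trial_id', '?')}", stacklevel=2)
            continue
        for cid, (t0, t1) in enumerate(cycles):
            series = {
                "pelvic_tilt": tilt, "pelvic_obliquity": obliquity,
                "pelvic_rotation": rotation,
                "hip_flexion": hip[:, 0], "hip_abduction": hip[:, 1],
                "hip_rotation": hip[:, 2],
                "knee_flexion": knee[:, 0], "ankle_dorsiflexion": ankle[:, 0],
            }
            values = np.empty((9, T))
            for i, var in enumerate(VARIABLES):
                if var == "foot_progression":
                    values[i] = foot_progression_angle(
                        pelvis_centre, frames.joint_centres[f"ankle_{s}"],
                        frames.joint_centres[f"toe_{s}"], trial.time, t0, t1, T, side)
                else:
                    values[i] = time_normalise(series[var], trial.time, t0, t1, T)
            out.append(GaitCycleWaveforms(
                values=values, side=side, cycle_id=cid,
                meta=dict(trial.meta, engine=engine, cycle=(t0, t1))))
    return out


def extract_waveforms_dk(trial: MarkerTrial, frames: SegmentFrames,
                         T: int = DEFAULT_T) -> list[GaitCycleWaveforms]:
    """Per-cycle nine-variable waveforms from direct-kinematics frames."""
    return waveforms_from_frames(frames, frames.origins["pelvis"], trial, T, engine="dk")
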