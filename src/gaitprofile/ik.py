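"""Multibody-optimisation inverse kinematics (global optimisation engine).

Per frame, the free coordinates q of the constrained skeletal chain are fit
to the observed markers by weighted least squares,

    min_q  sum_m  w_m * || p_m^obs - FK_m(q) ||^2 ,

solved with a damped Gauss-Newton (Levenberg-style) iteration on analytic
marker Jacobians; the iteration stops when the coordinate update norm drops
below the tolerance or the iteration cap is reached (flagged).  Frames are
solved sequentially with warm starts from the previous frame's solution;
frame 1 cold-starts from the neutral pose.  Bounds are enforced by
projection.  No global search is attempted: the warm-start chain is the
documented tie-break between multiple minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SolvabilityError, ValidationError
from .metrics import DEFAULT_T, GaitCycleWaveforms
from .model import SkeletalModel, rotation_about
from .trial import MarkerTrial

#: Default marker weights: anatomical markers 1, wand markers 0.5 (the thigh
#: wand carries the largest soft-tissue artefact).
DEFAULT_WEIGHTS = {"THI": 0.5, "TIB": 0.5}


def _weight_for(label: str, table: dict[str, float]) -> float:
    if label in table:
        return table[label]
    for key, w in table.items():
        if label.endswith(key):
            return w
    return 1.0


@dataclass
class IKConfig:
    marker_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    tolerance: float = 1e-6
    max_iterations: int = 100
    warm_start: bool = True
    bounds_enforced: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if any(w < 0 for w in self.marker_weights.values()):
            raise ValidationError("marker weights must be non-negative")


@dataclass
class IKResult:
    q_trajectory: np.ndarray            # (n_frames, n_coordinates)
    coordinate_names: list[str]
    marker_labels: list[str]
    residuals: np.ndarray               # (n_frames, n_markers) distances, metres
    converged: np.ndarray               # (n_frames,) bool
    iterations: np.ndarray              # (n_frames,)

    @property
    def marker_rms(self) -> dict[str, float]:
        """Per-marker trial RMS tracking error (metres)."""
        rms = np.sqrt(np.mean(self.residuals ** 2, axis=0))
        return dict(zip(self.marker_labels, rms.tolist()))


# ---------------------------------------------------------------------------
# Forward kinematics with analytic Jacobian bookkeeping
# ---------------------------------------------------------------------------

class _Chain:
    """Precomputed chain structure for fast repeated FK/Jacobian evaluation."""

    def __init__(self, model: SkeletalModel, labels: list[str]):
        self.model = model
        self.labels = labels
        free = {c: i for i, c in enumerate(model.coordinate_names)}
        self.n_free = len(free)
        seg_index = {seg.name: k for k, seg in enumerate(model.segments)}
        self.parent_idx = [None if s.parent is None else seg_index[s.parent]
                           for s in model.segments]
        self.segments = model.segments
        # marker bookkeeping
        marker_seg = {}
        for k, seg in enumerate(model.segments):
            for lab in seg.local_markers:
                marker_seg[lab] = (k, seg.local_markers[lab])
        self.marker_seg_idx = np.array([marker_seg[lab][0] for lab in labels])
        self.marker_local = np.stack([marker_seg[lab][1] for lab in labels])
        # per segment: free-coordinate slots [(slot_in_joint, free_index)], dof types
        self.seg_free = []
        for seg in model.segments:
            self.seg_free.append([(i, free[c]) for i, c in enumerate(seg.coordinate_names)
                                  if c in free])
        # descendant mask: marker m depends on coordinate of segment k iff k
        # is an ancestor of the marker's segment
        n_seg = len(model.segments)
        anc = np.zeros((n_seg, n_seg), dtype=bool)
        for k in range(n_seg):
            s = k
            while s is not None:
                anc[k, s] = True
                s = self.parent_idx[s]
        # (n_free,) segment owning each free coordinate
        owner = np.empty(self.n_free, dtype=int)
        for k, slots in enumerate(self.seg_free):
            for _, j in slots:
                owner[j] = k
        self.dep = anc[self.marker_seg_idx][:, owner]       # (M, n_free)

    def fk_jac(self, q: np.ndarray):
        """Marker positions (M,3) and Jacobian (M,3,C) at q."""
        qmap = self.model.full_q(q)
        n_seg = len(self.segments)
        R_all = np.empty((n_seg, 3, 3))
        o_all = np.empty((n_seg, 3))
        C = self.n_free
        axes_w = np.empty((C, 3))          # world axis per free coordinate
        jorig_w = np.empty((C, 3))         # world joint origin per free coordinate
        is_trans = np.zeros(C, dtype=bool)
        for k, seg in enumerate(self.segments):
            p = self.parent_idx[k]
            if p is None:
                Rp, op = np.eye(3), np.zeros(3)
            else:
                Rp, op = R_all[p], o_all[p]
            origin = op + Rp @ seg.joint_origin_in_parent
            joint_origin = origin
            Rj = np.eye(3)
            free_slots = dict(self.seg_free[k])
            for i, (axis, dof, cname) in enumerate(zip(seg.joint_axes, seg.joint_dof_types,
                                                       seg.coordinate_names)):
                val = qmap[cname]
                if i in free_slots:
                    j = free_slots[i]
                    axes_w[j] = Rp @ (Rj @ axis) if dof == "rot" else Rp @ axis
                    jorig_w[j] = joint_origin
                    is_trans[j] = dof == "trans"
                if dof == "trans":
                    origin = origin + Rp @ (axis * val)
                    joint_origin = origin
                else:
                    Rj = Rj @ rotation_about(axis, val)
            R_all[k] = Rp @ Rj
            o_all[k] = origin
        P = o_all[self.marker_seg_idx] + np.einsum(
            "mij,mj->mi", R_all[self.marker_seg_idx], self.marker_local)
        # rotational columns: cross(axis_j, P_m - origin_j); translational: axis_j
        diff = P[:, None, :] - jorig_w[None, :, :]               # (M, C, 3)
        J = np.cross(np.broadcast_to(axes_w, diff.shape), diff)  # (M, C, 3)
        J[:, is_trans, :] = axes_w[is_trans]
        J *= self.dep[:, :, None]
        return P, np.swapaxes(J, 1, 2)


def _collinear(points: np.ndarray) -> bool:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s.size < 2 or s[1] < 1e-9


def solve_frame(model: SkeletalModel, observed: dict[str, np.ndarray],
                q0: np.ndarray, cfg: IKConfig | None = None,
                chain: _Chain | None = None, cost_history: list | None = None):
    """Weighted least-squares fit of one frame.

    Returns ``(q, residuals, converged, n_iterations)`` where residuals are
    per-marker distances in the order of the observed labels attached to the
    chain.  If ``cost_history`` is a list, the weighted objective value of
    every accepted iterate is appended to it (non-increasing by design).
    """
    cfg = cfg or IKConfig()
    if chain is None:
        labels = [m for m in model.marker_labels
                  if m in observed and _weight_for(m, cfg.marker_weights) > 0]
        chain = _Chain(model, labels)
    labels = chain.labels
    if len(labels) < 3:
        raise SolvabilityError(f"only {len(labels)} usable markers; frame under-determined")
    obs = np.stack([np.asarray(observed[m], float) for m in labels])
    if np.isnan(obs).any():
        bad = labels[int(np.flatnonzero(np.isnan(obs).any(axis=1))[0])]
        raise SolvabilityError(f"observed marker {bad} contains NaN")
    if _collinear(obs):
        raise SolvabilityError("observed markers are collinear; frame under-determined")
    w = np.array([_weight_for(m, cfg.marker_weights) for m in labels])
    sw = np.repeat(np.sqrt(w), 3)

    lo, hi = model.bounds_arrays()
    q = np.asarray(q0, float).copy()
    if q.shape != (model.n_coordinates,):
        raise ValidationError("q0 length does not match model coordinates")
    if cfg.bounds_enforced:
        q = np.clip(q, lo, hi)

    lam = 1e-6
    P, J = chain.fk_jac(q)
    r = ((obs - P).ravel()) * sw
    cost = float(r @ r)
    if cost_history is not None:
        cost_history.append(cost)
    n_iter = 0
    converged = False
    for n_iter in range(1, cfg.max_iterations + 1):
        Jw = J.reshape(-1, q.size) * sw[:, None]
        A = Jw.T @ Jw
        g = Jw.T @ r
        accepted = False
        for _ in range(25):
            try:
                delta = np.linalg.solve(A + lam * np.eye(q.size), g)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            q_new = q + delta
            if cfg.bounds_enforced:
                q_new = np.clip(q_new, lo, hi)
            P_new, J_new = chain.fk_jac(q_new)
            r_new = ((obs - P_new).ravel()) * sw
            cost_new = float(r_new @ r_new)
            if cost_new <= cost + 1e-15:
                accepted = True
                lam = max(lam / 3, 1e-10)
                step = float(np.linalg.norm(q_new - q))
                q, P, J, r, cost = q_new, P_new, J_new, r_new, cost_new
                if cost_history is not None:
                    cost_history.append(cost)
                break
            lam *= 10
        if not accepted:
            converged = True      # no descent direction left: at a local minimum
            break
        if step < cfg.tolerance:
            converged = True
            break

    residuals = np.linalg.norm(obs - P, axis=1)
    return q, residuals, converged, n_iter


def solve_trial(model: SkeletalModel, trial: MarkerTrial,
                cfg: IKConfig | None = None) -> IKResult:
    """Frame-sequential IK over a trial with warm starts.

    Any unsolvable frame raises :class:`SolvabilityError` naming the frame;
    frames are never silently skipped.
    """
    cfg = cfg or IKConfig()
    labels = [m for m in model.marker_labels
              if m in trial.markers and _weight_for(m, cfg.marker_weights) > 0]
    chain = _Chain(model, labels)
    n = trial.n_frames
    C = model.n_coordinates
    q_traj = np.empty((n, C))
    residuals = np.empty((n, len(labels)))
    converged = np.empty(n, dtype=bool)
    iterations = np.empty(n, dtype=int)

    neutral = np.zeros(C)
    q_prev = neutral
    for i in range(n):
        observed = {m: trial.markers[m][i] for m in labels}
        q0 = q_prev if (cfg.warm_start and i > 0) else neutral
        try:
            q, res, conv, it = solve_frame(model, observed, q0, cfg, chain)
        except SolvabilityError as exc:
            raise SolvabilityError(f"frame {i}: {exc}") from exc
        q_traj[i], residuals[i], converged[i], iterations[i] = q, res, conv, it
        q_prev = q
    return IKResult(q_trajectory=q_traj, coordinate_names=list(model.coordinate_names),
                    marker_labels=labels, residuals=residuals,
                    converged=converged, iterations=iterations)


def body_kinematics(model: SkeletalModel, q_trajectory: np.ndarray):
    """Segment frames and pelvis-origin trajectory for a solved trajectory.

    Returns ``(pelvis_centres (n,3), rotations {segment: (n,3,3)},
    origins {segment: (n,3)}, joint_centres {name: (n,3)})`` — the inputs
    the waveform extraction and the FPA construction need.
    """
    from .model import segment_frames

    q_trajectory = np.asarray(q_trajectory, float)
    if q_trajectory.ndim != 2 or q_trajectory.shape[1] != model.n_coordinates:
        raise ValidationError("q_trajectory must be (n_frames, n_coordinates)")
    n = q_trajectory.shape[0]
    names = [seg.name for seg in model.segments]
    rotations = {s: np.empty((n, 3, 3)) for s in names}
    origins = {s: np.empty((n, 3)) for s in names}
    for i in range(n):
        frames = segment_frames(model, q_trajectory[i])
        for s in names:
            rotations[s][i], origins[s][i] = frames[s]
    # joint centres and TOE positions from the stored frames
    jcs: dict[str, np.ndarray] = {"pelvis_origin": origins["pelvis"]}
    jc_name = {"femur": "hip", "tibia": "knee", "talus": "ankle", "calcn": "subtalar"}
    for seg in model.segments:
        if seg.parent is None:
            continue
        base, s = seg.name.rsplit("_", 1)
        Rp, op = rotations[seg.parent], origins[seg.parent]
        jcs[f"{jc_name[base]}_{s}"] = op + np.einsum(
            "nij,j->ni", Rp, seg.joint_origin_in_parent)
        if base == "calcn":
            toe_local = seg.local_markers[f"{s.upper()}TOE"]
            jcs[f"toe_{s}"] = origins[seg.name] + np.einsum(
                "nij,j->ni", rotations[seg.name], toe_local)
    return jcs["pelvis_origin"], rotations, origins, jcs


def extract_waveforms_ik(model: SkeletalModel, trial: MarkerTrial, result: IKResult,
                         T: int = DEFAULT_T) -> list[GaitCycleWaveforms]:
    """Per-cycle nine-variable waveforms from the solved model kinematics.

    Uses the same variable definitions and Cardan sequences as the direct
    engine; the foot frame is the model's calcaneus segment.
    """
    from .directkin import SegmentFrames, waveforms_from_frames

    pelvis, rotations, origins, jcs = body_kinematics(model, result.q_trajectory)
    frames = SegmentFrames(
        rotations={"pelvis": rotations["pelvis"],
                   "femur_r": rotations["femur_r"], "femur_l": rotations["femur_l"],
                   "tibia_r": rotations["tibia_r"], "tibia_l": rotations["tibia_l"],
                   "foot_r": rotations["calcn_r"], "foot_l": rotations["calcn_l"]},
        origins={"pelvis": origins["pelvis"],
                 "femur_r": origins["femur_r"], "femur_l": origins["femur_l"],
                 "tibia_r": origins["tibia_r"], "tibia_l": origins["tibia_l"],
                 "foot_r": origins["calcn_r"], "foot_l": origins["calcn_l"]},
        joint_centres={"hip_r": jcs["hip_r"], "hip_l": jcs["hip_l"],
                       "knee_r": jcs["knee_r"], "knee_l": jcs["knee_l"],
                       "ankle_r": jcs["ankle_r"], "ankle_l": jcs["ankle_l"],
                       "toe_r": jcs["toe_r"], "toe_l": jcs["toe_l"]})
    return waveforms_from_frames(frames, pelvis, trial, T, engine="ik")
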