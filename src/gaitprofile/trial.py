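"""Marker-trajectory trial container.

A :class:`MarkerTrial` is the raw observation unit: uniformly sampled,
labelled 3-D marker trajectories (metres, laboratory frame: X progression,
Y left, Z up) plus per-side gait events (heel-strike / toe-off times in
seconds) and free-form metadata (subject, session, trial id, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class MarkerTrial:
    time: np.ndarray                       # (n,) seconds, uniform
    markers: dict[str, np.ndarray]         # label -> (n, 3) metres
    events: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValidationError("trial needs at least two samples")
        dt = np.diff(self.time)
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
            raise ValidationError("trial sampling is not uniform")
        self.markers = {k: np.asarray(v, float) for k, v in self.markers.items()}
        n = self.time.size
        for label, arr in self.markers.items():
            if arr.shape != (n, 3):
                raise ValidationError(
                    f"marker {label}: shape {arr.shape} != ({n}, 3)")
        for side, evs in self.events.items():
            for kind, times in evs.items():
                t = np.asarray(times, float)
                if t.size > 1 and not (np.diff(t) > 0).all():
                    raise ValidationError(
                        f"{side} {kind} event times are not strictly increasing")

    @property
    def rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    @property
    def n_frames(self) -> int:
        return int(self.time.size)

    def heel_strikes(self, side: str) -> np.ndarray:
        try:
            return np.asarray(self.events[side]["hs"], float)
        except KeyError as exc:
            raise ValidationError(f"trial has no heel-strike events for side {side!r}") from exc

    def cycles(self, side: str) -> list[tuple[float, float]]:
        """Consecutive heel-strike pairs delimiting complete gait cycles."""
        hs = self.heel_strikes(side)
        return [(float(hs[i]), float(hs[i + 1])) for i in range(hs.size - 1)]
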