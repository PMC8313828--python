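"""Event schedules for stimulus-locked calcium recordings.

A recording is a fixed-rate frame sequence (default 4 s per frame) with a
drug-free baseline, three stimulus events, and a terminal ionophore
positive control.  The schedule partitions the recording into half-open,
non-overlapping frame windows::

    baseline [0, b) | event 1 [e1, e2) | event 2 [e2, e3)
                    | event 3 [e3, c)  | control [c, n_frames)

so every frame belongs to exactly one window and a stimulus frame belongs
to the window of its own stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["EventSchedule", "paper_default_schedule"]


@dataclass(frozen=True)
class EventSchedule:
    """Frame timing of one calcium-imaging experiment.

    Parameters
    ----------
    n_frames : int
        Total frames recorded.
    baseline_frames : int
        Length ``b`` of the untreated baseline window ``[0, b)``.
    event_frames : tuple of int
        The three stimulus frames, strictly increasing, first one >= ``b``.
    control_frame : int
        Frame at which the positive control (ionomycin) is added; must lie
        after the last stimulus and before the end of the recording.
    frame_period : float
        Seconds per frame.
    event_labels : tuple of str
        Human-readable stimulus names, one per event.
    """

    n_frames: int
    baseline_frames: int = 50
    event_frames: tuple[int, int, int] = (50, 100, 150)
    control_frame: int = 200
    frame_period: float = 4.0
    event_labels: tuple[str, ...] = ("event1", "event2", "event3")

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError(f"n_frames must be positive, got {self.n_frames}")
        if self.frame_period <= 0:
            raise ValueError(f"frame_period must be positive, got {self.frame_period}")
        ev = tuple(int(f) for f in self.event_frames)
        if len(ev) != 3:
            raise ValueError(f"expected exactly 3 stimulus events, got {len(ev)}")
        object.__setattr__(self, "event_frames", ev)
        if not 0 < self.baseline_frames <= ev[0]:
            raise ValueError(
                f"baseline_frames must satisfy 0 < b <= first event "
                f"({ev[0]}), got {self.baseline_frames}"
            )
        if not ev[0] < ev[1] < ev[2]:
            raise ValueError(f"event frames must be strictly increasing, got {ev}")
        if not ev[2] < self.control_frame < self.n_frames:
            raise ValueError(
                f"control_frame must lie after the last event ({ev[2]}) and "
                f"before n_frames ({self.n_frames}), got {self.control_frame}"
            )
        if len(self.event_labels) != 3:
            raise ValueError("event_labels must name exactly 3 events")

    # -- windows ---------------------------------------------------------

    @property
    def baseline_window(self) -> tuple[int, int]:
        return (0, self.baseline_frames)

    @property
    def event_windows(self) -> tuple[tuple[int, int], ...]:
        """Half-open response windows, one per stimulus event."""
        e1, e2, e3 = self.event_frames
        return ((e1, e2), (e2, e3), (e3, self.control_frame))

    @property
    def control_window(self) -> tuple[int, int]:
        return (self.control_frame, self.n_frames)

    # -- time ------------------------------------------------------------

    def frame_to_time(self, frame: int) -> float:
        """Seconds since recording start of a frame index."""
        if not 0 <= frame < self.n_frames:
            raise ValueError(f"frame {frame} out of range [0, {self.n_frames})")
        return frame * self.frame_period

    @property
    def total_seconds(self) -> float:
        return self.n_frames * self.frame_period

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "baseline_frames": self.baseline_frames,
            "event_frames": list(self.event_frames),
            "control_frame": self.control_frame,
            "frame_period": self.frame_period,
            "event_labels": list(self.event_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventSchedule":
        known = {k: d[k] for k in (
            "n_frames", "baseline_frames", "event_frames",
            "control_frame", "frame_period", "event_labels",
        ) if k in d}
        if "event_frames" in known:
            known["event_frames"] = tuple(known["event_frames"])
        if "event_labels" in known:
            known["event_labels"] = tuple(known["event_labels"])
        return cls(**known)

    def with_labels(self, *labels: str) -> "EventSchedule":
        return replace(self, event_labels=tuple(labels))


def paper_default_schedule(n_frames: int = 215) -> EventSchedule:
    """The standard protocol: 4 s frames, 50-frame baseline, stimuli at
    frames 50/100/150, ionomycin at frame 200.

    Total recording length is a free parameter of the acquisition (the
    protocol fixes only the event positions); the 215-frame default gives
    860 s ~ 14 min.
    """
    return EventSchedule(n_frames=n_frames)
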