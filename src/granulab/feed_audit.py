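"""Feeder / pump delivery auditing.

Continuous granulation needs the powder feeder and liquid pump to track
their set points.  Given a log of cumulative delivered mass against time
and the nominal rate, this module computes the signed mass error, splits
it into maximal excursion episodes (excess ``+`` / shortfall ``-``), and
summarizes the worst duration and the worst normalized error.

Normalization: an episode's peak absolute mass error is expressed as a
percentage of the set-point mass due over that episode
(``100 * peak / (set_rate * duration / 60)``), which makes feeders
running at different rates directly comparable.  An alternative
normalization by total delivered mass is available via ``mode``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeedLog",
    "DeviationEpisode",
    "deviation_series",
    "segment_episodes",
    "normalize_episode_error",
    "audit_summary",
]


@dataclass
class FeedLog:
    """Cumulative delivered mass over time at a nominal set rate.

    ``t`` in seconds (strictly increasing), ``actual_mass`` cumulative
    delivered grams, ``set_rate`` in g/min.  Loss-in-weight recordings
    (mass remaining in the hopper) can be converted with
    :meth:`from_loss_in_weight`.
    """

    t: np.ndarray
    actual_mass: np.ndarray
    set_rate: float

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.actual_mass = np.asarray(self.actual_mass, dtype=float)
        if self.t.shape != self.actual_mass.shape or self.t.size == 0:
            raise ValueError("t and actual_mass must be equal-length, non-empty")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.set_rate <= 0:
            raise ValueError("set_rate must be positive")

    @classmethod
    def from_loss_in_weight(cls, t, hopper_mass, set_rate) -> "FeedLog":
        hopper = np.asarray(hopper_mass, dtype=float)
        return cls(t, hopper[0] - hopper, set_rate)

    @classmethod
    def from_csv(cls, path, set_rate, time_col="time_s", mass_col="mass_g") -> "FeedLog":
        df = pd.read_csv(path)
        return cls(df[time_col].to_numpy(), df[mass_col].to_numpy(), set_rate)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.t, "mass_g": self.actual_mass}).to_csv(
            path, index=False)


@dataclass
class DeviationEpisode:
    """One signed excursion of actual vs set delivered mass."""

    sign: int  # +1 excess, -1 shortfall
    t_start: float
    t_end: float
    peak_abs_error: float

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("episode duration must be positive")
        if self.peak_abs_error < 0:
            raise ValueError("peak_abs_error must be non-negative")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def deviation_series(log: FeedLog) -> np.ndarray:
    """Signed mass error err(t_i) = actual(t_i) - set_rate * (t_i - t_0) / 60."""
    return log.actual_mass - log.set_rate * (log.t - log.t[0]) / 60.0


def segment_episodes(t, err, dead_band: float = 0.0) -> list[DeviationEpisode]:
    """Split a mass-error series into maximal signed excursion episodes.

    An episode is a maximal run of consecutive samples with
    ``err > +dead_band`` (positive) or ``err < -dead_band`` (negative).
    Episode end times extend to the next sample outside the run (or one
    median sampling interval past the last sample), so a rectangular
    excursion's duration is recovered to within one sampling interval.
    """
    t = np.asarray(t, dtype=float)
    err = np.asarray(err, dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    if dead_band < 0:
        raise ValueError("dead_band must be >= 0")
    state = np.zeros(t.size, dtype=int)
    state[err > dead_band] = 1
    state[err < -dead_band] = -1
    step = float(np.median(np.diff(t))) if t.size > 1 else 1.0

    episodes: list[DeviationEpisode] = []
    i = 0
    n = t.size
    while i < n:
        s = state[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j < n and state[j] == s:
            j += 1
        t_end = t[j] if j < n else t[n - 1] + step
        episodes.append(
            DeviationEpisode(
                sign=int(s),
                t_start=float(t[i]),
                t_end=float(t_end),
                peak_abs_error=float(np.max(np.abs(err[i:j]))),
            )
        )
        i = j
    return episodes


def normalize_episode_error(ep: DeviationEpisode, set_rate: float,
                            mode: str = "episode_due",
                            total_mass: float | None = None) -> float:
    """Episode peak mass error as a percentage.

    ``episode_due`` (default): relative to the set-point mass due during
    the episode, ``set_rate * duration / 60``.  ``total_delivered``:
    relative to ``total_mass`` (grams, required).
    """
    if set_rate <= 0:
        raise ValueError("set_rate must be positive")
    if ep.duration <= 0:
        raise ValueError("episode duration must be positive")
    if mode == "episode_due":
        due = set_rate * ep.duration / 60.0
    elif mode == "total_delivered":
        if total_mass is None or total_mass <= 0:
            raise ValueError("total_delivered mode needs a positive total_mass")
        due = total_mass
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 100.0 * ep.peak_abs_error / due


def audit_summary(episodes, set_rate: float | None = None,
                  max_duration_limit: float | None = None,
                  max_error_limit: float | None = None) -> dict:
    """Worst-case duration (s) and normalized error (%) over all episodes.

    With limits given, flags whether either maximum exceeds its limit.
    Empty episode lists yield zeros.
    """
    episodes = list(episodes)
    if not episodes:
        out = {"max_duration": 0.0, "max_normalized_error": 0.0, "n_episodes": 0}
    else:
        durations = [ep.duration for ep in episodes]
        if set_rate is not None:
            errors = [normalize_episode_error(ep, set_rate) for ep in episodes]
        else:
            errors = [0.0]
        out = {
            "max_duration": float(max(durations)),
            "max_normalized_error": float(max(errors)),
            "n_episodes": len(episodes),
        }
    if max_duration_limit is not None:
        out["duration_exceeded"] = out["max_duration"] > max_duration_limit
    if max_error_limit is not None:
        out["error_exceeded"] = out["max_normalized_error"] > max_error_limit
    return out
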