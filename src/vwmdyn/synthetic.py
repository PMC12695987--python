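"""Synthetic cohorts for the copying task and the rigid report task.

Two generators, one underlying memory process:

* :func:`generate_copy_task_logs` emulates self-paced copying-task
  behavior: alternating viewing and building sessions, per-item view
  intervals, and placement decisions gated by the certainty/threshold
  process of :mod:`vwmdyn.mom` evaluated at each item's realized
  cumulative viewing time and delay.

* :func:`generate_rigid_task_data` emulates a temporally rigid
  continuous color-report experiment: angular report errors drawn from
  a von Mises distribution whose concentration is a multiplicatively
  separable function of presentation time and delay — the "no inherent
  interaction" ground truth.

Both are deterministic given their seed: per-participant substreams are
spawned from one root SeedSequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .measures import Event, TrialLog
from .mom import (
    MomParams,
    certainty_after_delay,
    certainty_after_viewing,
    forced_report_quality,
    free_report_outcome,
)


def _certainty_now(viewing_time: float, delay: float, p: "MomParams") -> float:
    return certainty_after_delay(
        certainty_after_viewing(viewing_time, p), max(delay, 0.0), p
    )

__all__ = [
    "TimingParams",
    "CohortConfig",
    "RigidConfig",
    "ConfigurationError",
    "generate_copy_task_logs",
    "generate_rigid_task_data",
]


class ConfigurationError(ValueError):
    """A generator configuration field is invalid."""


_VIEW_FAMILIES = ("lognormal", "constant", "exponential")


@dataclass(frozen=True)
class TimingParams:
    """Timing plumbing of the copying-task generator.

    The real task is self-paced, so these are generative conveniences,
    not empirical claims.  ``view_duration_family`` /
    ``view_duration_params`` specify the distribution of single-view
    durations (default: log-normal with median about 0.5 s, matching
    the sub-second views typical of the task).  ``session_policy``
    bounds how many items are inspected per viewing session; the
    default 1-4 makes multi-item sessions common.  ``reinspect_prob``
    is the per-slot probability of re-viewing an already-seen, not yet
    placed item, which exercises the cumulative-viewing-time and
    number-of-views covariates.
    """

    view_duration_family: str = "lognormal"
    view_duration_params: tuple = (math.log(0.5), 0.6)  # (mu, sigma) of log
    inter_view_gap: float = 0.3
    placement_interval: float = 1.5
    session_policy: tuple = (1, 4)  # (min_items, max_items) per viewing session
    reinspect_prob: float = 0.15

    def __post_init__(self) -> None:
        if self.view_duration_family not in _VIEW_FAMILIES:
            raise ConfigurationError(
                f"view_duration_family must be one of {_VIEW_FAMILIES}, "
                f"got {self.view_duration_family!r}"
            )
        if self.inter_view_gap < 0:
            raise ConfigurationError("inter_view_gap must be >= 0")
        if self.placement_interval < 0:
            raise ConfigurationError("placement_interval must be >= 0")
        lo, hi = self.session_policy
        if not (1 <= lo <= hi):
            raise ConfigurationError("session_policy must satisfy 1 <= min <= max")
        if not (0.0 <= self.reinspect_prob <= 1.0):
            raise ConfigurationError("reinspect_prob must be in [0, 1]")

    def draw_view_duration(self, rng: np.random.Generator) -> float:
        fam, par = self.view_duration_family, self.view_duration_params
        if fam == "lognormal":
            return float(rng.lognormal(par[0], par[1]))
        if fam == "exponential":
            return float(rng.exponential(par[0]))
        return float(par[0])  # constant


@dataclass(frozen=True)
class CohortConfig:
    """A simulated copying-task cohort.

    Defaults mirror the task geometry of the behavioral study
    conditions: 8 items per trial drawn from a 16-cell (4 x 4) grid.
    ``participant_sd`` is the log-scale SD of per-participant
    multiplicative factors on the encoding and decay timescales,
    introducing realistic between-participant heterogeneity.
    ``max_viewing_sessions`` caps runaway trials whose remaining items
    never clear the action threshold.
    """

    n_participants: int = 30
    n_trials_per_participant: int = 20
    n_items_per_trial: int = 8
    grid_size: int = 16
    mom: MomParams = field(default_factory=MomParams)
    timing: TimingParams = field(default_factory=TimingParams)
    seed: int = 0
    participant_sd: float = 0.2
    max_viewing_sessions: int = 12

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_trials_per_participant", "n_items_per_trial", "grid_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_items_per_trial > self.grid_size:
            raise ConfigurationError("n_items_per_trial cannot exceed grid_size")
        if self.participant_sd < 0:
            raise ConfigurationError("participant_sd must be >= 0")
        if self.max_viewing_sessions < 1:
            raise ConfigurationError("max_viewing_sessions must be >= 1")

    def with_(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


def _participant_params(base: MomParams, sd: float, rng: np.random.Generator) -> MomParams:
    if sd == 0:
        return base
    return base.with_(
        encoding_timescale=base.encoding_timescale * float(rng.lognormal(0.0, sd)),
        decay_timescale=base.decay_timescale * float(rng.lognormal(0.0, sd)),
    )


def _simulate_trial(
    participant_id: str,
    trial_index: int,
    cfg: CohortConfig,
    p: MomParams,
    rng: np.random.Generator,
) -> TrialLog:
    timing = cfg.timing
    cells = rng.choice(cfg.grid_size, size=cfg.n_items_per_trial, replace=False)
    items = [f"cell{c:02d}" for c in cells]
    unviewed = list(items)
    view_time: dict = {it: 0.0 for it in items}
    last_view_end: dict = {}
    n_views: dict = {it: 0 for it in items}
    placed: set = set()

    # session records: {"kind", "start", "end", "events": [(kind, item, t)]}
    sessions: list = []
    t = float(timing.inter_view_gap)
    open_view: Optional[dict] = None  # the viewing session being filled

    for _ in range(cfg.max_viewing_sessions):
        # --- viewing (or continue the still-open viewing session) ---
        lo, hi = timing.session_policy
        n_slots = int(rng.integers(lo, hi + 1))
        for _slot in range(n_slots):
            revisitable = [it for it in items if n_views[it] > 0 and it not in placed]
            if unviewed and (not revisitable or rng.random() >= timing.reinspect_prob):
                item = unviewed.pop(0)
            elif revisitable:
                item = revisitable[int(rng.integers(len(revisitable)))]
            else:
                break
            if open_view is not None:
                t += timing.inter_view_gap
            start = t
            dur = max(timing.draw_view_duration(rng), 1e-3)
            end = start + dur
            if open_view is None:
                open_view = {"kind": "viewing", "start": start, "end": end, "events": []}
            open_view["events"] += [("view_start", item, start), ("view_end", item, end)]
            open_view["end"] = end
            view_time[item] += dur
            last_view_end[item] = end
            n_views[item] += 1
            t = end
        if open_view is None:
            break
        # --- attempt placements; a building session is recorded only
        #     when at least one attempt succeeds (failed excursions
        #     leave no trace in the correct-placements-only alphabet,
        #     so the viewing session simply continues) ---
        # every viewed-and-unplaced item gets a placement decision, in
        # order of current certainty (the observer acts on the highest
        # peak first); sub-threshold or unlucky attempts leave no event
        build_start = open_view["end"]
        candidates = sorted(
            (it for it in items if n_views[it] > 0 and it not in placed),
            key=lambda it: -_certainty_now(view_time[it], build_start - last_view_end[it], p),
        )
        slot_t = build_start
        successes: list = []
        for item in candidates:
            slot_t += timing.placement_interval
            delay = slot_t - last_view_end[item]
            if free_report_outcome(view_time[item], delay, p, rng):
                successes.append((item, slot_t))
        if successes:
            sessions.append(open_view)
            open_view = None
            build = {
                "kind": "building",
                "start": build_start,
                "end": successes[-1][1],
                "events": [("place", it, pt) for it, pt in successes],
            }
            sessions.append(build)
            placed.update(it for it, _ in successes)
            t = slot_t + timing.inter_view_gap
        if len(placed) == len(items) and not unviewed:
            break

    if open_view is not None:
        # trailing viewing activity with no subsequent building session
        sessions.append(open_view)

    # tile: a building session extends to the next viewing session's start
    for a, b in zip(sessions, sessions[1:]):
        if a["kind"] == "building":
            a["end"] = b["start"]

    events: list = []
    for s in sessions:
        events.append(Event("session_start", s["kind"], s["start"]))
        events.extend(Event(k, it, et) for k, it, et in s["events"])
        events.append(Event("session_end", s["kind"], s["end"]))
    events.sort(key=lambda e: (e.time_s, _EVENT_ORDER[e.kind]))
    return TrialLog(participant_id=participant_id, trial_index=trial_index, events=events)


# stable tie-break at shared timestamps: a view/placement closes before
# its session ends, a session ends before the next one starts, and a
# view starts after its session opens
_EVENT_ORDER = {
    "view_end": 0,
    "place": 1,
    "session_end": 2,
    "session_start": 3,
    "view_start": 4,
}


def generate_copy_task_logs(config: CohortConfig) -> list:
    """Simulate event logs for a whole copying-task cohort.

    Each trial alternates viewing and building sessions; every
    placement refers to a previously viewed item and is drawn from the
    free-report certainty/threshold process at the item's realized
    cumulative viewing time and delay.  Identical config (including
    seed) yields identical logs.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_participants)
    logs = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"p{i + 1:03d}"
        p = _participant_params(config.mom, config.participant_sd, rng)
        for trial in range(1, config.n_trials_per_participant + 1):
            logs.append(_simulate_trial(pid, trial, config, p, rng))
    return logs


# ---------------------------------------------------------------------------
# Rigid continuous-report task
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidConfig:
    """A simulated rigid continuous-report experiment.

    Defaults mirror the within-participant design of the reference
    rigid experiment: presentation times 0.1 / 1.1 / 2.1 s crossed with
    delays 2 / 4 / 6 s, 33 trials per cell, set size (1 or 3)
    manipulated between participants.  Report-error concentration is
    kappa = scale * f(presentation) * g(delay) / set_size — log-additive
    in all three factors, with no built-in interaction.
    ``participant_scale_sd`` is the log-scale SD of a per-participant
    multiplicative factor on the concentration scale.
    """

    presentation_times: tuple = (0.1, 1.1, 2.1)
    delays: tuple = (2.0, 4.0, 6.0)
    set_sizes: tuple = (1, 3)
    trials_per_cell: int = 33
    n_participants: int = 60
    mom: MomParams = field(default_factory=MomParams)
    seed: int = 0
    participant_scale_sd: float = 0.4

    def __post_init__(self) -> None:
        if not self.presentation_times or not self.delays or not self.set_sizes:
            raise ConfigurationError("condition lists must be nonempty")
        if any(t <= 0 for t in self.presentation_times):
            raise ConfigurationError("presentation times must be > 0")
        if any(d < 0 for d in self.delays):
            raise ConfigurationError("delays must be >= 0")
        if any(s < 1 for s in self.set_sizes):
            raise ConfigurationError("set sizes must be >= 1")
        if self.trials_per_cell < 1:
            raise ConfigurationError("trials_per_cell must be >= 1")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.participant_scale_sd < 0:
            raise ConfigurationError("participant_scale_sd must be >= 0")

    def with_(self, **kwargs) -> "RigidConfig":
        return replace(self, **kwargs)


def _wrap_deg(err_rad: np.ndarray) -> np.ndarray:
    """Radians -> degrees in (-180, 180]."""
    deg = np.degrees(err_rad)
    deg = np.mod(deg + 180.0, 360.0) - 180.0
    deg[deg == -180.0] = 180.0
    return deg


def generate_rigid_task_data(config: RigidConfig) -> pd.DataFrame:
    """Simulate continuous-report records for a rigid-task experiment.

    Returns one row per trial with columns participant_id, trial,
    set_size, presentation_s, delay_s, error_deg.  Errors are von Mises
    with concentration separable in presentation time, delay, and set
    size; errors lie in (-180, 180].
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_participants)
    set_sizes = [config.set_sizes[i % len(config.set_sizes)] for i in range(config.n_participants)]
    frames = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"p{i + 1:03d}"
        scale_factor = (
            float(rng.lognormal(0.0, config.participant_scale_sd))
            if config.participant_scale_sd > 0
            else 1.0
        )
        p = config.mom.with_(
            concentration_scale=config.mom.concentration_scale * scale_factor
        )
        set_size = set_sizes[i]
        cells = [
            (v, d)
            for v in config.presentation_times
            for d in config.delays
            for _ in range(config.trials_per_cell)
        ]
        order = rng.permutation(len(cells))
        rows = []
        for trial, idx in enumerate(order, start=1):
            v, d = cells[idx]
            kappa = forced_report_quality(v, d, p) / set_size
            if kappa > 0:
                err = rng.vonmises(0.0, kappa)
            else:
                err = rng.uniform(-np.pi, np.pi)
            rows.append((pid, trial, set_size, v, d, err))
        df = pd.DataFrame(
            rows,
            columns=["participant_id", "trial", "set_size", "presentation_s", "delay_s", "error_rad"],
        )
        df["error_deg"] = _wrap_deg(df.pop("error_rad").to_numpy())
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
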