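"""File formats and run configuration.

Event logs are line-delimited TSV, one event per line::

    participant	trial	kind	item	time_s

where ``kind`` is one of view_start / view_end / place /
session_start / session_end.  For session markers the ``item`` column
carries the session kind (``viewing`` or ``building``).  Timestamps are
seconds from trial start with 3 decimal places, which is lossless for
cursor streams sampled at typical monitor rates.

Measured-item tables and report-record tables are plain TSV with a
header.  Run configuration round-trips through YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
import yaml

from .measures import EVENT_KINDS, Event, MalformedLogError, TrialLog, segment_sessions
from .mom import MomParams
from .synthetic import CohortConfig, RigidConfig, TimingParams

__all__ = [
    "LogParseError",
    "write_event_log",
    "read_event_log",
    "write_measured_items",
    "read_measured_items",
    "write_report_records",
    "read_report_records",
    "RunConfig",
    "load_run_config",
    "config_hash",
]

_EVENT_HEADER = ["participant", "trial", "kind", "item", "time_s"]


class LogParseError(ValueError):
    """An event-log file violates the schema; message lists offenses."""


def write_event_log(logs: Iterable[TrialLog], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_EVENT_HEADER) + "\n")
        for log in logs:
            for e in log.events:
                fh.write(
                    f"{log.participant_id}\t{log.trial_index}\t{e.kind}\t"
                    f"{e.item_id}\t{e.time_s:.3f}\n"
                )


def read_event_log(path, validate: bool = True) -> list:
    """Parse an event-log file into TrialLogs, strictly validated.

    Validation covers the line schema, time ordering, view nesting, and
    session alternation; the error message reports up to the first 10
    offending lines with their line numbers.
    """
    path = Path(path)
    offenses: list = []
    records: dict = {}
    order: list = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _EVENT_HEADER:
            raise LogParseError(
                f"{path}: bad header {header!r}, expected {_EVENT_HEADER!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                offenses.append(f"line {lineno}: expected 5 fields, got {len(parts)}")
                continue
            pid, trial_s, kind, item, time_s = parts
            if kind not in EVENT_KINDS:
                offenses.append(f"line {lineno}: unknown event kind {kind!r}")
                continue
            try:
                trial = int(trial_s)
                time = float(time_s)
            except ValueError:
                offenses.append(f"line {lineno}: non-numeric trial or time")
                continue
            key = (pid, trial)
            if key not in records:
                records[key] = []
                order.append(key)
            try:
                records[key].append((lineno, Event(kind, item, time)))
            except ValueError as exc:
                offenses.append(f"line {lineno}: {exc}")
            if len(offenses) >= 10:
                break
    if offenses:
        raise LogParseError(f"{path}: malformed log:\n  " + "\n  ".join(offenses[:10]))

    logs = []
    for pid, trial in order:
        tagged = records[(pid, trial)]
        for (ln_a, a), (ln_b, b) in zip(tagged, tagged[1:]):
            if b.time_s < a.time_s:
                offenses.append(
                    f"line {ln_b}: time {b.time_s} precedes t={a.time_s} (line {ln_a})"
                )
        if offenses:
            continue
        log = TrialLog(pid, trial, [e for _, e in tagged])
        if validate:
            try:
                segment_sessions(log)
            except MalformedLogError as exc:
                first_line = tagged[0][0]
                offenses.append(f"trial starting line {first_line}: {exc}")
                continue
        logs.append(log)
    if offenses:
        raise LogParseError(f"{path}: malformed log:\n  " + "\n  ".join(offenses[:10]))
    return logs


def write_measured_items(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_measured_items(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["placed"] = df["placed"].astype(bool)
    return df


def write_report_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_report_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full simulate -> measure -> fit -> dissociate run.

    One seed governs everything; component seeds are derived from it so
    a fixed RunConfig reproduces byte-identical outputs.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    rigid: RigidConfig = field(default_factory=RigidConfig)
    mom: MomParams = field(default_factory=MomParams)
    output_dir: str = "vwmdyn_demo"
    seed: int = 1
    log_level: str = "INFO"
    dissociation_n_per_cell: int = 500
    n_boot: int = 200

    def resolved(self) -> "RunConfig":
        """Propagate the global seed and shared model params downward."""
        cohort = self.cohort.with_(mom=self.mom, seed=self.seed)
        rigid = self.rigid.with_(mom=self.mom, seed=self.seed + 1)
        return RunConfig(
            cohort=cohort,
            rigid=rigid,
            mom=self.mom,
            output_dir=self.output_dir,
            seed=self.seed,
            log_level=self.log_level,
            dissociation_n_per_cell=self.dissociation_n_per_cell,
            n_boot=self.n_boot,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _build(cls, data: Optional[dict], **overrides):
    data = dict(data or {})
    data.update(overrides)
    return cls(**data)


def load_run_config(path=None, seed: Optional[int] = None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file plus keyword overrides.

    The YAML may contain ``mom``, ``timing``, ``cohort``, ``rigid`` and
    top-level run settings; omitted fields fall back to defaults.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    mom = _build(MomParams, raw.get("mom"))
    timing_raw = raw.get("timing")
    cohort_raw = dict(raw.get("cohort") or {})
    for key in ("session_policy",):
        if key in cohort_raw and isinstance(cohort_raw[key], list):
            cohort_raw[key] = tuple(cohort_raw[key])
    if timing_raw:
        timing_raw = dict(timing_raw)
        for key in ("session_policy", "view_duration_params"):
            if key in timing_raw and isinstance(timing_raw[key], list):
                timing_raw[key] = tuple(timing_raw[key])
        timing = _build(TimingParams, timing_raw)
    else:
        timing = TimingParams()
    cohort = _build(CohortConfig, cohort_raw, mom=mom, timing=timing)
    rigid_raw = dict(raw.get("rigid") or {})
    for key in ("presentation_times", "delays", "set_sizes"):
        if key in rigid_raw and isinstance(rigid_raw[key], list):
            rigid_raw[key] = tuple(rigid_raw[key])
    rigid = _build(RigidConfig, rigid_raw, mom=mom)
    run_raw = {
        k: raw[k]
        for k in ("output_dir", "seed", "log_level", "dissociation_n_per_cell", "n_boot")
        if k in raw
    }
    run_raw.update(overrides)
    if seed is not None:
        run_raw["seed"] = seed
    return RunConfig(cohort=cohort, rigid=rigid, mom=mom, **run_raw)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the scientific configuration.

    The output directory and log level are excluded: two runs that
    differ only in where they write are the same experiment.
    """
    payload = config.to_dict()
    payload.pop("output_dir", None)
    payload.pop("log_level", None)
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
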