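"""Observer-session evaluation metrics.

Five metrics summarize observer performance: recognition time, recognition
accuracy and confidence (1-5) for object recognition; grasping attempt time
and grasping accuracy for localization. A grasp scores 100% only when the
object was correctly grasped; coming within the 10-cm margin without a
correct grasp scores 0% but still counts as a timed attempt. Trials without
a successful outcome are censored at the protocol's maximum duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "SessionRecord",
    "ProtocolConfig",
    "SessionParseError",
    "recognition_metrics",
    "grasping_metrics",
    "read_session_csv",
    "write_session_csv",
    "metrics_report",
]

#: per-trial maximum durations (seconds) of the three experimental setups
SETUP_DURATIONS = {"single": 120.0, "multi": 240.0, "navigation": 180.0}

CSV_COLUMNS = [
    "object_label",
    "reported_label",
    "recognition_time_s",
    "confidence",
    "grasp_time_s",
    "grasped_correctly",
    "final_distance_cm",
]


class SessionParseError(ValueError):
    """Malformed session log (bad column set or row value)."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Trial protocol: per-trial time budget and the grasp distance margin."""

    max_duration: float = SETUP_DURATIONS["single"]
    grasp_margin: float = 10.0

    def __post_init__(self) -> None:
        if self.max_duration <= 0:
            raise ValueError("max_duration must be positive")
        if self.grasp_margin < 0:
            raise ValueError("grasp_margin must be non-negative")


@dataclass(frozen=True)
class SessionRecord:
    """One observer-object trial."""

    object_label: str
    reported_label: str | None
    recognition_time: float
    confidence: int
    grasp_time: float | None = None
    grasped_correctly: bool = False
    final_distance: float | None = None

    def __post_init__(self) -> None:
        if self.confidence not in (1, 2, 3, 4, 5):
            raise ValueError("confidence must be an integer in 1..5")
        if self.recognition_time < 0:
            raise ValueError("recognition_time must be non-negative")
        if self.grasp_time is not None and self.grasp_time < 0:
            raise ValueError("grasp_time must be non-negative")
        if self.final_distance is not None and self.final_distance < 0:
            raise ValueError("final_distance must be non-negative")

    @property
    def recognized(self) -> bool:
        return self.reported_label is not None and (
            self.reported_label == self.object_label
        )


def recognition_metrics(
    records: list[SessionRecord], cfg: ProtocolConfig | None = None
) -> tuple[float, float, float]:
    """(mean recognition time, recognition accuracy %, mean confidence).

    Accuracy is the percentage of trials whose reported label matches the
    true label. Unrecognized trials contribute the full protocol duration
    to the mean time (the observer used the whole window).
    """
    if not records:
        raise ValueError("no session records given")
    if cfg is None:
        cfg = ProtocolConfig()
    times = [
        rec.recognition_time if rec.recognized else cfg.max_duration
        for rec in records
    ]
    accuracy = 100.0 * sum(rec.recognized for rec in records) / len(records)
    confidence = sum(rec.confidence for rec in records) / len(records)
    # fsum: correctly-rounded, hence order-independent, mean
    return math.fsum(times) / len(times), accuracy, confidence


def grasping_metrics(
    records: list[SessionRecord], cfg: ProtocolConfig | None = None
) -> tuple[float, float]:
    """(mean grasping attempt time, grasping accuracy %).

    A trial scores 100 when the object was correctly grasped, else 0. A
    trial that came within ``grasp_margin`` of the object without a correct
    grasp scores 0 but its grasp time still counts as a valid attempt;
    trials with neither outcome are censored at the maximum duration.
    """
    if not records:
        raise ValueError("no session records given")
    if cfg is None:
        cfg = ProtocolConfig()
    scores = []
    times = []
    for rec in records:
        scores.append(100.0 if rec.grasped_correctly else 0.0)
        near_miss = (
            rec.final_distance is not None
            and rec.final_distance <= cfg.grasp_margin
        )
        if (rec.grasped_correctly or near_miss) and rec.grasp_time is not None:
            times.append(rec.grasp_time)
        else:
            times.append(cfg.max_duration)
    return math.fsum(times) / len(times), math.fsum(scores) / len(scores)


def _parse_optional_float(value, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SessionParseError(f"row {row}: bad {column} value {value!r}") from None


def read_session_csv(path: str | Path) -> list[SessionRecord]:
    """Read a session log; raises :class:`SessionParseError` on bad rows."""
    try:
        df = pd.read_csv(path, dtype=object)
    except pd.errors.ParserError as exc:
        raise SessionParseError(f"{path}: {exc}") from None
    except pd.errors.EmptyDataError:
        raise SessionParseError(f"{path}: empty file (no header)") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SessionParseError(f"missing columns: {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        reported = row["reported_label"]
        if reported is None or (isinstance(reported, float) and pd.isna(reported)):
            reported = None
        try:
            rec = SessionRecord(
                object_label=str(row["object_label"]),
                reported_label=None if reported is None else str(reported),
                recognition_time=float(row["recognition_time_s"]),
                confidence=int(row["confidence"]),
                grasp_time=_parse_optional_float(row["grasp_time_s"], i, "grasp_time_s"),
                grasped_correctly=str(row["grasped_correctly"]).strip().lower()
                in ("1", "true", "yes"),
                final_distance=_parse_optional_float(
                    row["final_distance_cm"], i, "final_distance_cm"
                ),
            )
        except (TypeError, ValueError) as exc:
            raise SessionParseError(f"row {i}: {exc}") from None
        records.append(rec)
    return records


def write_session_csv(records: list[SessionRecord], path: str | Path) -> None:
    """Write records with the fixed header; round-trips losslessly."""
    df = pd.DataFrame(
        [
            {
                "object_label": r.object_label,
                "reported_label": "" if r.reported_label is None else r.reported_label,
                "recognition_time_s": r.recognition_time,
                "confidence": r.confidence,
                "grasp_time_s": "" if r.grasp_time is None else r.grasp_time,
                "grasped_correctly": str(r.grasped_correctly).lower(),
                "final_distance_cm": ""
                if r.final_distance is None
                else r.final_distance,
            }
            for r in records
        ],
        columns=CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def metrics_report(
    records: list[SessionRecord], cfg: ProtocolConfig | None = None
) -> dict:
    """All five metrics as a JSON-serializable dict."""
    rec_time, rec_acc, confidence = recognition_metrics(records, cfg)
    grasp_time, grasp_acc = grasping_metrics(records, cfg)
    return {
        "n_trials": len(records),
        "recognition_time_s": rec_time,
        "recognition_accuracy_pct": rec_acc,
        "confidence": confidence,
        "grasping_attempt_time_s": grasp_time,
        "grasping_accuracy_pct": grasp_acc,
    }


def format_report(report: dict) -> str:
    """Plain-text table of a metrics report."""
    lines = [f"{'metric':<28} value"]
    for key, value in report.items():
        if isinstance(value, float):
            lines.append(f"{key:<28} {value:.2f}")
        else:
            lines.append(f"{key:<28} {value}")
    return "\n".join(lines)
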