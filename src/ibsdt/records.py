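"""Per-subject critical-trial records and their CSV round trip.

One row per subject: the condition on the single critical trial (stimulus
present or absent), the stimulus features actually shown, the yes/no
"noticed" response (with an optional 0-3 confidence rating), the
forced-choice feature responses, and pre-computed exclusion flags.  Empty
string in the CSV means "not applicable".
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = ["CriticalTrialRecord", "read_records", "write_records", "records_to_frame", "COLUMNS"]

COLUMNS = [
    "subject_id",
    "experiment_id",
    "condition",
    "stim_color",
    "stim_shape",
    "stim_side",
    "attended_color",
    "noticed",
    "notice_confidence",
    "color_response",
    "shape_response",
    "side_response",
    "excluded",
    "exclusion_reason",
]

_CONDITIONS = {"present", "absent"}
_SIDES = {"left", "right"}
_NOTICED = {"yes", "no"}


@dataclass(frozen=True)
class CriticalTrialRecord:
    subject_id: str
    experiment_id: str
    condition: str
    stim_color: Optional[str] = None
    stim_shape: Optional[str] = None
    stim_side: Optional[str] = None
    attended_color: Optional[str] = None
    noticed: str = "no"
    notice_confidence: Optional[int] = None
    color_response: Optional[str] = None
    shape_response: Optional[str] = None
    side_response: Optional[str] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.condition not in _CONDITIONS:
            raise ValueError(f"condition must be 'present' or 'absent', got {self.condition!r}")
        if self.noticed not in _NOTICED:
            raise ValueError(f"noticed must be 'yes' or 'no', got {self.noticed!r}")
        if self.condition == "absent":
            for f in ("stim_color", "stim_shape", "stim_side"):
                if getattr(self, f) is not None:
                    raise ValueError(
                        f"absent-condition record {self.subject_id!r} carries a stimulus "
                        f"feature ({f}={getattr(self, f)!r})"
                    )
        if self.stim_side is not None and self.stim_side not in _SIDES:
            raise ValueError(f"stim_side must be 'left' or 'right', got {self.stim_side!r}")
        if self.side_response is not None and self.side_response not in _SIDES:
            raise ValueError(f"side_response must be 'left' or 'right', got {self.side_response!r}")
        if self.notice_confidence is not None and self.notice_confidence not in (0, 1, 2, 3):
            raise ValueError(
                f"notice_confidence must be an integer 0-3, got {self.notice_confidence!r}"
            )
        if self.excluded and not self.exclusion_reason:
            raise ValueError(f"excluded record {self.subject_id!r} lacks an exclusion reason")


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def records_to_frame(records: Iterable[CriticalTrialRecord]) -> pd.DataFrame:
    """Tabular view with the canonical column order; None rendered as ''."""
    rows = [{f.name: _cell(getattr(r, f.name)) for f in fields(CriticalTrialRecord)} for r in records]
    return pd.DataFrame(rows, columns=COLUMNS)


def write_records(records: Iterable[CriticalTrialRecord], path: Union[str, Path]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def _parse_row(row: dict) -> CriticalTrialRecord:
    def opt(name: str) -> Optional[str]:
        v = row[name]
        return None if v == "" else v

    conf = opt("notice_confidence")
    excluded_raw = row["excluded"].strip().lower()
    if excluded_raw not in {"true", "false", ""}:
        raise ValueError(f"excluded must be 'true' or 'false', got {row['excluded']!r}")
    return CriticalTrialRecord(
        subject_id=row["subject_id"],
        experiment_id=row["experiment_id"],
        condition=row["condition"],
        stim_color=opt("stim_color"),
        stim_shape=opt("stim_shape"),
        stim_side=opt("stim_side"),
        attended_color=opt("attended_color"),
        noticed=row["noticed"],
        notice_confidence=None if conf is None else int(conf),
        color_response=opt("color_response"),
        shape_response=opt("shape_response"),
        side_response=opt("side_response"),
        excluded=excluded_raw == "true",
        exclusion_reason=opt("exclusion_reason"),
    )


def read_records(path: Union[str, Path]) -> list[CriticalTrialRecord]:
    """Read and validate a records CSV.

    Raises a single ``ValueError`` listing any missing columns, or every
    malformed row with its (1-based, header-exclusive) row number.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"records file {path} is missing mandatory columns: {', '.join(missing)}")
    records: list[CriticalTrialRecord] = []
    errors: list[str] = []
    for i, row in enumerate(frame[COLUMNS].to_dict(orient="records"), start=1):
        try:
            records.append(_parse_row(row))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError(f"records file {path} has malformed rows:\n" + "\n".join(errors))
    return records
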