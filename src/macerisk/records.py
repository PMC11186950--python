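"""Time-to-event records with competing-event coding.

Event codes: 0 = censored, 1 = event of interest (MACE), 2 = competing
event (non-cardiovascular death). Times are days from the start of
treatment, strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["SurvivalRecord", "read_records_csv", "write_records_csv", "records_to_arrays"]

CENSORED, MACE, COMPETING_DEATH = 0, 1, 2


class RecordError(ValueError):
    pass


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    time: float  # days
    event: int  # 0 censored, 1 MACE, 2 non-CV death

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise RecordError(
                f"subject {self.subject_id!r}: time must be positive finite, got {self.time}"
            )
        if self.event not in (0, 1, 2):
            raise RecordError(
                f"subject {self.subject_id!r}: event must be 0/1/2, got {self.event}"
            )


def records_to_arrays(records: Sequence[SurvivalRecord]):
    """Split records into (ids, time, event) numpy arrays."""
    ids = np.array([r.subject_id for r in records])
    time = np.array([r.time for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=int)
    return ids, time, event


def read_records_csv(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path)
    need = {"subject_id", "time_days", "event"}
    if not need.issubset(df.columns):
        raise RecordError(f"records CSV requires columns {sorted(need)}")
    return [
        SurvivalRecord(str(r.subject_id), float(r.time_days), int(r.event))
        for r in df.itertuples(index=False)
    ]


def write_records_csv(records: Iterable[SurvivalRecord], path) -> None:
    records = list(records)
    pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "time_days": [r.time for r in records],
            "event": [r.event for r in records],
        }
    ).to_csv(path, index=False)
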