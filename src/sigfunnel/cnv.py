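"""CNV recurrence selection and cross-cohort exclusivity.

Copy-number events (already called upstream; calling itself is out of
scope) are compared across cohorts purely by their start coordinate:
an event key is (chrom, start).  A key is *recurrent* in a cohort when
events with that key occur in at least ``min_samples`` distinct samples.
Case-specific keys are the case-recurrent keys absent from the control
side; by default "absent" means not control-*recurrent* (a flag widens
this to any control occurrence).

Input/output is BED-like tab-separated text with columns
chrom, start, end, type, sample_id[, group].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd


class CNVType(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"


@dataclass(frozen=True)
class CNVEvent:
    sample_id: str
    chrom: str
    start: int  # 1-based
    end: int
    type: CNVType
    ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end} on {self.chrom}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start)


def select_recurrent_events(
    events: Iterable[CNVEvent], min_samples: int = 2
) -> set:
    """Start keys observed in >= min_samples distinct samples."""
    samples_by_key: dict[tuple, set] = {}
    for ev in events:
        samples_by_key.setdefault(ev.key, set()).add(ev.sample_id)
    return {k for k, s in samples_by_key.items() if len(s) >= min_samples}


def group_specific_events(
    case_events: Sequence[CNVEvent],
    control_events: Sequence[CNVEvent],
    min_samples: int = 2,
    against_all_control: bool = False,
) -> tuple[list, int, int]:
    """Case-recurrent events at start keys not shared with the control cohort.

    Returns (surviving case events, number of unique keys, number of
    events those keys cover).  With ``against_all_control`` the control
    side contributes every key it contains, recurrent or not.
    """
    case_keys = select_recurrent_events(case_events, min_samples)
    if against_all_control:
        control_keys = {ev.key for ev in control_events}
    else:
        control_keys = select_recurrent_events(control_events, min_samples)
    specific = case_keys - control_keys
    survivors = [ev for ev in case_events if ev.key in specific]
    return survivors, len(specific), len(survivors)


def read_cnv_table(path: str) -> list[CNVEvent]:
    """Read BED-like CNV calls (chrom, start, end, type, sample_id[, ratio])."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["chrom", "start", "end", "type", "sample_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing CNV columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        ratio = d.get("ratio", "")
        out.append(
            CNVEvent(
                sample_id=str(d["sample_id"]).strip(),
                chrom=str(d["chrom"]).strip(),
                start=int(d["start"]),
                end=int(d["end"]),
                type=CNVType(str(d["type"]).strip().upper()),
                ratio=float(ratio) if str(ratio).strip() else None,
            )
        )
    return out


def write_cnv_table(events: Iterable[CNVEvent], path: str) -> None:
    rows = [
        {
            "chrom": ev.chrom,
            "start": ev.start,
            "end": ev.end,
            "type": ev.type.value,
            "sample_id": ev.sample_id,
            "ratio": "" if ev.ratio is None else repr(ev.ratio),
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "type", "sample_id", "ratio"]).to_csv(
        path, sep="\t", index=False
    )
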