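"""Packaged reference data: the published phase-shift table.

The study reported, for 11 search terms, the mean pre- and
post-transition acrophase (UTC) and their signed difference in minutes,
by season.  Those printed numbers are shipped as a CSV and exposed as
typed rows; their internal consistency (printed delta == circular
difference of the printed phases) is the table's own self-test and the
package's exact acceptance surface for circular phase arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

import pandas as pd

__all__ = ["Table1Row", "table1", "table1_frame", "word_categories"]

CATEGORIES = ("sleep_health", "medication", "random")


@dataclass(frozen=True)
class Table1Row:
    """One published word x season row: mean phases (hours, UTC) and delta (min)."""

    word: str
    category: str
    season: str
    phase_pre: float
    phase_post: float
    delta_min: int
    p_label: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.season not in ("spring", "autumn"):
            raise ValueError(f"unknown season {self.season!r}")


def _hhmm_to_hours(text: str) -> float:
    hh, mm = text.split(":")
    return int(hh) + int(mm) / 60.0


def table1_frame() -> pd.DataFrame:
    """The published phase table as a DataFrame (phases parsed to hours)."""
    with files("rsvphase.data").joinpath("table1.csv").open("r") as fh:
        df = pd.read_csv(fh)
    df["phase_pre"] = df["phase_pre"].map(_hhmm_to_hours)
    df["phase_post"] = df["phase_post"].map(_hhmm_to_hours)
    return df


def table1() -> list[Table1Row]:
    """All 22 published rows (11 words x 2 seasons), exactly as printed."""
    return [
        Table1Row(
            word=r.word,
            category=r.category,
            season=r.season,
            phase_pre=r.phase_pre,
            phase_post=r.phase_post,
            delta_min=int(r.delta_min),
            p_label=r.p_label,
        )
        for r in table1_frame().itertuples()
    ]


def word_categories() -> dict[str, str]:
    """Map word -> category for the 11 analysed search terms."""
    return {row.word: row.category for row in table1()}
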