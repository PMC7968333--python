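"""Derivation and editing of heifer fertility traits.

Three traits are derived from raw reproductive event records:

* **AFC** — age at first calving, in days (calving date minus birth date);
* **IFL** — interval from first to last service, in days; 0 when the
  heifer conceived at the first service;
* **CR**  — conception rate at first service, coded 1 for a confirmed
  pregnancy after the first service and 0 otherwise.

Editing keeps AFC in [500, 1100] days and IFL in [0, 365] days
(bounds inclusive) and drops animals that changed herds between the
service and calving events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

AFC_RANGE = (500, 1100)
IFL_RANGE = (0, 365)

TRAITS = ("AFC", "IFL", "CR")


@dataclass
class EditReport:
    """Record counts removed by each editing rule."""

    n_in: int = 0
    n_out: int = 0
    removed: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"n_in": self.n_in, "n_out": self.n_out, "removed": dict(self.removed)}


def derive_traits(raw: pd.DataFrame) -> tuple[pd.DataFrame, EditReport]:
    """Derive AFC/IFL/CR and fixed-effect factors from raw event records.

    Expected columns: ``heifer_id``, ``herd``, ``birth_date``,
    ``first_service_date``, ``last_service_date``, ``calving_date``,
    ``conceived_first`` (0/1), ``technician``, ``semen_type``; optionally
    ``herd_calving`` (herd at the calving event, used by the herd-change
    filter).  Records with unordered dates (birth <= first service <=
    last service <= calving) are flagged and dropped with a log entry.

    Returns the derived table and a report of dropped records.
    """
    df = raw.copy()
    for c in ("birth_date", "first_service_date", "last_service_date", "calving_date"):
        df[c] = pd.to_datetime(df[c])

    ordered = (
        (df["birth_date"] <= df["first_service_date"])
        & (df["first_service_date"] <= df["last_service_date"])
        & (df["last_service_date"] <= df["calving_date"])
    )
    report = EditReport(n_in=len(df))
    n_bad = int((~ordered).sum())
    if n_bad:
        logger.warning("dropping %d records with unordered event dates", n_bad)
    report.removed["unordered_dates"] = n_bad
    df = df[ordered].copy()

    df["AFC"] = (df["calving_date"] - df["birth_date"]).dt.days
    df["IFL"] = (df["last_service_date"] - df["first_service_date"]).dt.days
    df["CR"] = df["conceived_first"].astype(int)
    fs = df["first_service_date"]
    df["hym"] = (
        df["herd"].astype(str) + "-" + fs.dt.year.astype(str) + "-" + fs.dt.month.astype(str).str.zfill(2)
    )
    report.n_out = len(df)
    return df, report


def edit_filters(
    table: pd.DataFrame,
    afc_range: tuple[float, float] = AFC_RANGE,
    ifl_range: tuple[float, float] = IFL_RANGE,
) -> tuple[pd.DataFrame, EditReport]:
    """Apply the range and herd-change edits; bounds are inclusive.

    Returns the filtered table and removal counts per rule.  Filtering is
    idempotent and the counts sum to ``n_in - n_out``.
    """
    report = EditReport(n_in=len(table))
    df = table

    keep = df["AFC"].between(*afc_range)
    report.removed["afc_out_of_range"] = int((~keep).sum())
    df = df[keep]

    keep = df["IFL"].between(*ifl_range)
    report.removed["ifl_out_of_range"] = int((~keep).sum())
    df = df[keep]

    if "herd_calving" in df.columns:
        changed = df["herd_calving"].notna() & (
            df["herd_calving"].astype(str) != df["herd"].astype(str)
        )
    else:
        changed = pd.Series(False, index=df.index)
    report.removed["herd_change"] = int(changed.sum())
    df = df[~changed].copy()

    report.n_out = len(df)
    for rule, n in report.removed.items():
        if n:
            logger.info("edit filter %s removed %d records", rule, n)
    return df, report
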