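"""Shared per-patient record schema used by the simulator, statistics and CLI."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import pandas as pd

MTICI_GRADES = ("0", "1", "2a", "2b", "3")

#: Ordinal coding used when mTICI enters a regression or correlation.
MTICI_ORDINAL = {g: i for i, g in enumerate(MTICI_GRADES)}

#: Columns written to / expected from cohort CSV files.
COHORT_COLUMNS = [
    "id", "cta_index", "age", "sex", "slice_thickness_mm", "mtici",
    "procedure_time_min", "nihss_pre", "nihss_post", "mrs90",
    "occlusion_site", "residual_flow",
]


@dataclass
class PatientRecord:
    """One cohort row: the imaging index plus covariates and outcomes."""

    id: str
    cta_index: float
    age: float
    sex: str                     # "F" | "M"
    slice_thickness_mm: float
    mtici: str                   # one of MTICI_GRADES
    procedure_time_min: float
    nihss_pre: int
    nihss_post: int
    mrs90: int | None            # 0-6; None when 90-day follow-up is missing
    occlusion_site: str = "M1"
    residual_flow: bool = False

    def __post_init__(self) -> None:
        if self.mtici not in MTICI_GRADES:
            raise ValueError(f"mtici must be one of {MTICI_GRADES}, got {self.mtici!r}")
        if not 0 <= self.nihss_pre <= 42 or not 0 <= self.nihss_post <= 42:
            raise ValueError("NIHSS scores must lie in [0, 42]")
        if self.mrs90 is not None and not 0 <= self.mrs90 <= 6:
            raise ValueError("mrs90 must lie in [0, 6] when present")

    @property
    def favorable(self) -> bool | None:
        """90-day favorable outcome: mRS <= 2 (None when mRS is missing)."""
        return None if self.mrs90 is None else self.mrs90 <= 2


def records_to_frame(records) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records], columns=COHORT_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    known = {f.name for f in fields(PatientRecord)}
    recs = []
    for _, row in df.iterrows():
        kw = {k: row[k] for k in df.columns if k in known}
        if "mrs90" in kw and pd.isna(kw["mrs90"]):
            kw["mrs90"] = None
        elif "mrs90" in kw:
            kw["mrs90"] = int(kw["mrs90"])
        kw["mtici"] = str(kw["mtici"])
        kw["nihss_pre"] = int(kw["nihss_pre"])
        kw["nihss_post"] = int(kw["nihss_post"])
        if "residual_flow" in kw:
            kw["residual_flow"] = bool(kw["residual_flow"])
        recs.append(PatientRecord(**kw))
    return recs
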