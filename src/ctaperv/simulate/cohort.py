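"""Simulated patient cohorts and two-rater measurement tables.

Group sizes and the per-outcome-group index distributions default to the
published validation-cohort figures (30 favorable ~ N(-0.52, 0.13), 51
non-favorable ~ N(-0.70, 0.09)); the original perviousness cohort is
available as an alternate preset. Index draws are rejection-truncated to
the open interval (-1, 1), the mathematical range of the asymmetry index.

Covariates follow the printed marginal summaries (median/IQR or category
counts); the distributional forms (normal age, log-normal procedure time,
normality of the index within outcome groups) are modelling assumptions
of this generator, not claims about the source data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..records import MTICI_GRADES, PatientRecord

__all__ = [
    "CohortSimSpec",
    "generate_cohort",
    "generate_rater_pairs",
    "simulate_rater_study",
    "cohort_spec",
    "PRESETS",
]

_IQR_TO_SD = 2 * 0.6744897501960817  # IQR of a standard normal


@dataclass
class CohortSimSpec:
    n_favorable: int = 30
    n_nonfavorable: int = 51
    mean_fav: float = -0.52
    sd_fav: float = 0.13
    mean_nonfav: float = -0.70
    sd_nonfav: float = 0.09
    age_median: float = 77.0
    age_iqr: tuple[float, float] = (69.0, 84.0)
    female_frac: float = 53 / 87
    mtici_counts: tuple[float, ...] = (6, 1, 2, 25, 52)  # grades 0,1,2a,2b,3
    procedure_time_median: float = 31.0
    procedure_time_iqr: tuple[float, float] = (21.0, 62.0)
    nihss_pre_median: float = 13.0
    nihss_pre_iqr: tuple[float, float] = (7.0, 18.0)
    nihss_post_median: float = 5.0
    nihss_post_iqr: tuple[float, float] = (1.0, 13.0)
    # higher index -> lower discharge NIHSS; slope in score units per index unit
    nihss_index_slope: float = -12.0
    slice_thickness_choices: tuple[float, ...] = (0.6, 1.0, 2.0, 3.0)
    slice_thickness_probs: tuple[float, ...] = (0.7, 0.15, 0.1, 0.05)
    rater_noise_sd: float = 0.058
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_favorable <= 0 or self.n_nonfavorable <= 0:
            raise ValueError("group sizes must be positive")
        if self.sd_fav <= 0 or self.sd_nonfav <= 0:
            raise ValueError("group SDs must be positive")
        if self.rater_noise_sd < 0:
            raise ValueError("rater_noise_sd must be non-negative")


#: Named parameter sets: ``validation`` is the default; ``perviousness``
#: uses the first cohort's group sizes and index distributions.
PRESETS: dict[str, dict] = {
    "validation": {},
    "perviousness": dict(
        n_favorable=23,
        n_nonfavorable=28,
        mean_fav=-0.55,
        sd_fav=0.16,
        mean_nonfav=-0.64,
        sd_nonfav=0.14,
        age_median=78.0,
        age_iqr=(71.0, 86.0),
        female_frac=49 / 101,
        mtici_counts=(12, 1, 5, 33, 50),
        procedure_time_median=35.0,
        procedure_time_iqr=(22.0, 49.5),
        nihss_pre_median=14.0,
        nihss_pre_iqr=(10.0, 18.0),
        nihss_post_median=6.0,
        nihss_post_iqr=(1.0, 12.0),
    ),
}


def cohort_spec(preset: str = "validation", **overrides) -> CohortSimSpec:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; options: {sorted(PRESETS)}")
    kw = dict(PRESETS[preset])
    kw.update(overrides)
    return CohortSimSpec(**kw)


def _truncated_normal(rng, mean, sd, n, lo=-1.0, hi=1.0):
    """Rejection sampling from N(mean, sd) restricted to (lo, hi)."""
    if sd == 0:
        return np.full(n, float(mean))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        keep = draw[(draw > lo) & (draw < hi)][: n - filled]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def _median_iqr_normal(rng, median, iqr, n, lo=None, hi=None):
    sd = (iqr[1] - iqr[0]) / _IQR_TO_SD
    x = rng.normal(median, sd, n)
    if lo is not None or hi is not None:
        x = np.clip(x, lo, hi)
    return x


def _median_iqr_lognormal(rng, median, iqr, n):
    sigma = np.log(iqr[1] / iqr[0]) / _IQR_TO_SD
    return np.exp(rng.normal(np.log(median), sigma, n))


def generate_cohort(spec: CohortSimSpec) -> list[PatientRecord]:
    """Draw one cohort; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_favorable + spec.n_nonfavorable
    favorable = np.r_[np.ones(spec.n_favorable, bool), np.zeros(spec.n_nonfavorable, bool)]

    index = np.empty(n)
    index[favorable] = _truncated_normal(rng, spec.mean_fav, spec.sd_fav, spec.n_favorable)
    index[~favorable] = _truncated_normal(
        rng, spec.mean_nonfav, spec.sd_nonfav, spec.n_nonfavorable
    )

    age = _median_iqr_normal(rng, spec.age_median, spec.age_iqr, n, lo=18, hi=102)
    sex = np.where(rng.random(n) < spec.female_frac, "F", "M")
    mtici_p = np.asarray(spec.mtici_counts, float)
    mtici = rng.choice(list(MTICI_GRADES), size=n, p=mtici_p / mtici_p.sum())
    proc = _median_iqr_lognormal(
        rng, spec.procedure_time_median, spec.procedure_time_iqr, n
    )
    nihss_pre = np.clip(
        np.rint(_median_iqr_normal(rng, spec.nihss_pre_median, spec.nihss_pre_iqr, n)),
        0, 42,
    ).astype(int)
    overall_mean = (
        spec.n_favorable * spec.mean_fav + spec.n_nonfavorable * spec.mean_nonfav
    ) / n
    post_sd = (spec.nihss_post_iqr[1] - spec.nihss_post_iqr[0]) / _IQR_TO_SD
    nihss_post = np.clip(
        np.rint(
            spec.nihss_post_median
            + spec.nihss_index_slope * (index - overall_mean)
            + rng.normal(0.0, post_sd, n)
        ),
        0, 42,
    ).astype(int)
    thickness = rng.choice(
        spec.slice_thickness_choices, size=n, p=spec.slice_thickness_probs
    )
    mrs = np.where(favorable, rng.integers(0, 3, n), rng.integers(3, 7, n))

    records = [
        PatientRecord(
            id=f"sim{i:04d}",
            cta_index=float(index[i]),
            age=float(np.round(age[i], 1)),
            sex=str(sex[i]),
            slice_thickness_mm=float(thickness[i]),
            mtici=str(mtici[i]),
            procedure_time_min=float(np.round(proc[i], 1)),
            nihss_pre=int(nihss_pre[i]),
            nihss_post=int(nihss_post[i]),
            mrs90=int(mrs[i]),
        )
        for i in range(n)
    ]
    order = rng.permutation(n)
    return [records[i] for i in order]


def generate_rater_pairs(
    records, rater_noise_sd: float, seed: int
) -> pd.DataFrame:
    """Two independent re-measurements of each record's index.

    Each rater observes ``true index + N(0, rater_noise_sd)`` noise,
    independent between raters and subjects.
    """
    if rater_noise_sd < 0:
        raise ValueError("rater_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    truth = np.array([r.cta_index for r in records], dtype=float)
    noise = rng.normal(0.0, rater_noise_sd, size=(len(truth), 2)) if rater_noise_sd else np.zeros((len(truth), 2))
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "rater1": truth + noise[:, 0],
            "rater2": truth + noise[:, 1],
        }
    )


def simulate_rater_study(
    n_subjects: int, true_icc: float, seed: int,
    between_sd: float = 1.0,
) -> pd.DataFrame:
    """Two-rater table whose population ICC(2,1) equals ``true_icc``.

    Subject effects are N(0, between_sd^2); the rater-noise SD is solved
    from ``icc = sigma_s^2 / (sigma_s^2 + sigma_e^2)``.
    """
    if not 0 < true_icc < 1:
        raise ValueError("true_icc must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    noise_sd = between_sd * np.sqrt(1.0 / true_icc - 1.0)
    truth = rng.normal(0.0, between_sd, n_subjects)
    noise = rng.normal(0.0, noise_sd, size=(n_subjects, 2))
    return pd.DataFrame(
        {
            "id": [f"subj{i:04d}" for i in range(n_subjects)],
            "rater1": truth + noise[:, 0],
            "rater2": truth + noise[:, 1],
        }
    )
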