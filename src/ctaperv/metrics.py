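"""Perviousness statistics: attenuation change, void fraction and CTA-index.

Definitions, for mean HU measured at the occlusion site (T) and at the
corresponding contralateral patent vessel (C) on each scan:

* attenuation change   ``delta = HU_on_CTA - HU_on_NCCT`` (per site)
* void fraction        ``epsilon = delta_T / delta_C``
* CTA-index            ``(HU_T - HU_C) / (HU_T + HU_C)`` on the CTA alone,
  an asymmetry index bounded in (-1, 1) for positive inputs.

Negative attenuation changes (possible under noise) are kept, not
clipped, and flagged so downstream statistics see symmetric noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

__all__ = [
    "cta_index", "delta_attenuation", "void_fraction", "compute_result",
    "PerviousnessResult", "MetricError",
    "FLAG_NEGATIVE_UPTAKE", "FLAG_NEGATIVE_CONTRA",
]


class MetricError(ValueError):
    """Non-physical input to a perviousness formula."""


FLAG_NEGATIVE_UPTAKE = "negative-uptake"
FLAG_NEGATIVE_CONTRA = "negative-contralateral-change"


def cta_index(hu_t: float, hu_c: float) -> float:
    """Relative thrombus attenuation on CTA: ``(hu_t - hu_c)/(hu_t + hu_c)``.

    Antisymmetric under argument swap and invariant to joint positive
    scaling. Requires ``hu_t + hu_c > 0`` (both sites should attenuate
    positively on a contrast-bearing vessel).
    """
    s = hu_t + hu_c
    if s <= 0:
        raise MetricError(
            f"non-physical attenuation pair (HU_T={hu_t}, HU_C={hu_c}): "
            "HU_T + HU_C must be positive"
        )
    return (hu_t - hu_c) / s


def delta_attenuation(hu_cta: float, hu_ncct: float) -> float:
    """Attenuation increase from NCCT to CTA at one site (may be negative)."""
    return hu_cta - hu_ncct


def void_fraction(delta_t: float, delta_c: float) -> float:
    """Thrombus attenuation change normalized by the contralateral change."""
    if delta_c <= 0:
        raise MetricError(
            f"no contralateral enhancement (delta_c={delta_c}): the reference "
            "artery must enhance"
        )
    return delta_t / delta_c


@dataclass
class PerviousnessResult:
    """All per-patient perviousness quantities plus quality flags."""

    hu_t_cta: float
    hu_c_cta: float
    hu_t_ncct: float
    hu_c_ncct: float
    delta_t: float
    delta_c: float
    void_fraction: float
    cta_index: float
    flags: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "hu_t_cta", "hu_c_cta", "hu_t_ncct", "hu_c_ncct",
                "delta_t", "delta_c", "void_fraction", "cta_index",
            )
        }
        d["flags"] = sorted(self.flags)
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def compute_result(samples) -> PerviousnessResult:
    """Assemble a :class:`PerviousnessResult` from the four mean-HU samples.

    ``samples`` maps ``(scan, side)`` keys — scan in {"CTA", "NCCT"},
    side in {"T", "C"} — to objects with a ``mean_hu`` attribute (or bare
    floats). A missing combination is reported by name.
    """
    required = [(scan, side) for scan in ("CTA", "NCCT") for side in ("T", "C")]
    missing = [k for k in required if k not in samples]
    if missing:
        raise MetricError(
            "missing attenuation sample(s): "
            + ", ".join(f"{scan}/{side}" for scan, side in missing)
        )

    def hu(scan, side):
        v = samples[(scan, side)]
        return float(getattr(v, "mean_hu", v))

    hu_t_cta, hu_c_cta = hu("CTA", "T"), hu("CTA", "C")
    hu_t_ncct, hu_c_ncct = hu("NCCT", "T"), hu("NCCT", "C")
    dt = delta_attenuation(hu_t_cta, hu_t_ncct)
    dc = delta_attenuation(hu_c_cta, hu_c_ncct)

    flags = set()
    if dt < 0:
        flags.add(FLAG_NEGATIVE_UPTAKE)
    if dc < 0:
        flags.add(FLAG_NEGATIVE_CONTRA)

    return PerviousnessResult(
        hu_t_cta=hu_t_cta,
        hu_c_cta=hu_c_cta,
        hu_t_ncct=hu_t_ncct,
        hu_c_ncct=hu_c_ncct,
        delta_t=dt,
        delta_c=dc,
        void_fraction=void_fraction(dt, dc),
        cta_index=cta_index(hu_t_cta, hu_c_cta),
        flags=frozenset(flags),
    )
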