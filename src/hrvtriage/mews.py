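"""Modified early warning score (MEWS).

Five physiologic components, each binned to an integer 0–3 subscore:
respiratory rate, heart rate, systolic blood pressure, temperature and the
AVPU consciousness level. The total is the sum (0–14; the respiratory-rate
and temperature scales top out below 3 on one side).

The published bins are integer-labelled (e.g. respiratory rate "9 to 14" vs
"15 to 20"), which leaves gaps for fractional measurements. Inputs are
therefore rounded to the bins' printed resolution before binning — heart
rate, respiratory rate and systolic pressure to the nearest integer,
temperature to one decimal — which makes the bins exhaustive and
non-overlapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

AVPU_LEVELS = ("alert", "voice", "pain", "unresponsive")

#: Plausible physiologic ranges; violations warn but do not error.
_PLAUSIBLE = {
    "resp_rate": (0, 80),
    "heart_rate": (0, 300),
    "sbp": (0, 300),
    "temperature": (25, 45),
}


class MissingVitalError(ValueError):
    """A scored vital sign is absent: the total would be misleading."""


@dataclass
class Vitals:
    """Triage vital signs. The five scored fields are required for a MEWS;
    the remainder (age, dbp, spo2, gcs, pain_score) are carried for the
    machine-learning feature vector but do not enter the MEWS."""

    resp_rate: float | None = None      # breaths/min
    heart_rate: float | None = None     # beats/min
    sbp: float | None = None            # mmHg
    temperature: float | None = None    # deg C
    avpu: str | None = None             # alert | voice | pain | unresponsive
    age: float | None = None            # years
    dbp: float | None = None            # mmHg
    spo2: float | None = None           # %
    gcs: float | None = None            # 3-15
    pain_score: float | None = None     # 0-10

    def __post_init__(self) -> None:
        if self.avpu is not None:
            a = self.avpu.strip().lower()
            if a not in AVPU_LEVELS:
                raise ValueError(f"avpu must be one of {AVPU_LEVELS}, got {self.avpu!r}")
            self.avpu = a
        for name, (lo, hi) in _PLAUSIBLE.items():
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                warnings.warn(f"{name}={v} outside plausible range [{lo}, {hi}]",
                              stacklevel=2)


@dataclass
class MewsResult:
    sub_scores: dict[str, int]
    total: int


def _score_resp_rate(rr: int) -> int:
    if rr <= 8:
        return 2
    if rr <= 14:
        return 0
    if rr <= 20:
        return 1
    if rr <= 29:
        return 2
    return 3


def _score_heart_rate(hr: int) -> int:
    if hr <= 40:
        return 2
    if hr <= 50:
        return 1
    if hr <= 100:
        return 0
    if hr <= 110:
        return 1
    if hr <= 129:
        return 2
    return 3


def _score_sbp(sbp: int) -> int:
    if sbp <= 70:
        return 3
    if sbp <= 80:
        return 2
    if sbp <= 100:
        return 1
    if sbp <= 199:
        return 0
    return 2


def _score_temperature(t: float) -> int:
    # t has been rounded to 1 decimal; compare in tenths to avoid float fuzz
    tenths = round(t * 10)
    if tenths <= 350:
        return 2
    if tenths <= 360:
        return 1
    if tenths <= 380:
        return 0
    if tenths <= 385:
        return 1
    return 2


def _score_avpu(avpu: str) -> int:
    return AVPU_LEVELS.index(avpu)


def mews_score(v: Vitals) -> MewsResult:
    """Compute the MEWS with per-component subscores.

    Raises
    ------
    MissingVitalError
        If any of the five scored fields is ``None`` — a missing component
        never silently scores zero.
    """
    required = ("resp_rate", "heart_rate", "sbp", "temperature", "avpu")
    missing = [f for f in required if getattr(v, f) is None]
    if missing:
        raise MissingVitalError(f"cannot score MEWS, missing: {', '.join(missing)}")
    sub = {
        "resp_rate": _score_resp_rate(int(round(v.resp_rate))),
        "heart_rate": _score_heart_rate(int(round(v.heart_rate))),
        "sbp": _score_sbp(int(round(v.sbp))),
        "temperature": _score_temperature(round(v.temperature, 1)),
        "avpu": _score_avpu(v.avpu),
    }
    return MewsResult(sub_scores=sub, total=sum(sub.values()))


def mews_positive(result: MewsResult, cutoff: int = 3) -> bool:
    """Screen-positive flag: total at or above the cutoff (default >= 3)."""
    return result.total >= cutoff
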