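"""Revised Trauma Score (RTS) and TRISS survival model.

RTS is a weighted sum of coded GCS, systolic blood pressure, and respiratory
rate points::

    RTS = 0.9368 * GCS_pts + 0.7326 * SBP_pts + 0.2908 * RR_pts

TRISS maps RTS, ISS and an age >= 55 indicator through a mechanism-specific
logistic model to a probability of survival::

    P(survive) = 1 - 1 / (1 + exp(b)),
    b = b0 + b_rts * RTS + b_iss * ISS + b_age * 1{age >= 55}

with blunt coefficients (-0.4499, 0.8085, -0.0835, -1.743) and penetrating
coefficients (-2.5355, 0.9934, -0.0651, -1.136).  Mortality risk is the
complement of survival.

All scalar operations accept numpy arrays and broadcast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "RTS_WEIGHTS",
    "RTS_MAX",
    "TRISS_COEFFICIENTS",
    "AGE_THRESHOLD",
    "RtsPoints",
    "TraumaScorePanel",
    "gcs_points",
    "sbp_points",
    "rr_points",
    "rts",
    "triss_survival",
    "assemble_panels",
]

#: (GCS, SBP, RR) point weights of the RTS.
RTS_WEIGHTS = (0.9368, 0.7326, 0.2908)

#: Maximum attainable RTS (all points = 4).
RTS_MAX = 4 * sum(RTS_WEIGHTS)

AGE_THRESHOLD = 55

#: mechanism -> (intercept, b_rts, b_iss, b_age)
TRISS_COEFFICIENTS: Mapping[str, tuple[float, float, float, float]] = {
    "blunt": (-0.4499, 0.8085, -0.0835, -1.743),
    "penetrating": (-2.5355, 0.9934, -0.0651, -1.136),
}


@dataclass(frozen=True)
class RtsPoints:
    gcs_points: int
    sbp_points: int
    rr_points: int

    def __post_init__(self):
        for name in ("gcs_points", "sbp_points", "rr_points"):
            v = getattr(self, name)
            if v not in (0, 1, 2, 3, 4):
                raise ValueError(f"{name} must be in 0..4, got {v!r}")


@dataclass(frozen=True)
class TraumaScorePanel:
    """One score variant for one patient."""

    variant: str  # real | ml_rts | ml_triss | ml_triss2
    rts: float
    triss_survival: float

    @property
    def mortality_risk(self) -> float:
        return 1.0 - self.triss_survival


def _check_range(x, lo, hi, name):
    x = np.asarray(x)
    if np.any((x < lo) | (x > hi)):
        raise ValueError(f"{name} out of range [{lo}, {hi}]")
    return x


def gcs_points(gcs):
    """GCS -> RTS points: 3->0, 4-5->1, 6-8->2, 9-12->3, 13-15->4."""
    g = _check_range(np.asarray(gcs, dtype=int), 3, 15, "gcs")
    pts = np.select([g == 3, g <= 5, g <= 8, g <= 12], [0, 1, 2, 3], default=4)
    return pts if pts.ndim else int(pts)


def sbp_points(sbp):
    """SBP (mmHg) -> RTS points: 0->0, 1-49->1, 50-75->2, 76-89->3, >89->4."""
    s = np.asarray(sbp, dtype=float)
    if np.any(s < 0):
        raise ValueError("sbp must be non-negative")
    pts = np.select([s == 0, s <= 49, s <= 75, s <= 89], [0, 1, 2, 3], default=4)
    return pts if pts.ndim else int(pts)


def rr_points(rr):
    """RR (breaths/min) -> RTS points: 0->0, 1-5->1, 6-9->2, 10-29->4, >29->3."""
    r = np.asarray(rr, dtype=float)
    if np.any(r < 0):
        raise ValueError("rr must be non-negative")
    pts = np.select([r == 0, r <= 5, r <= 9, r <= 29], [0, 1, 2, 4], default=3)
    return pts if pts.ndim else int(pts)


def rts(points: RtsPoints) -> float:
    """Weighted RTS from a points triple, full precision."""
    w = RTS_WEIGHTS
    return (
        w[0] * points.gcs_points + w[1] * points.sbp_points + w[2] * points.rr_points
    )


def rts_from_values(gcs, sbp, rr):
    """RTS computed directly from raw GCS / SBP / RR values (vectorized)."""
    w = RTS_WEIGHTS
    return (
        w[0] * np.asarray(gcs_points(gcs))
        + w[1] * np.asarray(sbp_points(sbp))
        + w[2] * np.asarray(rr_points(rr))
    )


def triss_survival(rts_value, iss, age, mechanism: str):
    """TRISS probability of survival.

    Parameters
    ----------
    rts_value : RTS in [0, 7.8408].
    iss : ISS, real-valued, in [1, 75] (ML estimates enter unrounded).
    age : age in years; only the >= 55 indicator enters the model.
    mechanism : "blunt" or "penetrating"; TRISS is defined only for these.
    """
    if mechanism not in TRISS_COEFFICIENTS:
        raise ValueError(
            f"TRISS is defined only for blunt/penetrating mechanisms, got {mechanism!r}"
        )
    r = _check_range(np.asarray(rts_value, dtype=float), 0.0, RTS_MAX + 1e-9, "rts")
    i = _check_range(np.asarray(iss, dtype=float), 1.0, 75.0, "iss")
    a = np.asarray(age, dtype=float)
    b0, brts, biss, bage = TRISS_COEFFICIENTS[mechanism]
    b = b0 + brts * r + biss * i + bage * (a >= AGE_THRESHOLD)
    # 1 - 1/(1+e^b) == logistic(b); evaluated in the numerically stable form
    p = np.where(b >= 0, 1.0 / (1.0 + np.exp(-b)), np.exp(b) / (1.0 + np.exp(b)))
    return p if p.ndim else float(p)


def assemble_panels(
    gcs: int,
    iss: float,
    age: float,
    mechanism: str,
    measured_sbp: float,
    measured_rr: float,
    ml_gcs: Optional[int] = None,
    ml_iss: Optional[float] = None,
) -> dict[str, TraumaScorePanel]:
    """Build the four score panels for one patient.

    real      : true GCS and true ISS.
    ml_rts    : ML-GCS substituted into the RTS (ISS stays true).
    ml_triss  : ML-ISS substituted into TRISS, RTS keeps the real GCS.
    ml_triss2 : both ML-ISS and ML-GCS substituted.

    SBP and RR points always come from the measured (cleaned, windowed)
    vital-sign summaries.  ML-ISS is clamped to [1, 75] and enters the TRISS
    linear predictor unrounded.
    """
    if not (np.isfinite(measured_sbp) and np.isfinite(measured_rr)):
        raise ValueError("measured SBP/RR summary unavailable; panel incomputable")
    sp = sbp_points(measured_sbp)
    rp = rr_points(measured_rr)

    def _panel(variant, g, i):
        r = rts(RtsPoints(int(gcs_points(g)), int(sp), int(rp)))
        i = float(np.clip(i, 1.0, 75.0))
        return TraumaScorePanel(variant, r, triss_survival(r, i, age, mechanism))

    panels = {"real": _panel("real", gcs, iss)}
    if ml_gcs is not None:
        panels["ml_rts"] = _panel("ml_rts", ml_gcs, iss)
    if ml_iss is not None:
        panels["ml_triss"] = _panel("ml_triss", gcs, ml_iss)
    if ml_gcs is not None and ml_iss is not None:
        panels["ml_triss2"] = _panel("ml_triss2", ml_gcs, ml_iss)
    return panels
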