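"""Shared clinical category maps for GCS and ISS.

Single source of truth for the coarse severity bins used by case weighting,
confusion-matrix aggregation, and the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "CategoryMap",
    "GCS_CATEGORIES",
    "ISS_CATEGORIES",
    "GCS_POINTS_CATEGORIES",
    "gcs_category",
    "iss_category",
]


@dataclass(frozen=True)
class CategoryMap:
    """Total mapping from raw integer scores to ordered category labels."""

    name: str
    labels: tuple[str, ...]
    mapper: Callable[[np.ndarray], np.ndarray]

    def __call__(self, raw) -> np.ndarray:
        raw = np.asarray(raw)
        out = self.mapper(raw)
        if np.any(out < 0):
            bad = np.unique(raw[out < 0])
            raise ValueError(f"{self.name}: unmapped raw values {bad.tolist()}")
        return out

    def label_of(self, raw) -> np.ndarray:
        return np.asarray(self.labels)[self(raw)]


def _gcs_mapper(g: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=int)
    out = np.full(g.shape, -1, dtype=int)
    out[(g >= 3) & (g <= 8)] = 2
    out[(g >= 9) & (g <= 12)] = 1
    out[(g >= 13) & (g <= 15)] = 0
    return out


def _iss_mapper(i: np.ndarray) -> np.ndarray:
    i = np.asarray(i, dtype=int)
    out = np.full(i.shape, -1, dtype=int)
    out[(i >= 1) & (i <= 8)] = 0
    out[(i >= 9) & (i <= 15)] = 1
    out[(i >= 16) & (i <= 24)] = 2
    out[i > 24] = 3
    return out


def _gcs_points_mapper(g: np.ndarray) -> np.ndarray:
    # five RTS-point bins: 3 | 4-5 | 6-8 | 9-12 | 13-15 -> 0..4
    from .trauma_scores import gcs_points

    return np.asarray(gcs_points(g), dtype=int)


#: Mild (13-15) / Moderate (9-12) / Severe (3-8) TBI categories.
GCS_CATEGORIES = CategoryMap("gcs_tbi", ("mild", "moderate", "severe"), _gcs_mapper)

#: Mild (1-8) / Moderate (9-15) / Severe (16-24) / Profound (>24) ISS bins.
ISS_CATEGORIES = CategoryMap(
    "iss", ("mild", "moderate", "severe", "profound"), _iss_mapper
)

#: GCS aggregated to the five RTS points categories (0..4).
GCS_POINTS_CATEGORIES = CategoryMap(
    "gcs_rts_points", ("0", "1", "2", "3", "4"), _gcs_points_mapper
)


def gcs_category(gcs) -> np.ndarray:
    """Category index: 0=mild, 1=moderate, 2=severe."""
    return GCS_CATEGORIES(gcs)


def iss_category(iss) -> np.ndarray:
    """Category index: 0=mild, 1=moderate, 2=severe, 3=profound."""
    return ISS_CATEGORIES(iss)
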