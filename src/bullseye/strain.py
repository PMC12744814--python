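"""Segmental left-ventricular longitudinal strain: data model and summaries.

Longitudinal strain measures the fractional shortening of a myocardial wall
segment between end-diastole and end-systole,

    GLS(%) = 100 * (MLs - MLd) / MLd,

where MLs and MLd are the myocardial lengths at end-systole and end-diastole.
A healthy, contracting wall shortens, so strain is *negative* — around −18 %
in normal myocardium.  Clinical reports often quote the magnitude (e.g.
"GLS 15.6 %"); this package stores strain **signed** and normalizes
magnitude-convention input on read.

The left ventricle is divided into 18 segments (6 basal, 6 mid, 6 apical)
displayed on a polar "bull's-eye" map.  :class:`StrainMap` holds the 18
segmental values; per-territory summaries live here while the territory
definitions themselves live in :mod:`bullseye.pattern`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

N_SEGMENTS = 18

__all__ = [
    "N_SEGMENTS",
    "SegmentStrain",
    "StrainMap",
    "MyocardialLengths",
    "compute_gls",
    "normalize_sign",
    "average_gls",
    "regional_gls",
]


@dataclass(frozen=True)
class SegmentStrain:
    """Strain of a single myocardial segment.

    Parameters
    ----------
    segment_id
        Segment number, 1–18 (basal 1–6, mid 7–12, apical 13–18).
    gls
        Longitudinal strain in percent.  Negative means systolic shortening
        in the signed convention.
    valid
        False marks a segment that could not be measured (e.g. poor
        speckle tracking); its ``gls`` is ignored.
    """

    segment_id: int
    gls: float
    valid: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.segment_id <= N_SEGMENTS):
            raise ValueError(f"segment_id must be in 1..18, got {self.segment_id}")
        if self.valid:
            if not math.isfinite(self.gls):
                raise ValueError(f"segment {self.segment_id}: gls must be finite")
            if abs(self.gls) >= 100:
                raise ValueError(
                    f"segment {self.segment_id}: |gls| must be < 100 %, got {self.gls}"
                )


class StrainMap:
    """The 18 segmental strain values of one study, as a polar map.

    Internally a length-18 float array indexed by ``segment_id - 1``;
    invalid/missing segments are NaN.  ``convention`` is ``"signed"``
    (negative = shortening) or ``"magnitude"`` (absolute values, as printed
    in many clinical tables); analysis functions require the signed form —
    see :func:`normalize_sign`.
    """

    __slots__ = ("values", "convention")

    def __init__(
        self,
        values: Iterable[float] | np.ndarray,
        convention: Literal["signed", "magnitude"] = "signed",
    ) -> None:
        arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                         dtype=float)
        if arr.shape != (N_SEGMENTS,):
            raise ValueError(f"a strain map needs exactly {N_SEGMENTS} values, got {arr.shape}")
        finite = np.isfinite(arr)
        if np.any(np.abs(arr[finite]) >= 100):
            raise ValueError("|gls| must be < 100 % for every valid segment")
        if np.any(np.isinf(arr)):
            raise ValueError("gls values must be finite or NaN (missing)")
        if convention not in ("signed", "magnitude"):
            raise ValueError(f"unknown convention {convention!r}")
        self.values = arr
        self.convention = convention

    @classmethod
    def from_segments(
        cls,
        segments: Iterable[SegmentStrain],
        convention: Literal["signed", "magnitude"] = "signed",
    ) -> "StrainMap":
        vals = np.full(N_SEGMENTS, np.nan)
        seen: set[int] = set()
        for seg in segments:
            if seg.segment_id in seen:
                raise ValueError(f"duplicate segment_id {seg.segment_id}")
            seen.add(seg.segment_id)
            vals[seg.segment_id - 1] = seg.gls if seg.valid else np.nan
        if seen != set(range(1, N_SEGMENTS + 1)):
            missing = sorted(set(range(1, N_SEGMENTS + 1)) - seen)
            raise ValueError(f"missing segment ids: {missing}")
        return cls(vals, convention)

    def segments(self) -> list[SegmentStrain]:
        return [
            SegmentStrain(i + 1, float(v) if math.isfinite(v) else 0.0,
                          valid=bool(math.isfinite(v)))
            for i, v in enumerate(self.values)
        ]

    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def __getitem__(self, segment_id: int) -> float:
        if not (1 <= segment_id <= N_SEGMENTS):
            raise KeyError(segment_id)
        return float(self.values[segment_id - 1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StrainMap):
            return NotImplemented
        return (self.convention == other.convention
                and np.array_equal(self.values, other.values, equal_nan=True))

    def __repr__(self) -> str:
        return f"StrainMap({self.values!r}, convention={self.convention!r})"


@dataclass(frozen=True)
class MyocardialLengths:
    """Myocardial length at end-systole (``mls``) and end-diastole (``mld``),
    in any single consistent unit; both strictly positive."""

    mls: float
    mld: float

    def __post_init__(self) -> None:
        if not (self.mls > 0 and self.mld > 0):
            raise ValueError(f"lengths must be positive, got mls={self.mls}, mld={self.mld}")


def compute_gls(lengths: MyocardialLengths) -> float:
    """Longitudinal strain in percent from end-systolic/diastolic lengths.

    ``100 * (MLs - MLd) / MLd``: negative when the wall shortens, zero when
    the length does not change, positive for paradoxical lengthening.
    """
    return 100.0 * (lengths.mls - lengths.mld) / lengths.mld


def normalize_sign(strain_map: StrainMap) -> StrainMap:
    """Return ``strain_map`` in the signed convention.

    Magnitude-convention values ``v`` (all non-negative) become ``-v``;
    a signed map is returned unchanged.  Idempotent.

    Raises
    ------
    ValueError
        If a magnitude-convention map contains negative values (mixed-sign
        input is ambiguous and refused).
    """
    if strain_map.convention == "signed":
        return strain_map
    vals = strain_map.values
    if np.any(vals[np.isfinite(vals)] < 0):
        raise ValueError("magnitude-convention map contains negative values; "
                         "declare the convention of the input correctly")
    return StrainMap(-vals, convention="signed")


def _valid_mean(values: np.ndarray, allow_missing: int, what: str) -> float:
    n_missing = int(np.isnan(values).sum())
    if n_missing > allow_missing:
        raise ValueError(
            f"{what}: {n_missing} missing segment(s), allowed {allow_missing}"
        )
    if n_missing == values.size:
        raise ValueError(f"{what}: no valid segments")
    return float(np.nanmean(values))


def average_gls(strain_map: StrainMap, allow_missing: int = 0) -> float:
    """Mean of the 18 signed segmental strain values ("average LV GLS").

    Missing segments are a hard error by default; ``allow_missing`` (≤ 2 is
    the sanctioned ceiling) averages over the valid segments instead.
    """
    strain_map = normalize_sign(strain_map)
    return _valid_mean(strain_map.values, allow_missing, "average_gls")


def regional_gls(strain_map: StrainMap, vessel: str, allow_missing: int = 0) -> float:
    """Mean signed strain over the 6 segments of one coronary territory.

    ``vessel`` is ``"LAD"``, ``"LCx"`` or ``"RCA"``; the segment lists are
    defined in :mod:`bullseye.pattern`.
    """
    from .pattern import TERRITORIES  # territory definitions live with the classifier

    if vessel not in TERRITORIES:
        raise ValueError(f"unknown vessel {vessel!r}; expected one of {sorted(TERRITORIES)}")
    strain_map = normalize_sign(strain_map)
    idx = [s - 1 for s in TERRITORIES[vessel]]
    return _valid_mean(strain_map.values[idx], allow_missing, f"regional_gls[{vessel}]")
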