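"""Coronary territories on the 18-segment polar map and the ischemic
bull's-eye pattern classifier.

Each coronary artery perfuses six segments:

* LAD (left anterior descending): 1, 2, 7, 8, 13, 14
* LCx (left circumflex):          5, 6, 11, 12, 17, 18
* RCA (right coronary):           3, 4, 9, 10, 15, 16

The ischemic pattern rule: a territory is flagged when it contains more than
two *consecutive* impaired segments — i.e. a connected cluster of at least
three segments whose signed strain magnitude is below the 15 % cutoff
(signed value strictly greater than −15).  The study is positive when any
territory is flagged.

"Consecutive" on a polar map is read as adjacency: circumferential
neighbours within a ring (ids differing by 1 mod 6 inside rings 1–6, 7–12,
13–18) plus radial neighbours across rings (ids differing by exactly 6).
An alternative ``index_run`` mode counts runs of consecutive ids in the
territory's sorted segment list; both ship because the clinical phrasing is
ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Dict, Literal, Mapping, Tuple

import numpy as np

from .strain import N_SEGMENTS, StrainMap, normalize_sign

VESSELS: Tuple[str, ...] = ("LAD", "LCx", "RCA")

TERRITORIES: Mapping[str, Tuple[int, ...]] = {
    "LAD": (1, 2, 7, 8, 13, 14),
    "LCx": (5, 6, 11, 12, 17, 18),
    "RCA": (3, 4, 9, 10, 15, 16),
}

_SEGMENT_TO_VESSEL: Dict[int, str] = {
    seg: vessel for vessel, segs in TERRITORIES.items() for seg in segs
}

DEFAULT_CUTOFF = -15.0

__all__ = [
    "VESSELS",
    "TERRITORIES",
    "DEFAULT_CUTOFF",
    "PatternConfig",
    "PatternResult",
    "territory_of",
    "is_impaired",
    "adjacent",
    "detect_pattern",
    "detect_pattern_batch",
    "plot_bullseye",
]


def territory_of(segment_id: int) -> str:
    """Vessel ("LAD"/"LCx"/"RCA") perfusing ``segment_id`` (1–18)."""
    if not (1 <= segment_id <= N_SEGMENTS):
        raise ValueError(f"segment_id must be in 1..18, got {segment_id}")
    return _SEGMENT_TO_VESSEL[segment_id]


def is_impaired(gls: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """True when a signed strain value fails the cutoff.

    Impairment means the magnitude of shortening falls *below* the cutoff
    magnitude: signed ``gls`` strictly greater than ``cutoff``.  Exactly
    −15.0 is therefore NOT impaired.  NaN (missing, when permitted) counts
    as not impaired, the conservative direction for pattern positivity.
    """
    return bool(gls > cutoff)


def adjacent(s1: int, s2: int) -> bool:
    """Polar-map adjacency of two segments.

    Same ring and circumferential neighbours (positions differing by 1 mod
    6 within rings {1–6}, {7–12}, {13–18}), or radial neighbours (ids
    differing by exactly 6).
    """
    for s in (s1, s2):
        if not (1 <= s <= N_SEGMENTS):
            raise ValueError(f"segment id must be in 1..18, got {s}")
    if s1 == s2:
        return False
    ring1, pos1 = divmod(s1 - 1, 6)
    ring2, pos2 = divmod(s2 - 1, 6)
    if ring1 == ring2:
        return (pos1 - pos2) % 6 in (1, 5)
    return abs(s1 - s2) == 6


@dataclass(frozen=True)
class PatternConfig:
    """Tunables of the ischemic-pattern rule.

    cutoff: signed strain cutoff in percent (default −15).
    min_cluster: minimum size of a connected impaired cluster
        ("more than two consecutive segments" = 3).
    adjacency_mode: "polar_graph" (2-D adjacency on the bull's-eye) or
        "index_run" (runs of consecutive ids within a territory's sorted
        segment list).
    allow_missing: number of NaN segments tolerated per map; missing
        segments count as non-impaired.
    """

    cutoff: float = DEFAULT_CUTOFF
    min_cluster: int = 3
    adjacency_mode: Literal["polar_graph", "index_run"] = "polar_graph"
    allow_missing: int = 0

    def __post_init__(self) -> None:
        if not self.cutoff < 0:
            raise ValueError("cutoff must be negative in the signed convention")
        if self.min_cluster < 1:
            raise ValueError("min_cluster must be >= 1")
        if self.adjacency_mode not in ("polar_graph", "index_run"):
            raise ValueError(f"unknown adjacency_mode {self.adjacency_mode!r}")
        if self.allow_missing < 0:
            raise ValueError("allow_missing must be >= 0")


@dataclass(frozen=True)
class PatternResult:
    """Per-territory and overall ischemic-pattern flags."""

    per_territory: Mapping[str, bool] = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return any(self.per_territory.values())

    @property
    def lad(self) -> bool:
        return self.per_territory["LAD"]

    @property
    def lcx(self) -> bool:
        return self.per_territory["LCx"]

    @property
    def rca(self) -> bool:
        return self.per_territory["RCA"]

    def to_dict(self) -> Dict[str, bool]:
        return {"lad": self.lad, "lcx": self.lcx, "rca": self.rca,
                "overall": self.overall}


@lru_cache(maxsize=None)
def _cluster_index_sets(vessel: str, k: int, mode: str) -> Tuple[Tuple[int, ...], ...]:
    """All minimal clusters of size k within a territory, as 0-based index
    tuples into the 18-vector.

    polar_graph: connected k-subsets of the territory subgraph.  A connected
    impaired set of size >= k exists iff one of these is fully impaired
    (prune leaves of a spanning tree to see any connected set contains
    connected subsets of every smaller size).
    index_run: k consecutive positions in the sorted segment list.
    """
    segs = TERRITORIES[vessel]
    if mode == "index_run":
        ordered = sorted(segs)
        return tuple(
            tuple(s - 1 for s in ordered[i:i + k])
            for i in range(len(ordered) - k + 1)
        )
    out = []
    for subset in combinations(segs, k):
        # connectivity by BFS over the subset
        todo, seen = [subset[0]], {subset[0]}
        while todo:
            cur = todo.pop()
            for other in subset:
                if other not in seen and adjacent(cur, other):
                    seen.add(other)
                    todo.append(other)
        if len(seen) == k:
            out.append(tuple(s - 1 for s in subset))
    return tuple(out)


def _check_missing(values: np.ndarray, allow_missing: int) -> None:
    n_missing = int(np.isnan(values).sum()) if values.ndim == 1 else None
    if values.ndim == 1:
        if n_missing > allow_missing:
            raise ValueError(f"{n_missing} missing segment(s), allowed {allow_missing}")
    else:
        per_row = np.isnan(values).sum(axis=1)
        bad = np.nonzero(per_row > allow_missing)[0]
        if bad.size:
            raise ValueError(
                f"{bad.size} map(s) exceed the missing-segment allowance "
                f"({allow_missing}); first offending row index {bad[0]}"
            )


def detect_pattern(
    strain_map: StrainMap,
    config: PatternConfig | None = None,
    territories: Mapping[str, Tuple[int, ...]] = TERRITORIES,
) -> PatternResult:
    """Classify one strain map with the ischemic bull's-eye rule.

    For each territory the flag is true iff a connected set (under the
    configured adjacency, restricted to the territory's segments) of at
    least ``min_cluster`` impaired segments exists; ``overall`` is the OR
    over territories.
    """
    config = config or PatternConfig()
    strain_map = normalize_sign(strain_map)
    values = strain_map.values
    _check_missing(values, config.allow_missing)

    flags: Dict[str, bool] = {}
    for vessel, segs in territories.items():
        impaired = [s for s in segs if is_impaired(values[s - 1], config.cutoff)]
        if config.adjacency_mode == "index_run":
            ordered = sorted(segs)
            run = best = 0
            for s in ordered:
                run = run + 1 if s in impaired else 0
                best = max(best, run)
            flags[vessel] = best >= config.min_cluster
        else:
            # connected components of the impaired territory subgraph
            remaining = set(impaired)
            best = 0
            while remaining:
                todo = [remaining.pop()]
                size = 1
                while todo:
                    cur = todo.pop()
                    nbrs = [s for s in remaining if adjacent(cur, s)]
                    for s in nbrs:
                        remaining.remove(s)
                        todo.append(s)
                    size += len(nbrs)
                best = max(best, size)
            flags[vessel] = best >= config.min_cluster
    return PatternResult(per_territory=flags)


def detect_pattern_batch(
    values: np.ndarray,
    config: PatternConfig | None = None,
) -> Dict[str, np.ndarray]:
    """Vectorized pattern classification of ``n`` maps at once.

    ``values`` is an (n, 18) signed-strain array.  Returns boolean arrays
    under keys "LAD", "LCx", "RCA" and "overall".  Row-for-row identical to
    :func:`detect_pattern` (the flag is true iff some minimal cluster of
    ``min_cluster`` segments is fully impaired).
    """
    config = config or PatternConfig()
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != N_SEGMENTS:
        raise ValueError(f"expected (n, {N_SEGMENTS}) array, got {values.shape}")
    _check_missing(values, config.allow_missing)

    with np.errstate(invalid="ignore"):
        impaired = values > config.cutoff  # NaN compares false
    out: Dict[str, np.ndarray] = {}
    overall = np.zeros(values.shape[0], dtype=bool)
    for vessel in VESSELS:
        clusters = _cluster_index_sets(vessel, config.min_cluster,
                                       config.adjacency_mode)
        flag = np.zeros(values.shape[0], dtype=bool)
        for idx in clusters:
            flag |= impaired[:, list(idx)].all(axis=1)
        out[vessel] = flag
        overall |= flag
    out["overall"] = overall
    return out


# ---------------------------------------------------------------------------
# optional report plot

_RING_SEGMENTS = ((1, 2, 3, 4, 5, 6), (7, 8, 9, 10, 11, 12), (13, 14, 15, 16, 17, 18))


def plot_bullseye(strain_map: StrainMap, config: PatternConfig | None = None,
                  ax=None, cmap: str = "RdYlGn_r"):
    """Polar bull's-eye plot of one strain map; impaired segments outlined.

    The angular layout is cosmetic (it does not affect classification):
    each ring's six segments occupy equal 60-degree sectors in id order.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    config = config or PatternConfig()
    strain_map = normalize_sign(strain_map)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    vmin, vmax = -25.0, 0.0
    cm = plt.get_cmap(cmap)
    for ring, segs in enumerate(_RING_SEGMENTS):
        r0, r1 = 1.0 - (ring + 1) / 3.0, 1.0 - ring / 3.0
        for j, seg in enumerate(segs):
            theta = np.linspace(j * np.pi / 3, (j + 1) * np.pi / 3, 16)
            val = strain_map[seg]
            color = cm((np.clip(val, vmin, vmax) - vmin) / (vmax - vmin)) \
                if np.isfinite(val) else (0.8, 0.8, 0.8)
            ax.fill_between(theta, r0, r1, color=color,
                            edgecolor="crimson" if is_impaired(val, config.cutoff)
                            else "black",
                            linewidth=1.5 if is_impaired(val, config.cutoff) else 0.5)
            ax.text((j + 0.5) * np.pi / 3, (r0 + r1) / 2, str(seg),
                    ha="center", va="center", fontsize=7)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
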