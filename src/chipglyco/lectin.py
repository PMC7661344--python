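"""Lectin-microarray normalization and differential glycan calling.

The protocol implemented here follows the standard glycomics workflow for
spotted lectin arrays: per-scope averaged-background subtraction, a validity
cut at background mean + k·SD (k = 2 by default), per-block global-median
normalization (each lectin's median of effective spots divided by the sum
of all lectin medians in that block, giving the normalized fluorescence
intensity, NFI), aggregation over the nine replicate blocks of a
three-slide design, and differential calling by NFI fold change plus a
paired two-sided t-test across blocks.

Two fold-change tiers are first-class:

* ``STRICT``  -- up at fold >= 2.0, down at fold <= 0.5
* ``REPORTED`` -- up at fold > 1.5, down at fold < 0.67

The validity rule is the conventional reading of "values less than the
average background +/- 2 SD were removed": a spot is effective iff its raw
foreground reaches mean(background) + k * SD(background) over its scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy import stats

Scope = Literal["block", "slide"]


@dataclass(frozen=True)
class SpotMeasurement:
    """One scanned array spot: foreground and local background intensity (a.u.)."""

    slide_id: str
    block_id: str
    lectin_id: str
    foreground: float
    background: float
    corrected: float | None = None
    effective: bool | None = None

    def __post_init__(self) -> None:
        if self.foreground < 0 or self.background < 0:
            raise ValueError("spot intensities must be non-negative")


@dataclass(frozen=True)
class BlockProfile:
    """Per-lectin normalized medians for one (slide, block)."""

    slide_id: str
    block_id: str
    medians: dict[str, float]
    normalized: dict[str, float]


@dataclass(frozen=True)
class LectinSummary:
    lectin_id: str
    condition: str
    mean_nfi: float
    sd_nfi: float
    n_blocks: int


@dataclass(frozen=True)
class DifferentialGlycanCall:
    lectin_id: str
    fold_change: float
    p_value: float
    call: Literal["UP", "DOWN", "UNCHANGED"]
    tier: Literal["STRICT", "REPORTED"]


TIERS: dict[str, tuple[float, float, bool]] = {
    # (up threshold, down threshold, inclusive comparison)
    "STRICT": (2.0, 0.5, True),
    "REPORTED": (1.5, 0.67, False),
}


def _scope_key(spot: SpotMeasurement, scope: Scope) -> tuple:
    return (spot.slide_id, spot.block_id) if scope == "block" else (spot.slide_id,)


def _background_stats(
    spots: list[SpotMeasurement], scope: Scope
) -> dict[tuple, tuple[float, float]]:
    groups: dict[tuple, list[float]] = {}
    for s in spots:
        groups.setdefault(_scope_key(s, scope), []).append(s.background)
    out = {}
    for key, vals in groups.items():
        mean = float(np.mean(vals))
        if len(vals) < 2:
            warnings.warn(
                f"background SD undefined for scope unit {key}; treated as 0",
                stacklevel=2,
            )
            sd = 0.0
        else:
            sd = float(np.std(vals, ddof=1))
        out[key] = (mean, sd)
    return out


def subtract_background(
    spots: list[SpotMeasurement], scope: Scope = "block"
) -> list[SpotMeasurement]:
    """Subtract the scope-averaged background from each foreground.

    Corrected values may be negative at this stage; the validity filter
    downstream decides which spots survive.
    """
    if not spots:
        raise ValueError("no spots to correct")
    bg = _background_stats(spots, scope)
    return [
        replace(s, corrected=s.foreground - bg[_scope_key(s, scope)][0]) for s in spots
    ]


def flag_effective(
    spots: list[SpotMeasurement], k: float = 2.0, scope: Scope = "block"
) -> list[SpotMeasurement]:
    """Flag spots whose raw foreground reaches mean_bg + k * sd_bg.

    Ineffective spots stay in the list (flagged False) so the caller can
    report removal rates; downstream normalization ignores them.
    """
    if not spots:
        raise ValueError("no spots to flag")
    bg = _background_stats(spots, scope)
    out = []
    for s in spots:
        mean, sd = bg[_scope_key(s, scope)]
        corrected = s.corrected if s.corrected is not None else s.foreground - mean
        out.append(replace(s, corrected=corrected, effective=s.foreground >= mean + k * sd))
    return out


def normalize_block(spots: list[SpotMeasurement]) -> BlockProfile | None:
    """Per-lectin median of effective spots, globally normalized so the
    medians of one block sum to 1 (the per-block NFI).

    Returns None for a block with zero effective spots (the block is
    dropped, with a warning carrying the reason).
    """
    if not spots:
        raise ValueError("empty block")
    keys = {(s.slide_id, s.block_id) for s in spots}
    if len(keys) != 1:
        raise ValueError(f"normalize_block got spots from multiple blocks: {keys}")
    slide_id, block_id = next(iter(keys))
    by_lectin: dict[str, list[float]] = {}
    for s in spots:
        if s.effective:
            if s.corrected is None:
                raise ValueError("spots must be background-corrected before normalization")
            by_lectin.setdefault(s.lectin_id, []).append(s.corrected)
    if not by_lectin:
        warnings.warn(
            f"block ({slide_id}, {block_id}) dropped: zero effective spots",
            stacklevel=2,
        )
        return None
    medians = {lec: float(np.median(v)) for lec, v in by_lectin.items()}
    total = sum(medians.values())
    if total == 0:
        warnings.warn(
            f"block ({slide_id}, {block_id}) dropped: zero median sum", stacklevel=2
        )
        return None
    normalized = {lec: m / total for lec, m in medians.items()}
    return BlockProfile(slide_id, block_id, medians, normalized)


def process_condition(
    spots: list[SpotMeasurement], k: float = 2.0, scope: Scope = "block"
) -> list[BlockProfile]:
    """Background-correct, validity-filter, and normalize every block."""
    flagged = flag_effective(subtract_background(spots, scope), k=k, scope=scope)
    by_block: dict[tuple[str, str], list[SpotMeasurement]] = {}
    for s in flagged:
        by_block.setdefault((s.slide_id, s.block_id), []).append(s)
    profiles = []
    for key in sorted(by_block):
        prof = normalize_block(by_block[key])
        if prof is not None:
            profiles.append(prof)
    return profiles


def aggregate(profiles: list[BlockProfile], condition: str = "") -> list[LectinSummary]:
    """Mean and SD of the per-block NFI for each lectin across blocks."""
    if len(profiles) < 2:
        raise ValueError("need at least two blocks for an SD")
    values: dict[str, list[float]] = {}
    for prof in profiles:
        for lec, v in prof.normalized.items():
            values.setdefault(lec, []).append(v)
    out = []
    for lec in sorted(values):
        vals = values[lec]
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        out.append(
            LectinSummary(
                lectin_id=lec,
                condition=condition,
                mean_nfi=float(np.mean(vals)),
                sd_nfi=sd,
                n_blocks=len(vals),
            )
        )
    return out


def differential_call(
    control_profiles: list[BlockProfile],
    treatment_profiles: list[BlockProfile],
    tiers: tuple[str, ...] = ("STRICT", "REPORTED"),
    alpha: float = 0.05,
) -> list[DifferentialGlycanCall]:
    """Call UP/DOWN/UNCHANGED lectins between two conditions.

    Fold change is mean treatment NFI over mean control NFI; significance is
    a two-sided paired t-test over blocks matched by (slide, block) index.
    A lectin is UP (or DOWN) only when both the tier's fold criterion and
    p < alpha hold. One call per requested tier per lectin. Lectins whose
    control mean is zero are skipped (fold undefined).
    """
    ctl = {(p.slide_id, p.block_id): p for p in control_profiles}
    trt = {(p.slide_id, p.block_id): p for p in treatment_profiles}
    shared_blocks = sorted(set(ctl) & set(trt))
    if len(shared_blocks) < 2:
        raise ValueError("need at least two paired blocks for the paired t-test")

    lectins = sorted(
        set().union(*(p.normalized for p in control_profiles))
        & set().union(*(p.normalized for p in treatment_profiles))
    )
    calls: list[DifferentialGlycanCall] = []
    for lec in lectins:
        pairs = [
            (ctl[b].normalized[lec], trt[b].normalized[lec])
            for b in shared_blocks
            if lec in ctl[b].normalized and lec in trt[b].normalized
        ]
        if len(pairs) < 2:
            continue
        c = np.array([p[0] for p in pairs])
        t = np.array([p[1] for p in pairs])
        mean_c, mean_t = float(c.mean()), float(t.mean())
        if mean_c == 0:
            warnings.warn(f"{lec}: control mean NFI is 0; fold undefined", stacklevel=2)
            continue
        fold = mean_t / mean_c
        if np.allclose(t - c, 0):
            p_value = 1.0  # no paired difference at all
        else:
            with warnings.catch_warnings():
                # zero-variance paired differences trip a scipy precision
                # warning; the resulting p (0 or nan) is handled below
                warnings.simplefilter("ignore", RuntimeWarning)
                p_value = float(stats.ttest_rel(t, c).pvalue)
            if math.isnan(p_value):
                p_value = 1.0
        for tier in tiers:
            up, down, inclusive = TIERS[tier]
            if inclusive:
                is_up, is_down = fold >= up, fold <= down
            else:
                is_up, is_down = fold > up, fold < down
            if is_up and p_value < alpha:
                call = "UP"
            elif is_down and p_value < alpha:
                call = "DOWN"
            else:
                call = "UNCHANGED"
            calls.append(
                DifferentialGlycanCall(
                    lectin_id=lec,
                    fold_change=fold,
                    p_value=p_value,
                    call=call,  # type: ignore[arg-type]
                    tier=tier,  # type: ignore[arg-type]
                )
            )
    return calls
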