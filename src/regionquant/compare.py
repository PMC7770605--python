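"""Downstream statistics: validity, reliability, cross-species, ratios, gradients.

All percent differences use the reference (manual) count as the
denominator: pct = 100·(test − ref)/ref, reported both as a real and as a
half-up rounded integer for display. Cross-species comparisons recompute
densities at the mapped-target level from summed totals over summed
volumes (volume-weighted), never by averaging densities. Dorsoventral
gradients are classified by Spearman rank correlation between section
order and per-section density, so the classification is invariant to any
strictly monotone transform of the densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .atlas import CrossAtlasMapping
from .quantify import RegionEstimate, round_half_up


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    count_ref: int
    count_test: int
    pct_diff: float
    pct_diff_rounded: int


@dataclass(frozen=True)
class CrossSpeciesRow:
    target: str
    density_a: float | None
    density_b: float | None
    ratio: float | None
    pct_lower_a_vs_b: float | None
    status: str = "ok"


@dataclass(frozen=True)
class GradientProfile:
    label: str
    samples: tuple[tuple[float, float], ...]  # (axis_coord_mm, density) dorsal→ventral
    spearman_rho: float | None
    classification: str  # decreasing | increasing | none | insufficient data


def percent_difference(count_ref: float, count_test: float) -> tuple[float, int]:
    """Percent difference of a test count relative to a reference count.

    Returns the real value and its half-up rounded integer; negative means
    the test count is lower.
    """
    if count_ref <= 0:
        raise ValueError("reference count must be > 0")
    pct = 100.0 * (count_test - count_ref) / count_ref
    return pct, round_half_up(pct)


def validity_table(
    manual: Mapping[str, int], automated: Mapping[str, int]
) -> list[ComparisonRow]:
    """Compare automated against manual counts group by group.

    Emits one row per group plus an ``ALL`` row over the summed counts.
    """
    if set(manual) != set(automated):
        raise ValueError(
            f"group sets differ: {sorted(set(manual) ^ set(automated))}"
        )
    rows = []
    for label in manual:
        pct, rounded = percent_difference(manual[label], automated[label])
        rows.append(
            ComparisonRow(
                label=label,
                count_ref=manual[label],
                count_test=automated[label],
                pct_diff=pct,
                pct_diff_rounded=rounded,
            )
        )
    total_ref, total_test = sum(manual.values()), sum(automated.values())
    pct, rounded = percent_difference(total_ref, total_test)
    rows.append(ComparisonRow("ALL", total_ref, total_test, pct, rounded))
    return rows


@dataclass(frozen=True)
class ReliabilityResult:
    """Absolute percent differences of each rater against the reference.

    ``per_rater_group`` maps (rater index, group) → |pct diff|. The summary
    ranges are reported at three granularities because a min–max spread can
    be taken over raters, over groups, or over both.
    """

    per_rater_group: dict[tuple[int, str], float]
    overall_range: tuple[float, float]
    per_rater_range: dict[int, tuple[float, float]]
    per_group_range: dict[str, tuple[float, float]]


def rater_reliability(
    tables: Sequence[Mapping[str, int]], reference_index: int = 0
) -> ReliabilityResult:
    """Inter-rater agreement of count tables against one reference rater.

    Each non-reference table is compared group by group with the reference
    by absolute percent difference; summaries give the (min, max) range
    over everything, per rater, and per group.
    """
    if len(tables) < 2:
        raise ValueError("need at least two rater tables")
    groups = set(tables[reference_index])
    for i, t in enumerate(tables):
        if set(t) != groups:
            raise ValueError(f"rater {i} has a different group set")
    ref = tables[reference_index]
    per: dict[tuple[int, str], float] = {}
    for i, t in enumerate(tables):
        if i == reference_index:
            continue
        for g in groups:
            pct, _ = percent_difference(ref[g], t[g])
            per[(i, g)] = abs(pct)
    all_vals = list(per.values())
    per_rater = {
        i: (
            min(v for (r, _), v in per.items() if r == i),
            max(v for (r, _), v in per.items() if r == i),
        )
        for i in {r for r, _ in per}
    }
    per_group = {
        g: (
            min(v for (_, gg), v in per.items() if gg == g),
            max(v for (_, gg), v in per.items() if gg == g),
        )
        for g in groups
    }
    return ReliabilityResult(
        per_rater_group=per,
        overall_range=(min(all_vals), max(all_vals)),
        per_rater_range=per_rater,
        per_group_range=per_group,
    )


def cell_type_fraction(total_a: float, total_b: float) -> float:
    """Fraction of cell type a among a + b, for per-region ratio charts."""
    if total_a < 0 or total_b < 0:
        raise ValueError("totals must be >= 0")
    s = total_a + total_b
    if s == 0:
        raise ValueError("a + b must be > 0")
    return total_a / s


def cross_species_table(
    estimates_a: Mapping[int, RegionEstimate],
    estimates_b: Mapping[int, RegionEstimate],
    mapping: CrossAtlasMapping,
) -> list[CrossSpeciesRow]:
    """Compare densities between two atlases at the mapped-target level.

    For each mapping row, the target density in each atlas is recomputed as
    Σ totals / Σ volumes over the listed source regions (volume-weighted),
    then compared: ``pct_lower_a_vs_b`` = 100·(1 − ρ_a/ρ_b), positive when
    atlas A is sparser. Rows with missing source regions carry a reason
    code instead of numbers.
    """
    rows: list[CrossSpeciesRow] = []
    for target, ids_a, ids_b in mapping.rows:
        missing_a = [i for i in ids_a if i not in estimates_a]
        missing_b = [i for i in ids_b if i not in estimates_b]
        if missing_a or missing_b:
            rows.append(
                CrossSpeciesRow(
                    target=target,
                    density_a=None,
                    density_b=None,
                    ratio=None,
                    pct_lower_a_vs_b=None,
                    status=f"missing regions A{missing_a} B{missing_b}",
                )
            )
            continue

        def pooled_density(ests, ids):
            total = sum(ests[i].total_estimate or 0 for i in ids)
            vol = sum(ests[i].volume_mm3 or 0.0 for i in ids)
            return total / vol if vol > 0 else None

        da = pooled_density(estimates_a, ids_a)
        db = pooled_density(estimates_b, ids_b)
        if da is None or db is None or db == 0:
            rows.append(
                CrossSpeciesRow(target, da, db, None, None, status="undefined density")
            )
            continue
        rows.append(
            CrossSpeciesRow(
                target=target,
                density_a=da,
                density_b=db,
                ratio=da / db,
                pct_lower_a_vs_b=100.0 * (1.0 - da / db),
            )
        )
    return rows


def per_section_density(
    n_profiles: int, region_area_px: int, pixel_size_um: float, thickness_um: float
) -> float:
    """Profiles per mm³ of one section's region slab: n / (area · T)."""
    if region_area_px <= 0:
        raise ValueError("region_area_px must be > 0")
    vol_mm3 = region_area_px * (pixel_size_um / 1000.0) ** 2 * (thickness_um / 1000.0)
    return n_profiles / vol_mm3


def gradient_profile(
    label: str,
    samples: Sequence[tuple[float, float]],
    min_sections: int = 4,
    rho_threshold: float = 0.5,
) -> GradientProfile:
    """Classify the dorsoventral trend of per-section densities.

    ``samples`` are (axis_coord_mm, density) pairs; sections are ordered by
    descending axis coordinate (dorsal first) and the Spearman rank
    correlation between that order and density is computed. rho ≤ −threshold
    classifies as ``decreasing`` (density falls toward ventral), rho ≥
    +threshold as ``increasing``, otherwise ``none``. Fewer than
    ``min_sections`` samples yields an ``insufficient data`` result.
    """
    ordered = tuple(sorted(samples, key=lambda t: -t[0]))
    if len(ordered) < min_sections:
        return GradientProfile(label, ordered, None, "insufficient data")
    densities = [d for _, d in ordered]
    if len(set(densities)) == 1:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(np.arange(len(densities)), densities).statistic)
        if math.isnan(rho):
            rho = 0.0
    if rho <= -rho_threshold:
        cls = "decreasing"
    elif rho >= rho_threshold:
        cls = "increasing"
    else:
        cls = "none"
    return GradientProfile(label, ordered, rho, cls)
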