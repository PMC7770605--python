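"""Profile counts → corrected totals and atlas-volume densities.

Profile counts from 2D sections overestimate cell numbers because
sectioning splits cells across adjacent sections. Abercrombie's correction

    N = n · T / (T + D)

converts a profile count n into an estimated cell number using section
thickness T and mean cell diameter D (both in µm). When only every k-th
section is analyzed, the corrected count is multiplied by the sampling
interval k to represent the whole series, and rounded half-up to an
integer total. Densities divide the total by the region volume taken from
the three-dimensional reference atlas (never by section-derived areas).

The correction order — sum raw profiles over sampled sections, correct,
multiply by k, round once — keeps rounding error from accumulating across
sections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .atlas import UNGROUPED, AtlasSection, RegionOntology
from .extraction import DetectedObject

UNASSIGNED = "UNASSIGNED"
STATUS_OK = "ok"
STATUS_OVERSATURATED = "not reported (oversaturated)"
STATUS_NO_VOLUME = "density omitted (no volume)"


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (2.5 → 3, −2.5 → −3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class QuantParams:
    """Correction and extrapolation parameters.

    T_um : section thickness in µm.
    D_um : mean cell diameter in µm for the stained population.
    k : section sampling interval (every k-th section analyzed).
    """

    T_um: float = 40.0
    D_um: float = 15.0
    k: int = 6

    def __post_init__(self) -> None:
        if self.T_um <= 0:
            raise ValueError("T_um must be > 0")
        if self.D_um < 0:
            raise ValueError("D_um must be >= 0")
        if self.k < 1 or int(self.k) != self.k:
            raise ValueError("k must be an integer >= 1")


@dataclass(frozen=True)
class SectionRegionCount:
    """Non-excluded profile count for one region/group in one section."""

    section_index: int
    label: str | int
    n_profiles: int
    region_area_px: int = 0

    def __post_init__(self) -> None:
        if self.n_profiles < 0:
            raise ValueError("n_profiles must be >= 0")


@dataclass
class RegionEstimate:
    """Whole-region estimate for one region or custom group."""

    label: str | int
    n_raw: int
    n_corrected: float | None
    total_estimate: int | None
    volume_mm3: float | None
    density_per_mm3: float | None
    scope: str = "unilateral"
    status: str = STATUS_OK


def abercrombie(n: float, T_um: float, D_um: float) -> float:
    """Corrected cell count N = n·T/(T+D).

    Monotone increasing in n and T, decreasing in D; the D = 0 limit is the
    identity (point-like cells are never split).
    """
    if T_um <= 0:
        raise ValueError("T_um must be > 0")
    if D_um < 0:
        raise ValueError("D_um must be >= 0")
    if n < 0:
        raise ValueError("profile count must be >= 0")
    return n * T_um / (T_um + D_um)


def count_profiles(
    objects_per_section: Mapping[int, Sequence[DetectedObject]],
    grouping: Mapping[int, str] | None = None,
    sections: Sequence[AtlasSection] | None = None,
) -> list[SectionRegionCount]:
    """Tally non-excluded objects per section per group.

    ``grouping`` is a resolved leaf → group map; without it, counts are per
    leaf region id. Objects assigned to label 0 are tallied under
    ``UNASSIGNED`` and never added to any region, so group counts plus the
    unassigned count always conserve the total. ``sections``, if given,
    supply per-group pixel areas (for per-section densities).
    """
    areas: dict[tuple[int, str | int], int] = {}
    if sections is not None:
        import numpy as np

        for sec in sections:
            ids, counts = np.unique(sec.labels, return_counts=True)
            for rid, cnt in zip(ids.tolist(), counts.tolist()):
                if rid == 0:
                    continue
                lab = grouping.get(rid, UNGROUPED) if grouping is not None else rid
                key = (sec.section_index, lab)
                areas[key] = areas.get(key, 0) + int(cnt)

    tallies: dict[tuple[int, str | int], int] = {}
    for section_index, objects in objects_per_section.items():
        for o in objects:
            if o.excluded:
                continue
            if o.region_id == 0:
                lab: str | int = UNASSIGNED
            elif grouping is not None:
                lab = grouping.get(o.region_id, UNGROUPED)
            else:
                lab = o.region_id
            key = (section_index, lab)
            tallies[key] = tallies.get(key, 0) + 1

    keys = set(tallies) | set(areas)
    return [
        SectionRegionCount(
            section_index=s,
            label=lab,
            n_profiles=tallies.get((s, lab), 0),
            region_area_px=areas.get((s, lab), 0),
        )
        for s, lab in sorted(keys, key=lambda t: (t[0], str(t[1])))
    ]


def estimate_region(
    counts: Sequence[SectionRegionCount],
    params: QuantParams,
    volumes: Mapping[str | int, float] | None = None,
    oversaturated: Mapping[str | int, bool] | None = None,
    scope: str = "unilateral",
) -> list[RegionEstimate]:
    """Aggregate section counts into whole-region totals and densities.

    Per region: n_raw = Σ profiles over sampled sections;
    total = round_half_up(k · n_raw · T/(T+D)); density = total / V when a
    volume is available. Regions flagged oversaturated are emitted with all
    numbers suppressed and a reason code; a missing volume omits only the
    density.
    """
    volumes = volumes or {}
    oversaturated = oversaturated or {}
    n_raw: dict[str | int, int] = {}
    for c in counts:
        n_raw[c.label] = n_raw.get(c.label, 0) + c.n_profiles

    estimates: list[RegionEstimate] = []
    for label in sorted(n_raw, key=str):
        if oversaturated.get(label, False):
            estimates.append(
                RegionEstimate(
                    label=label,
                    n_raw=n_raw[label],
                    n_corrected=None,
                    total_estimate=None,
                    volume_mm3=volumes.get(label),
                    density_per_mm3=None,
                    scope=scope,
                    status=STATUS_OVERSATURATED,
                )
            )
            continue
        corrected = abercrombie(n_raw[label], params.T_um, params.D_um)
        total = round_half_up(params.k * corrected)
        vol = volumes.get(label)
        if vol is not None and vol > 0:
            density = total / vol
            status = STATUS_OK
        else:
            density = None
            vol = vol if vol is not None else None
            status = STATUS_NO_VOLUME if label != UNASSIGNED else STATUS_OK
        estimates.append(
            RegionEstimate(
                label=label,
                n_raw=n_raw[label],
                n_corrected=corrected,
                total_estimate=total,
                volume_mm3=vol,
                density_per_mm3=density,
                scope=scope,
                status=status,
            )
        )
    return estimates


def bilateral_merge(
    left: RegionEstimate,
    right: RegionEstimate,
    bilateral_volume_mm3: float | None = None,
) -> RegionEstimate:
    """Merge two unilateral estimates of the same region into a bilateral one.

    Raw, corrected and total counts add; the density is recomputed from the
    bilateral volume (defaulting to the volume already attached, which the
    reference atlas reports bilaterally).
    """
    if left.label != right.label:
        raise ValueError(f"label mismatch: {left.label!r} vs {right.label!r}")
    if left.scope != "unilateral" or right.scope != "unilateral":
        raise ValueError("bilateral_merge requires two unilateral estimates")
    vol = bilateral_volume_mm3
    if vol is None:
        vol = left.volume_mm3 if left.volume_mm3 is not None else right.volume_mm3
    n_corrected = None
    if left.n_corrected is not None and right.n_corrected is not None:
        n_corrected = left.n_corrected + right.n_corrected
    total = None
    if left.total_estimate is not None and right.total_estimate is not None:
        total = left.total_estimate + right.total_estimate
    density = total / vol if (total is not None and vol and vol > 0) else None
    status = STATUS_OK
    if left.status != STATUS_OK or right.status != STATUS_OK:
        status = left.status if left.status != STATUS_OK else right.status
    return RegionEstimate(
        label=left.label,
        n_raw=left.n_raw + right.n_raw,
        n_corrected=n_corrected,
        total_estimate=total,
        volume_mm3=vol,
        density_per_mm3=density,
        scope="bilateral",
        status=status,
    )


def exclude_flagged(
    estimates: Sequence[RegionEstimate], ontology: RegionOntology
) -> list[RegionEstimate]:
    """Suppress estimates for oversaturated regions.

    A region counts as flagged if its own node or any ancestor node is
    marked oversaturated, so flagging a parent suppresses every member leaf
    in a leaf-level report. Suppressed rows stay in the output with status
    ``not reported (oversaturated)`` and no numbers.
    """
    flagged_labels: set[str | int] = set()
    for node in ontology.nodes:
        if node.oversaturated:
            for leaf in ontology.descendant_leaves(node.region_id):
                flagged_labels.add(leaf)
                flagged_labels.add(ontology[leaf].acronym)
            flagged_labels.add(node.region_id)
            flagged_labels.add(node.acronym)

    out: list[RegionEstimate] = []
    for est in estimates:
        if est.label in flagged_labels:
            out.append(
                replace(
                    est,
                    n_corrected=None,
                    total_estimate=None,
                    density_per_mm3=None,
                    status=STATUS_OVERSATURATED,
                )
            )
        else:
            out.append(replace(est))
    return out
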