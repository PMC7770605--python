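"""Connected-component extraction, region assignment, and manual exclusion.

Each foreground component of a binary segmentation mask becomes one
:class:`DetectedObject`. Every object is assigned to exactly one atlas
region — the region covering the majority of its pixels — mirroring a
quantifier run with object splitting switched off, so cells straddling a
region boundary are never double-counted. A post-hoc exclusion step flags
erroneously segmented objects (clutter) so they never enter counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .atlas import AtlasSection

STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ExtractionParams:
    """Component labeling settings.

    connectivity 8 merges diagonal pixel chains into one object;
    ``min_size_px`` suppresses speckle below that pixel count.
    """

    connectivity: int = 8
    min_size_px: int = 4

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_size_px < 0:
            raise ValueError("min_size_px must be >= 0")


@dataclass
class DetectedObject:
    """One connected foreground component of a section mask."""

    object_id: int
    pixel_count: int
    centroid: tuple[float, float]
    region_id: int = 0
    hemisphere: str = "none"
    excluded: bool = False
    pixels: np.ndarray | None = field(default=None, repr=False, compare=False)


def _as_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return mask
    vals = set(np.unique(mask).tolist())
    if vals <= {0, 1} or vals <= {0, 255}:
        return mask > 0
    raise ValueError(f"mask is not binary: values {sorted(vals)[:10]}")


def extract_objects(
    mask: np.ndarray, params: ExtractionParams = ExtractionParams()
) -> list[DetectedObject]:
    """Label maximal connected foreground components of a binary mask.

    Components smaller than ``min_size_px`` are dropped. Object ids are
    assigned 0, 1, ... in the order each component's first pixel is met in
    a row-major scan.
    """
    binary = _as_binary(mask)
    struct = STRUCT_4 if params.connectivity == 4 else STRUCT_8
    labeled, n = ndimage.label(binary, structure=struct)
    if n == 0:
        return []
    flat = labeled.ravel()
    fg = np.flatnonzero(flat)
    # first row-major occurrence of each label determines scan order
    order = {}
    for idx in fg:
        lab = flat[idx]
        if lab not in order:
            order[lab] = idx
            if len(order) == n:
                break
    sizes = ndimage.sum_labels(binary, labeled, index=np.arange(1, n + 1))
    objects: list[DetectedObject] = []
    next_id = 0
    for lab in sorted(order, key=order.get):
        size = int(sizes[lab - 1])
        if size < params.min_size_px:
            continue
        pix = np.argwhere(labeled == lab)
        centroid = (float(pix[:, 0].mean()), float(pix[:, 1].mean()))
        objects.append(
            DetectedObject(
                object_id=next_id,
                pixel_count=size,
                centroid=centroid,
                pixels=pix,
            )
        )
        next_id += 1
    return objects


def _majority(values: np.ndarray, zero_is_fallback: bool) -> int:
    vals, counts = np.unique(values, return_counts=True)
    if zero_is_fallback:
        nz = vals != 0
        if nz.any():
            vals, counts = vals[nz], counts[nz]
    best = counts.max()
    # tie -> lowest id; np.unique returns vals sorted ascending
    return int(vals[counts == best][0])


def assign_region(obj: DetectedObject, section: AtlasSection) -> DetectedObject:
    """Assign the object to the single region covering most of its pixels.

    Label 0 (outside atlas) wins only when no nonzero label overlaps the
    object; ties break to the lowest region id. Hemisphere, if the section
    carries a hemisphere mask, is assigned by the same majority rule.
    """
    if obj.pixels is None:
        raise ValueError("object carries no pixel coordinates")
    rows, cols = obj.pixels[:, 0], obj.pixels[:, 1]
    region_id = _majority(section.labels[rows, cols], zero_is_fallback=True)
    hemisphere = "none"
    if section.hemisphere is not None:
        code = _majority(section.hemisphere[rows, cols], zero_is_fallback=True)
        hemisphere = {0: "none", 1: "left", 2: "right"}[code]
    return replace(obj, region_id=region_id, hemisphere=hemisphere)


def apply_exclusions(
    objects: Sequence[DetectedObject],
    registry: Iterable[tuple[float, float]] | np.ndarray | None,
    tolerance_px: float = 5.0,
) -> tuple[list[DetectedObject], list[str]]:
    """Flag objects named by an exclusion registry; they stay listed but
    never enter counts.

    ``registry`` is either an iterable of (row, col) reference points, each
    resolving to the object containing that point (falling back to the
    nearest object centroid within ``tolerance_px``), or a boolean exclusion
    mask that excludes every object whose centroid it covers. Unresolvable
    references produce warning strings, not errors.
    """
    warnings: list[str] = []
    out = [replace(o) for o in objects]
    if registry is None:
        return out, warnings

    if isinstance(registry, np.ndarray) and registry.ndim == 2 and registry.dtype == bool:
        for o in out:
            r, c = int(round(o.centroid[0])), int(round(o.centroid[1]))
            if 0 <= r < registry.shape[0] and 0 <= c < registry.shape[1] and registry[r, c]:
                o.excluded = True
        return out, warnings

    pixel_owner: dict[tuple[int, int], int] = {}
    for i, o in enumerate(out):
        if o.pixels is not None:
            for r, c in o.pixels:
                pixel_owner[(int(r), int(c))] = i
    for point in registry:
        pr, pc = float(point[0]), float(point[1])
        idx = pixel_owner.get((int(round(pr)), int(round(pc))))
        if idx is None:
            dists = [
                (np.hypot(o.centroid[0] - pr, o.centroid[1] - pc), i)
                for i, o in enumerate(out)
            ]
            if dists:
                d, i = min(dists)
                if d <= tolerance_px:
                    idx = i
        if idx is None:
            warnings.append(f"unresolvable exclusion reference at ({pr:.1f}, {pc:.1f})")
        else:
            out[idx].excluded = True
    return out, warnings
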