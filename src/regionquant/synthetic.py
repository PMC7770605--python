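"""Synthetic atlas series, planted cell masks, clutter, and slab sectioning.

The generator produces the inputs the quantification pipeline consumes —
multi-region atlas label maps and binary segmentation masks — together with
an exact registry of every planted object, so counting, assignment and
exclusion can be tested against known ground truth.

Planted cells are ideal discs placed entirely inside one region, at least
``min_gap_px`` away from region boundaries and from each other, which makes
the region-assignment ground truth unambiguous. Clutter ("artifacts") are
irregular blobs flagged in the registry; they emulate erroneously segmented
non-cell objects such as clustered neuropil, and exercise the manual
exclusion step.

:func:`simulate_sectioning` reduces spherical cells of diameter D to depth
intervals cut by slabs of thickness T. A cell appears as a profile in every
slab its interval intersects, so profile counts overcount true cell numbers
by (T+D)/T on average — exactly the bias Abercrombie's correction
N = n·T/(T+D) removes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .atlas import AtlasSection, RegionNode, RegionOntology


class PlacementError(RuntimeError):
    """Raised when discs or blobs cannot be placed under the gap constraints."""


@dataclass(frozen=True)
class PlantedObject:
    object_id: int
    section_index: int
    row: float
    col: float
    radius_px: float
    region_id: int
    is_artifact: bool


@dataclass
class GroundTruth:
    """Registry of planted objects and the per-(section, region) cell counts.

    ``counts`` holds only non-artifact cells; the invariant that it equals
    the registry tally is re-derivable via :meth:`recount`.
    """

    objects: list[PlantedObject] = field(default_factory=list)

    def recount(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for o in self.objects:
            if not o.is_artifact:
                key = (o.section_index, o.region_id)
                counts[key] = counts.get(key, 0) + 1
        return counts

    def count(self, section_index: int, region_id: int) -> int:
        return self.recount().get((section_index, region_id), 0)

    def artifacts(self) -> list[PlantedObject]:
        return [o for o in self.objects if o.is_artifact]

    def cells(self) -> list[PlantedObject]:
        return [o for o in self.objects if not o.is_artifact]

    def write_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "section": o.section_index,
                "region_id": o.region_id,
                "object_id": o.object_id,
                "row": o.row,
                "col": o.col,
                "radius": o.radius_px,
                "is_artifact": int(o.is_artifact),
            }
            for o in self.objects
        ]
        pd.DataFrame(
            rows,
            columns=["section", "region_id", "object_id", "row", "col", "radius", "is_artifact"],
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t")
        objs = [
            PlantedObject(
                object_id=int(r.object_id),
                section_index=int(r.section),
                row=float(r.row),
                col=float(r.col),
                radius_px=float(r.radius),
                region_id=int(r.region_id),
                is_artifact=bool(r.is_artifact),
            )
            for r in df.itertuples()
        ]
        return cls(objects=objs)


@dataclass
class SlabSimResult:
    """Outcome of one sphere-in-slab sectioning simulation.

    ``profile_counts`` maps sampled slab index → number of cell profiles
    observed in that slab. Only every k-th slab is sampled, mirroring a
    1-in-k section sampling design.
    """

    true_cell_count: int
    profile_counts: dict[int, int]
    T_um: float
    D_um: float
    k: int
    tissue_depth_um: float
    seed: int

    @property
    def total_profiles(self) -> int:
        return sum(self.profile_counts.values())

    @property
    def n_sampled_sections(self) -> int:
        return len(self.profile_counts)


# ---------------------------------------------------------------------------
# Atlas series generation


def _leaf_ontology(n_leaves: int) -> RegionOntology:
    """A flat ontology: root 1, leaves 2..n_leaves+1, unit volumes."""
    nodes = [
        RegionNode(1, "ROOT", "root", None, (0, 0, 0), 0.0),
    ]
    for i in range(n_leaves):
        rid = i + 2
        nodes.append(
            RegionNode(
                rid,
                f"R{rid}",
                f"region {rid}",
                1,
                (50 + (37 * i) % 200, (91 * i) % 256, (53 * i + 11) % 256),
                1.0,
            )
        )
    return RegionOntology(nodes)


def generate_atlas_series(
    n_sections: int,
    shape: tuple[int, int],
    n_leaves: int,
    geometry: str = "bands",
    pixel_size_um: float = 10.0,
    thickness_um: float = 40.0,
    axis_start_mm: float = 0.0,
    axis_step_mm: float = 0.24,
    seed: int = 0,
) -> tuple[list[AtlasSection], RegionOntology]:
    """Generate ``n_sections`` label maps partitioned among ``n_leaves`` regions.

    ``geometry='bands'`` splits the image into equal-width vertical bands in
    leaf-id order; ``'voronoi'`` partitions pixels by nearest random site.
    ``axis_coord_mm`` decreases by ``axis_step_mm`` per section (dorsal →
    ventral ordering). Deterministic for a given seed.
    """
    h, w = shape
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    if h < 8 or w < 8:
        raise ValueError("shape must be at least 8x8")
    ontology = _leaf_ontology(n_leaves)
    leaf_ids = ontology.leaf_ids()
    rng = np.random.default_rng(seed)

    sections: list[AtlasSection] = []
    for s in range(n_sections):
        if geometry == "bands":
            cols = np.arange(w)
            band = np.minimum(cols * n_leaves // w, n_leaves - 1)
            labels = np.take(leaf_ids, band)[None, :].repeat(h, axis=0)
        elif geometry == "voronoi":
            sites = rng.uniform(0, [h, w], size=(n_leaves, 2))
            rr, cc = np.mgrid[0:h, 0:w]
            pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
            nearest = cKDTree(sites).query(pts)[1]
            labels = np.take(leaf_ids, nearest).reshape(h, w)
        else:
            raise ValueError(f"unknown geometry {geometry!r}")
        sections.append(
            AtlasSection(
                labels=labels.astype(np.int64),
                section_index=s,
                pixel_size_um=pixel_size_um,
                thickness_um=thickness_um,
                axis_coord_mm=axis_start_mm - s * axis_step_mm,
            )
        )
    return sections, ontology


# ---------------------------------------------------------------------------
# Cell planting


def plant_cells(
    sections: Sequence[AtlasSection],
    density_spec: Mapping[int, float],
    radius_px: tuple[int, int] = (3, 5),
    min_gap_px: int = 2,
    seed: int = 0,
    fixed_counts: bool = False,
    max_attempts_per_disc: int = 500,
) -> tuple[list[np.ndarray], GroundTruth]:
    """Plant disjoint circular cell profiles into binary masks.

    ``density_spec`` maps region_id → mean profiles per mm² per section
    (Poisson-drawn), or, with ``fixed_counts=True``, region_id → exact
    profile count per section. Every disc lies entirely inside its region
    and at least ``min_gap_px`` pixels from the region boundary and from
    every other disc, so both the count and the region-assignment ground
    truth are exact.
    """
    rng = np.random.default_rng(seed)
    r_lo, r_hi = radius_px
    if r_lo < 1 or r_hi < r_lo:
        raise ValueError("invalid radius_px range")

    masks: list[np.ndarray] = []
    gt = GroundTruth()
    next_id = 0
    for section in sections:
        mask = np.zeros(section.shape, dtype=bool)
        placed: list[tuple[float, float, float]] = []  # row, col, radius
        px_mm2 = (section.pixel_size_um / 1000.0) ** 2
        for region_id in sorted(density_spec):
            region_mask = section.labels == region_id
            area_px = int(region_mask.sum())
            if area_px == 0:
                continue
            if fixed_counts:
                n = int(density_spec[region_id])
            else:
                mean = float(density_spec[region_id]) * area_px * px_mm2
                n = int(rng.poisson(mean))
            if n == 0:
                continue
            disc_area = math.pi * r_hi**2
            if n * disc_area > 0.4 * area_px:
                raise PlacementError(
                    f"region {region_id}: {n} discs of radius <= {r_hi} exceed "
                    f"40% of region area ({area_px} px)"
                )
            # valid center: further than radius+gap from any non-region pixel
            dt = distance_transform_edt(region_mask)
            for _ in range(n):
                for attempt in range(max_attempts_per_disc):
                    radius = int(rng.integers(r_lo, r_hi + 1))
                    valid = np.argwhere(dt > radius + min_gap_px)
                    if len(valid) == 0:
                        continue
                    row, col = valid[rng.integers(len(valid))]
                    ok = all(
                        math.hypot(row - pr, col - pc) >= radius + prad + min_gap_px
                        for pr, pc, prad in placed
                    )
                    if ok:
                        break
                else:
                    raise PlacementError(
                        f"region {region_id}: could not place disc after "
                        f"{max_attempts_per_disc} attempts (section "
                        f"{section.section_index})"
                    )
                rr, cc = np.ogrid[0 : section.shape[0], 0 : section.shape[1]]
                mask |= (rr - row) ** 2 + (cc - col) ** 2 <= radius**2
                placed.append((float(row), float(col), float(radius)))
                gt.objects.append(
                    PlantedObject(
                        object_id=next_id,
                        section_index=section.section_index,
                        row=float(row),
                        col=float(col),
                        radius_px=float(radius),
                        region_id=int(region_id),
                        is_artifact=False,
                    )
                )
                next_id += 1
        masks.append(mask)
    return masks, gt


def inject_artifacts(
    mask: np.ndarray,
    ground_truth: GroundTruth,
    n_artifacts: int,
    size_px: tuple[int, int] = (6, 20),
    seed: int = 0,
    section_index: int = 0,
    min_gap_px: int = 2,
    section: AtlasSection | None = None,
    max_attempts: int = 500,
) -> tuple[np.ndarray, GroundTruth]:
    """Add ``n_artifacts`` irregular clutter blobs to a mask.

    Blobs are grown by a random walk to a size drawn from ``size_px``, kept
    at least ``min_gap_px`` away from all existing foreground, and recorded
    in the registry with ``is_artifact=True``. If ``section`` is given the
    registry stores each blob's majority region; otherwise region_id is 0.
    The input mask is not modified.
    """
    if n_artifacts < 0:
        raise ValueError("n_artifacts must be >= 0")
    mask = mask.copy()
    gt = GroundTruth(objects=list(ground_truth.objects))
    if n_artifacts == 0:
        return mask, gt
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    next_id = max((o.object_id for o in gt.objects), default=-1) + 1
    for _ in range(n_artifacts):
        for attempt in range(max_attempts):
            size = int(rng.integers(size_px[0], size_px[1] + 1))
            dt_free = distance_transform_edt(~mask)
            start = (int(rng.integers(h)), int(rng.integers(w)))
            blob = {start}
            frontier = [start]
            while len(blob) < size and frontier:
                r, c = frontier[rng.integers(len(frontier))]
                moves = [(r + 1, c), (r - 1, c), (r, c + 1), (r, c - 1)]
                rng.shuffle(moves)
                grown = False
                for nr, nc in moves:
                    if 0 <= nr < h and 0 <= nc < w and (nr, nc) not in blob:
                        blob.add((nr, nc))
                        frontier.append((nr, nc))
                        grown = True
                        break
                if not grown:
                    frontier.remove((r, c))
            if len(blob) < size:
                continue
            if all(dt_free[r, c] > min_gap_px for r, c in blob):
                break
        else:
            raise PlacementError(
                f"could not place artifact blob after {max_attempts} attempts"
            )
        rows = np.array([p[0] for p in blob])
        cols = np.array([p[1] for p in blob])
        mask[rows, cols] = True
        region_id = 0
        if section is not None:
            vals, counts = np.unique(section.labels[rows, cols], return_counts=True)
            nz = vals != 0
            if nz.any():
                vals, counts = vals[nz], counts[nz]
            region_id = int(vals[np.argmax(counts)])
        gt.objects.append(
            PlantedObject(
                object_id=next_id,
                section_index=section_index,
                row=float(rows.mean()),
                col=float(cols.mean()),
                radius_px=float(math.sqrt(len(blob) / math.pi)),
                region_id=region_id,
                is_artifact=True,
            )
        )
        next_id += 1
    return mask, gt


# ---------------------------------------------------------------------------
# Sphere-in-slab sectioning


def simulate_sectioning(
    true_cell_count: int,
    T_um: float,
    D_um: float,
    k: int = 1,
    tissue_depth_um: float = 40000.0,
    seed: int = 0,
    centers: Sequence[float] | None = None,
) -> SlabSimResult:
    """Cut ``true_cell_count`` spherical cells into slabs of thickness T.

    Cell centers are uniform on the depth axis. A cell of diameter D yields
    a profile in every slab [z_i, z_i + T) whose interval overlaps the open
    interval (center − D/2, center + D/2); for D = 0 the cell is a point
    assigned to the slab containing its center, with centers exactly on a
    slab boundary resolved to the lower slab. Only every k-th slab is
    reported as sampled. Explicit ``centers`` override the uniform draw
    (for deterministic checks).
    """
    if D_um < 0 or T_um <= 0 or k < 1 or tissue_depth_um < k * T_um:
        raise ValueError("parameter domain violation: need D>=0, T>0, k>=1, depth>=k*T")
    if centers is None:
        rng = np.random.default_rng(seed)
        centers = rng.uniform(0.0, tissue_depth_um, size=true_cell_count)
    else:
        centers = np.asarray(centers, dtype=float)
        if len(centers) != true_cell_count:
            raise ValueError("len(centers) must equal true_cell_count")
    n_slabs = int(tissue_depth_um // T_um)
    counts = np.zeros(n_slabs, dtype=int)
    if D_um == 0:
        idx = np.floor(centers / T_um).astype(int)
        on_boundary = (centers == idx * T_um) & (idx > 0)
        idx[on_boundary] -= 1
        idx = np.clip(idx, 0, n_slabs - 1)
        np.add.at(counts, idx, 1)
    else:
        lo = centers - D_um / 2.0
        hi = centers + D_um / 2.0
        first = np.maximum(np.floor(lo / T_um).astype(int), 0)
        # slab i overlaps (lo, hi) iff i*T < hi and (i+1)*T > lo
        last = np.minimum(np.ceil(hi / T_um).astype(int) - 1, n_slabs - 1)
        for f, l, lo_i, hi_i in zip(first, last, lo, hi):
            for i in range(f, l + 1):
                if i * T_um < hi_i and (i + 1) * T_um > lo_i:
                    counts[i] += 1
    sampled = {i: int(counts[i]) for i in range(0, n_slabs, k)}
    n_expected = int(tissue_depth_um // (k * T_um))
    sampled = dict(list(sampled.items())[:n_expected])
    return SlabSimResult(
        true_cell_count=true_cell_count,
        profile_counts=sampled,
        T_um=T_um,
        D_um=D_um,
        k=k,
        tissue_depth_um=tissue_depth_um,
        seed=seed,
    )
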