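"""Region ontologies, custom groupings, atlas label-map sections, and I/O.

An atlas label map is a 2D integer image, pixel-aligned with the section
photograph, whose values are region identifiers from a reference atlas
hierarchy (e.g. the Allen mouse CCFv3-2017 or the Waxholm rat WHSv2).
Pixel value 0 is reserved for "outside the atlas". Only leaf regions of the
ontology may appear in label images; higher levels exist for aggregation
and carry the reference-atlas volumes used for density estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

UNGROUPED = "UNGROUPED"

ONTOLOGY_COLUMNS = [
    "id",
    "acronym",
    "name",
    "parent_id",
    "r",
    "g",
    "b",
    "volume_mm3",
    "oversaturated",
]

HEADER_FIELDS = {
    "width",
    "height",
    "pixel_size_um",
    "thickness_um",
    "section_index",
    "axis_coord_mm",
}


class OntologyError(ValueError):
    """Structural violation in a region ontology (cycle, duplicate id, ...)."""


@dataclass(frozen=True)
class RegionNode:
    """One region of the atlas hierarchy.

    ``volume_mm3`` is the bilateral region volume taken from the
    three-dimensional reference atlas (not from section areas), used as the
    denominator of density estimates. ``oversaturated`` flags regions whose
    staining saturates the image so counts are invalid and must be
    suppressed from reports.
    """

    region_id: int
    acronym: str
    name: str
    parent_id: int | None
    color: tuple[int, int, int]
    volume_mm3: float
    oversaturated: bool = False

    def __post_init__(self) -> None:
        if self.region_id <= 0:
            raise OntologyError(f"region_id must be positive, got {self.region_id}")
        if self.volume_mm3 < 0:
            raise OntologyError(
                f"region {self.region_id}: negative volume {self.volume_mm3}"
            )
        if not all(0 <= c <= 255 for c in self.color):
            raise OntologyError(f"region {self.region_id}: color out of range")


class RegionOntology:
    """A rooted tree of :class:`RegionNode` objects.

    Invariants enforced at construction: unique ids, exactly one root,
    every node reachable from the root (hence no cycles), unique colors.
    """

    def __init__(self, nodes: Iterable[RegionNode]):
        nodes = list(nodes)
        self._nodes: dict[int, RegionNode] = {}
        for n in nodes:
            if n.region_id in self._nodes:
                raise OntologyError(f"duplicate region id {n.region_id}")
            self._nodes[n.region_id] = n

        roots = [n for n in nodes if n.parent_id is None]
        if len(roots) != 1:
            raise OntologyError(
                f"ontology must have exactly one root, found {len(roots)}: "
                f"{sorted(n.region_id for n in roots)}"
            )
        self.root = roots[0]

        self._children: dict[int, list[int]] = {n.region_id: [] for n in nodes}
        for n in nodes:
            if n.parent_id is not None:
                if n.parent_id not in self._nodes:
                    raise OntologyError(
                        f"region {n.region_id} references unknown parent {n.parent_id}"
                    )
                self._children[n.parent_id].append(n.region_id)

        # reachability check doubles as cycle detection in a parent-pointer graph
        seen: set[int] = set()
        stack = [self.root.region_id]
        while stack:
            rid = stack.pop()
            if rid in seen:
                continue
            seen.add(rid)
            stack.extend(self._children[rid])
        unreachable = set(self._nodes) - seen
        if unreachable:
            raise OntologyError(
                f"cycle or orphan subtree involving ids {sorted(unreachable)}"
            )

        colors = [n.color for n in nodes]
        if len(set(colors)) != len(colors):
            raise OntologyError("region colors are not unique")

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, region_id: int) -> bool:
        return region_id in self._nodes

    def __getitem__(self, region_id: int) -> RegionNode:
        return self._nodes[region_id]

    @property
    def nodes(self) -> list[RegionNode]:
        return [self._nodes[i] for i in sorted(self._nodes)]

    def children(self, region_id: int) -> list[RegionNode]:
        return [self._nodes[c] for c in sorted(self._children[region_id])]

    def leaves(self) -> list[RegionNode]:
        """Leaf regions in ascending id order; only these may label pixels."""
        return [
            self._nodes[i] for i in sorted(self._nodes) if not self._children[i]
        ]

    def leaf_ids(self) -> list[int]:
        return [n.region_id for n in self.leaves()]

    def is_leaf(self, region_id: int) -> bool:
        return region_id in self._nodes and not self._children[region_id]

    def descendant_leaves(self, region_id: int) -> list[int]:
        """All leaf ids in the subtree rooted at ``region_id`` (itself if leaf)."""
        out: list[int] = []
        stack = [region_id]
        while stack:
            rid = stack.pop()
            kids = self._children[rid]
            if kids:
                stack.extend(kids)
            else:
                out.append(rid)
        return sorted(out)

    def volume(self, region_id: int) -> float:
        return self._nodes[region_id].volume_mm3


@dataclass
class CustomGrouping:
    """A partition of (some) ontology leaves into named report groups.

    Mirrors the custom-region files used by atlas quantification tools:
    each mapped leaf belongs to exactly one group; leaves not mentioned
    fall into the implicit ``UNGROUPED`` bucket.
    """

    mapping: dict[int, str]
    group_order: list[str] = field(default_factory=list)
    group_names: dict[str, str] = field(default_factory=dict)

    @classmethod
    def identity(cls, ontology: RegionOntology) -> "CustomGrouping":
        m = {n.region_id: n.acronym for n in ontology.leaves()}
        return cls(mapping=m, group_order=[n.acronym for n in ontology.leaves()])

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, str]]) -> "CustomGrouping":
        mapping: dict[int, str] = {}
        order: list[str] = []
        for leaf_id, group in pairs:
            leaf_id = int(leaf_id)
            if leaf_id in mapping and mapping[leaf_id] != group:
                raise OntologyError(
                    f"leaf {leaf_id} mapped to both "
                    f"{mapping[leaf_id]!r} and {group!r} (partition violation)"
                )
            mapping[leaf_id] = group
            if group not in order:
                order.append(group)
        return cls(mapping=mapping, group_order=order)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CustomGrouping":
        df = pd.read_csv(path, sep="\t", dtype={"leaf_id": int, "group_acronym": str})
        if list(df.columns) != ["leaf_id", "group_acronym"]:
            raise OntologyError(
                f"grouping file must have columns leaf_id, group_acronym; "
                f"got {list(df.columns)}"
            )
        return cls.from_pairs(zip(df["leaf_id"], df["group_acronym"]))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"leaf_id": list(self.mapping), "group_acronym": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class AtlasSection:
    """One atlas label map: region id per pixel, plus acquisition geometry.

    ``thickness_um`` is the physical section thickness T entering the
    Abercrombie correction; ``axis_coord_mm`` orders sections along the
    cutting axis (a bregma-like coordinate, decreasing dorsal to ventral)
    for gradient profiling. ``hemisphere``, if present, is a same-shape
    array with 0 = none, 1 = left, 2 = right.
    """

    labels: np.ndarray
    section_index: int
    pixel_size_um: float
    thickness_um: float
    axis_coord_mm: float = 0.0
    hemisphere: np.ndarray | None = None

    HEMI_NONE, HEMI_LEFT, HEMI_RIGHT = 0, 1, 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D array")
        if self.pixel_size_um <= 0 or self.thickness_um <= 0:
            raise ValueError("pixel_size_um and thickness_um must be positive")
        if self.hemisphere is not None:
            self.hemisphere = np.asarray(self.hemisphere)
            if self.hemisphere.shape != self.labels.shape:
                raise ValueError("hemisphere mask shape must match labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def validate_against(self, ontology: RegionOntology) -> None:
        present = set(np.unique(self.labels).tolist()) - {0}
        bad = [rid for rid in sorted(present) if not ontology.is_leaf(rid)]
        if bad:
            raise OntologyError(
                f"section {self.section_index}: non-leaf or unknown label ids {bad}"
            )


@dataclass
class CrossAtlasMapping:
    """Rows mapping a shared target region to source region ids in two atlases.

    Used for cross-species comparison: e.g. the dentate gyrus corresponds to
    one set of CCFv3-2017 ids in the mouse and another set of WHSv2 ids in
    the rat.
    """

    rows: list[tuple[str, tuple[int, ...], tuple[int, ...]]]

    def __post_init__(self) -> None:
        seen_a: set[int] = set()
        seen_b: set[int] = set()
        for target, ids_a, ids_b in self.rows:
            if not ids_a or not ids_b:
                raise OntologyError(f"mapping row {target!r}: empty source id list")
            if seen_a & set(ids_a) or seen_b & set(ids_b):
                raise OntologyError(
                    f"mapping row {target!r}: source ids reused across rows"
                )
            seen_a |= set(ids_a)
            seen_b |= set(ids_b)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CrossAtlasMapping":
        df = pd.read_csv(path, sep="\t", dtype=str)
        expected = ["target_acronym", "atlasA_ids", "atlasB_ids"]
        if list(df.columns) != expected:
            raise OntologyError(f"mapping file must have columns {expected}")
        rows = []
        for _, r in df.iterrows():
            ids_a = tuple(int(x) for x in str(r["atlasA_ids"]).split(","))
            ids_b = tuple(int(x) for x in str(r["atlasB_ids"]).split(","))
            rows.append((r["target_acronym"], ids_a, ids_b))
        return cls(rows)


# ---------------------------------------------------------------------------
# Ontology I/O


def load_ontology(path: str | Path) -> RegionOntology:
    """Load and validate a region ontology from a TSV table.

    Expected columns: ``id acronym name parent_id r g b volume_mm3
    oversaturated`` (tab-separated; ``parent_id`` empty for the root;
    ``oversaturated`` in {0, 1}). Raises :class:`OntologyError` naming the
    offending ids on duplicates, cycles, multiple roots or negative volumes.
    """
    df = pd.read_csv(path, sep="\t", dtype={"acronym": str, "name": str})
    missing = set(ONTOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise OntologyError(f"ontology file missing columns {sorted(missing)}")
    nodes = []
    for _, r in df.iterrows():
        parent = None if pd.isna(r["parent_id"]) else int(r["parent_id"])
        nodes.append(
            RegionNode(
                region_id=int(r["id"]),
                acronym=str(r["acronym"]),
                name=str(r["name"]),
                parent_id=parent,
                color=(int(r["r"]), int(r["g"]), int(r["b"])),
                volume_mm3=float(r["volume_mm3"]),
                oversaturated=bool(int(r["oversaturated"])),
            )
        )
    return RegionOntology(nodes)


def write_ontology(ontology: RegionOntology, path: str | Path) -> None:
    rows = []
    for n in ontology.nodes:
        rows.append(
            {
                "id": n.region_id,
                "acronym": n.acronym,
                "name": n.name,
                "parent_id": "" if n.parent_id is None else n.parent_id,
                "r": n.color[0],
                "g": n.color[1],
                "b": n.color[2],
                "volume_mm3": n.volume_mm3,
                "oversaturated": int(n.oversaturated),
            }
        )
    pd.DataFrame(rows, columns=ONTOLOGY_COLUMNS).to_csv(path, sep="\t", index=False)


def resolve_grouping(
    ontology: RegionOntology, grouping: CustomGrouping
) -> dict[int, str]:
    """Resolve a custom grouping to a total leaf → group map.

    Every ontology leaf appears in the result; leaves the grouping does not
    mention map to ``UNGROUPED``. Ids that are not leaves of this ontology
    raise.
    """
    leaves = set(ontology.leaf_ids())
    bad = [i for i in grouping.mapping if i not in leaves]
    if bad:
        raise OntologyError(
            f"grouping references non-leaf or unknown ids {sorted(bad)}"
        )
    out = {leaf: UNGROUPED for leaf in sorted(leaves)}
    out.update(grouping.mapping)
    return out


# ---------------------------------------------------------------------------
# Atlas-section flat-file I/O
#
# Format: <stem>.flat holds the label image as little-endian unsigned 32-bit
# integers, row-major, origin top-left; <stem>.hdr.json holds the geometry.


def write_atlas_section(section: AtlasSection, stem: str | Path) -> tuple[Path, Path]:
    stem = Path(stem)
    flat_path = stem.with_suffix(".flat")
    hdr_path = stem.with_suffix(".hdr.json")
    h, w = section.labels.shape
    data = np.ascontiguousarray(section.labels, dtype="<u4")
    flat_path.write_bytes(data.tobytes())
    header = {
        "width": w,
        "height": h,
        "pixel_size_um": section.pixel_size_um,
        "thickness_um": section.thickness_um,
        "section_index": section.section_index,
        "axis_coord_mm": section.axis_coord_mm,
    }
    hdr_path.write_text(json.dumps(header, indent=1) + "\n")
    return flat_path, hdr_path


def read_atlas_section(flat_path: str | Path, header_path: str | Path) -> AtlasSection:
    flat_path = Path(flat_path)
    header_path = Path(header_path)
    header = json.loads(header_path.read_text())
    unknown = set(header) - HEADER_FIELDS
    if unknown:
        raise ValueError(f"unknown header field(s): {sorted(unknown)}")
    missing = HEADER_FIELDS - set(header)
    if missing:
        raise ValueError(f"missing header field(s): {sorted(missing)}")
    w, h = int(header["width"]), int(header["height"])
    raw = flat_path.read_bytes()
    if len(raw) != w * h * 4:
        raise ValueError(
            f"flat file size mismatch: expected {w * h * 4} bytes "
            f"({w}x{h} u32), got {len(raw)}"
        )
    labels = np.frombuffer(raw, dtype="<u4").reshape(h, w).astype(np.int64)
    return AtlasSection(
        labels=labels,
        section_index=int(header["section_index"]),
        pixel_size_um=float(header["pixel_size_um"]),
        thickness_um=float(header["thickness_um"]),
        axis_coord_mm=float(header["axis_coord_mm"]),
    )


def region_areas(section: AtlasSection) -> dict[int, int]:
    """Pixel count per region id present in the section, including 0.

    The counts always sum to ``width × height``.
    """
    ids, counts = np.unique(section.labels, return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts)}
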