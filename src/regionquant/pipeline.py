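"""Configuration-driven end-to-end runs, report writing, and run manifests.

A run executes extract → assign → exclude → count → quantify over a
directory of atlas sections and masks, writes TSV reports, and records a
manifest capturing the full configuration, input checksums and per-stage
row counts — enough to reproduce the run byte for byte. A conservation
audit (region counts + unassigned + excluded = extracted objects) is
asserted on every run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import (
    UNGROUPED,
    AtlasSection,
    CustomGrouping,
    RegionOntology,
    load_ontology,
    read_atlas_section,
    resolve_grouping,
)
from .extraction import DetectedObject, ExtractionParams, apply_exclusions, assign_region, extract_objects
from .quantify import (
    STATUS_OK,
    QuantParams,
    RegionEstimate,
    UNASSIGNED,
    count_profiles,
    estimate_region,
)

log = logging.getLogger("regionquant")

REGION_REPORT_SCHEMA = [
    ("region", "str"),
    ("n_raw", "int"),
    ("n_corrected", "real2"),
    ("total_estimate", "int"),
    ("volume_mm3", "real"),
    ("density_per_mm3", "real2"),
    ("status", "str"),
]

OBJECTS_SCHEMA = [
    ("section", "int"),
    ("object_id", "int"),
    ("pixel_count", "int"),
    ("row", "real2"),
    ("col", "real2"),
    ("region_id", "int"),
    ("hemisphere", "str"),
    ("excluded", "int"),
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    ontology: Path
    atlas_dir: Path
    mask_dir: Path
    output_dir: Path
    grouping: Path | None = None
    exclusions: Path | None = None
    thickness_um: float = 40.0
    diameter_um: float = 15.0
    interval: int = 6
    connectivity: int = 8
    min_size_px: int = 4
    scope: str = "unilateral"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        def p(key):
            return (base / raw[key]).resolve() if key in raw and raw[key] else None
        cfg = cls(
            ontology=p("ontology"),
            atlas_dir=p("atlas_dir"),
            mask_dir=p("mask_dir"),
            output_dir=(base / raw["output_dir"]).resolve(),
            grouping=p("grouping"),
            exclusions=p("exclusions"),
            **{
                k: raw[k]
                for k in (
                    "thickness_um",
                    "diameter_um",
                    "interval",
                    "connectivity",
                    "min_size_px",
                    "scope",
                    "seed",
                    "log_level",
                )
                if k in raw
            },
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("ontology", "atlas_dir", "mask_dir"):
            path = getattr(self, name)
            if path is None or not Path(path).exists():
                raise PipelineError("config", f"{name} path does not exist: {path}")
        for name in ("grouping", "exclusions"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise PipelineError("config", f"{name} path does not exist: {path}")
        QuantParams(self.thickness_um, self.diameter_um, self.interval)
        ExtractionParams(self.connectivity, self.min_size_px)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def format_value(value: Any, kind: str) -> str:
    if value is None:
        return ""
    if kind == "int":
        return str(int(value))
    if kind == "real2":
        return f"{float(value):.2f}"
    if kind == "real":
        return repr(float(value)) if value is not None else ""
    return str(value)


def write_report(
    rows: Sequence[Mapping[str, Any]], schema: Sequence[tuple[str, str]], path: str | Path
) -> Path:
    """Write rows as a UTF-8, LF-terminated TSV with a fixed column order.

    Integers print plain; densities and percentages print with 2 decimals;
    missing values print empty. Extra keys in a row are a schema violation.
    """
    path = Path(path)
    cols = [c for c, _ in schema]
    lines = ["\t".join(cols)]
    for row in rows:
        extra = set(row) - set(cols)
        if extra:
            raise ValueError(f"row has keys outside schema: {sorted(extra)}")
        lines.append("\t".join(format_value(row.get(c), k) for c, k in schema))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_section_series(atlas_dir: str | Path) -> list[AtlasSection]:
    """Read all <stem>.flat/<stem>.hdr.json pairs, ordered by section index."""
    atlas_dir = Path(atlas_dir)
    sections = []
    for flat in sorted(atlas_dir.glob("*.flat")):
        hdr = flat.with_suffix("").with_suffix(".hdr.json")
        if not hdr.exists():
            hdr = Path(str(flat)[: -len(".flat")] + ".hdr.json")
        if not hdr.exists():
            raise PipelineError("load", f"no header for {flat.name}")
        sections.append(read_atlas_section(flat, hdr))
    sections.sort(key=lambda s: s.section_index)
    return sections


def load_masks(mask_dir: str | Path) -> list[np.ndarray]:
    mask_dir = Path(mask_dir)
    masks = []
    for png in sorted(mask_dir.glob("*.png")):
        img = np.asarray(iio.imread(png))
        if img.ndim == 3:
            img = img[..., 0]
        masks.append(img > 0)
    return masks


def load_exclusions(path: str | Path) -> dict[int, list[tuple[float, float]]]:
    """Exclusion registry TSV: columns section, row, col."""
    df = pd.read_csv(path, sep="\t")
    out: dict[int, list[tuple[float, float]]] = {}
    for r in df.itertuples():
        out.setdefault(int(r.section), []).append((float(r.row), float(r.col)))
    return out


def group_volumes(
    ontology: RegionOntology, grouping: Mapping[int, str]
) -> tuple[dict[str, float], dict[str, bool]]:
    """Summed member-leaf volumes and oversaturation flags per group.

    A group is flagged when any member leaf is (transitively) oversaturated.
    """
    flagged_leaves: set[int] = set()
    for node in ontology.nodes:
        if node.oversaturated:
            flagged_leaves.update(ontology.descendant_leaves(node.region_id))
    vols: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for leaf, group in grouping.items():
        vols[group] = vols.get(group, 0.0) + ontology.volume(leaf)
        flags[group] = flags.get(group, False) or leaf in flagged_leaves
    return vols, flags


def run_pipeline(config: RunConfig) -> tuple[list[RegionEstimate], dict]:
    """Execute the full counting/correction pipeline for one series.

    Returns the region estimates and the manifest dict; writes
    ``region_report.tsv``, ``objects.tsv`` and ``manifest.json`` under the
    configured output directory. Any stage failure aborts with the stage
    name, removing partial outputs.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    warnings: list[str] = []
    try:
        ontology = load_ontology(config.ontology)
        if config.grouping is not None:
            grouping = resolve_grouping(ontology, CustomGrouping.read_tsv(config.grouping))
        else:
            grouping = resolve_grouping(ontology, CustomGrouping.identity(ontology))
        sections = load_section_series(config.atlas_dir)
        masks = load_masks(config.mask_dir)
        if len(masks) != len(sections):
            raise PipelineError(
                "load", f"{len(sections)} atlas sections but {len(masks)} masks"
            )
        exclusions = (
            load_exclusions(config.exclusions) if config.exclusions else {}
        )

        params = ExtractionParams(config.connectivity, config.min_size_px)
        objects_per_section: dict[int, list[DetectedObject]] = {}
        n_extracted = 0
        for section, mask in zip(sections, masks):
            if mask.shape != section.shape:
                raise PipelineError(
                    "extract",
                    f"section {section.section_index}: mask shape {mask.shape} "
                    f"!= atlas shape {section.shape}",
                )
            objs = [assign_region(o, section) for o in extract_objects(mask, params)]
            objs, warn = apply_exclusions(objs, exclusions.get(section.section_index))
            warnings.extend(warn)
            objects_per_section[section.section_index] = objs
            n_extracted += len(objs)

        counts = count_profiles(objects_per_section, grouping, sections)
        vols, flags = group_volumes(ontology, grouping)
        qparams = QuantParams(config.thickness_um, config.diameter_um, config.interval)
        estimates = estimate_region(counts, qparams, vols, flags, scope=config.scope)

        # conservation audit: counts partition the non-excluded objects
        n_excluded = sum(
            o.excluded for objs in objects_per_section.values() for o in objs
        )
        n_counted = sum(c.n_profiles for c in counts)
        if n_counted + n_excluded != n_extracted:
            raise PipelineError(
                "audit",
                f"conservation violated: {n_counted} counted + {n_excluded} "
                f"excluded != {n_extracted} extracted",
            )

        obj_rows = [
            {
                "section": s,
                "object_id": o.object_id,
                "pixel_count": o.pixel_count,
                "row": o.centroid[0],
                "col": o.centroid[1],
                "region_id": o.region_id,
                "hemisphere": o.hemisphere,
                "excluded": int(o.excluded),
            }
            for s in sorted(objects_per_section)
            for o in objects_per_section[s]
        ]
        written.append(write_report(obj_rows, OBJECTS_SCHEMA, out_dir / "objects.tsv"))

        est_rows = [
            {
                "region": str(e.label),
                "n_raw": e.n_raw,
                "n_corrected": e.n_corrected,
                "total_estimate": e.total_estimate,
                "volume_mm3": e.volume_mm3,
                "density_per_mm3": e.density_per_mm3,
                "status": e.status,
            }
            for e in estimates
        ]
        written.append(
            write_report(est_rows, REGION_REPORT_SCHEMA, out_dir / "region_report.tsv")
        )

        manifest = {
            "tool": "regionquant",
            "version": __version__,
            "config": {
                k: (str(v) if isinstance(v, Path) else v)
                for k, v in asdict(config).items()
            },
            "inputs": {
                "ontology": _sha256(Path(config.ontology)),
                "atlas": {
                    p.name: _sha256(p)
                    for p in sorted(Path(config.atlas_dir).glob("*.flat"))
                },
                "masks": {
                    p.name: _sha256(p)
                    for p in sorted(Path(config.mask_dir).glob("*.png"))
                },
            },
            "stages": {
                "sections": len(sections),
                "objects_extracted": n_extracted,
                "objects_excluded": n_excluded,
                "profiles_counted": n_counted,
                "regions_reported": len(estimates),
            },
            "outputs": {p.name: _sha256(p) for p in written},
            "warnings": warnings,
        }
        tmp = out_dir / "manifest.json.tmp"
        tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
        tmp.replace(out_dir / "manifest.json")
        return estimates, manifest
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:  # annotate unforeseen failures with a stage
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("run", str(exc)) from exc
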