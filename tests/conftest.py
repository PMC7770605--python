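from pathlib import Path

import numpy as np
import pytest

from regionquant import (
    AtlasSection,
    RegionNode,
    RegionOntology,
    generate_atlas_series,
    load_ontology,
    plant_cells,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def ontology12():
    """12-node / 8-leaf fixture ontology shipped with the repo."""
    return load_ontology(DATA_DIR / "ontology_12.tsv")


@pytest.fixture(scope="session")
def ontology12_path():
    return DATA_DIR / "ontology_12.tsv"


@pytest.fixture
def tiny_ontology():
    """Root with two leaves."""
    return RegionOntology(
        [
            RegionNode(1, "ROOT", "root", None, (0, 0, 0), 0.0),
            RegionNode(2, "A", "region a", 1, (10, 0, 0), 2.0),
            RegionNode(3, "B", "region b", 1, (0, 10, 0), 1.0),
        ]
    )


@pytest.fixture(scope="session")
def planted_series():
    """20-section, 5-region synthetic series with exact ground truth."""
    sections, ontology = generate_atlas_series(
        n_sections=20, shape=(96, 96), n_leaves=5, geometry="bands", seed=42
    )
    masks, gt = plant_cells(
        sections,
        {rid: 6 for rid in ontology.leaf_ids()},
        radius_px=(2, 4),
        min_gap_px=2,
        seed=7,
        fixed_counts=True,
    )
    return sections, ontology, masks, gt


def make_section(labels, **kw):
    defaults = dict(section_index=0, pixel_size_um=10.0, thickness_um=40.0)
    defaults.update(kw)
    return AtlasSection(labels=np.asarray(labels), **defaults)
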