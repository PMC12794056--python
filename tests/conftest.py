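import json

import numpy as np
import pytest

from afm.imaging import FibrosisParams
from afm.synthetic import generate_slide, reduced_spec


@pytest.fixture
def default_params():
    return FibrosisParams()


@pytest.fixture
def two_tubule_geojson(tmp_path):
    """Minimal two-feature FeatureCollection in the QuPath-style dialect."""
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "id": "a",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]]],
                },
                "properties": {"classification": {"name": "Distal"}},
            },
            {
                "type": "Feature",
                "id": "b",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[20, 20], [30, 20], [25, 30], [20, 20]]],
                },
                "properties": {"class": " proximal "},
            },
        ],
    }
    path = tmp_path / "tubules.geojson"
    path.write_text(json.dumps(doc))
    return path


@pytest.fixture(scope="session")
def small_slide():
    """One reduced-scale null slide (p0=0.25, delta=0) shared across tests."""
    return generate_slide(reduced_spec(seed=42, p0=0.25, delta=0.0))


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory):
    """A written-to-disk mini cohort: one PNG slide + GeoJSON per disease group."""
    from PIL import Image

    from afm.annotations import write_annotations

    root = tmp_path_factory.mktemp("cohort")
    paths = {}
    for i, disease in enumerate(["alport", "hypertensive", "vasculitis"]):
        spec = reduced_spec(
            seed=500 + i, width=300, height=300, n_distal=10, n_proximal=20,
            p0=0.2, delta=0.0,
        )
        slide = generate_slide(spec, ground_truth=False)
        img_path = root / f"{disease}.png"
        ann_path = root / f"{disease}.geojson"
        Image.fromarray(slide.image.pixels).save(img_path)
        write_annotations(slide.annotations, ann_path)
        paths[disease] = (img_path, ann_path)
    return paths


def make_tile(size: int = 64, rgb=(255, 255, 255)) -> np.ndarray:
    tile = np.empty((size, size, 3), dtype=np.uint8)
    tile[:] = rgb
    return tile
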