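import json

import numpy as np
import pytest

from phenopipe.synth import generate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape, density=0.3):
    return rng.random(shape) < density


def flood_fill_components(mask):
    """Brute-force 8-connected component oracle: BFS over pixel sets."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    comps = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack = [(i, j)]
                seen[i, j] = True
                pixels = set()
                while stack:
                    r, c = stack.pop()
                    pixels.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(frozenset(pixels))
    return comps


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory):
    """A 2-plant x 3-day x 3-view tree (18 images) with its manifest."""
    root = tmp_path_factory.mktemp("fixtures") / "tree"
    manifest = generate_tree(2, 3, seed=11, root=root)
    return root, manifest


STANDARD_WORKFLOW = [
    {"name": "filter", "operation": "colorFilter", "arguments": {"expr": "g > b"},
     "inputs": {"image": "raw"}, "outputs": {"image": "filtered"}},
    {"name": "chop", "operation": "contourChop", "arguments": {"min_area": 40},
     "inputs": {"image": "filtered"}, "outputs": {"image": "clean"}},
    {"name": "cut", "operation": "contourCut", "arguments": {"min_area": 40},
     "inputs": {"image": "clean"}, "outputs": {"image": "final"}},
    {"name": "extract", "operation": "extract", "arguments": {},
     "inputs": {"image": "final"}, "outputs": {}},
]


def write_templates(dirpath, template, workflows=("rgbsv", "rgbtv"), max_concurrent=1,
                    output_root=None, jobs=None):
    """Write the three JSON templates next to a fixture tree; returns paths."""
    proc = {"workflows": {imt: jobs or STANDARD_WORKFLOW for imt in workflows}}
    cfg = {
        "max_concurrent": max_concurrent,
        "output_root": str(output_root or dirpath / "out"),
        "seed": 1,
    }
    paths = (dirpath / "loading.json", dirpath / "processing.json", dirpath / "config.json")
    paths[0].write_text(json.dumps(template))
    paths[1].write_text(json.dumps(proc))
    paths[2].write_text(json.dumps(cfg))
    return paths
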