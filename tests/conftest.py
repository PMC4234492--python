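import numpy as np
import pytest

from colonyarray import colony_quant as cq
from colonyarray import synthetic_fixtures as sf

PRESET_18 = cq.GridPreset(rows=32, cols=48, dx=18.0, dy=18.0)


@pytest.fixture(scope="session")
def preset_18():
    """Grid preset matching the default synthetic render geometry."""
    return PRESET_18


@pytest.fixture(scope="session")
def uniform_render():
    """A clean uniform 1536-position render with its truth table."""
    spec = sf.PlateSpec(noise_sd=5.0, seed=101)
    img, truth = sf.render_plate(spec)
    return spec, img, truth


@pytest.fixture()
def screen_factory(tmp_path):
    """Simulate a paired screen into a temp folder; returns
    (manifest, folder) for the given spec."""

    def _make(spec: sf.ScreenSpec):
        out = tmp_path / f"screen_{spec.seed}"
        manifest = sf.simulate_screen(spec, out)
        return manifest, out

    return _make


def ground_truth_cell_counts(img, spec):
    """Independent per-cell pixel-count oracle on the thresholded
    ground-truth mask (no grid fitting, no particle analysis)."""
    mid = (int(spec.background_level) + int(spec.colony_level)) / 2.0
    mask = img.astype(float) > mid
    ox, oy = spec.origin
    counts = np.zeros((spec.rows, spec.cols), dtype=int)
    for r in range(spec.rows):
        for c in range(spec.cols):
            x = ox + c * spec.dx
            y = oy + r * spec.dy
            x0, x1 = int(round(x - spec.dx / 2)), int(round(x + spec.dx / 2))
            y0, y1 = int(round(y - spec.dy / 2)), int(round(y + spec.dy / 2))
            counts[r, c] = int(mask[max(0, y0):y1, max(0, x0):x1].sum())
    return counts
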