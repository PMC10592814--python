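import numpy as np
import pytest

from fociquant import AnalysisConfig, SceneSpec, generate_scene


@pytest.fixture
def config():
    """Default analysis configuration for a two-channel LC3B/Ub plate."""
    return AnalysisConfig(
        segmentation_channel="LC3B",
        foci_channel="LC3B",
        coloc_channels=("LC3B", "Ub"),
        stain_channels=("Ub",),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_scene():
    """One deterministic 12-cell field with foci in every cell."""
    spec = SceneSpec(seed=7)
    return generate_scene(spec)


def label_at_center(labels: np.ndarray, row: float, col: float, radius: float) -> int:
    """Majority label over a cell's core disk (robust to 1-px watershed lines)."""
    rr, cc = np.mgrid[0 : labels.shape[0], 0 : labels.shape[1]]
    core = (rr - row) ** 2 + (cc - col) ** 2 <= (0.5 * radius) ** 2
    vals = labels[core]
    vals = vals[vals > 0]
    return 0 if vals.size == 0 else int(np.bincount(vals).argmax())
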