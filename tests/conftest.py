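import numpy as np
import pytest

import seedmorph as sm
from seedmorph.imaging import Particle, ScaleCalibration


def particle_from_mask(mask: np.ndarray, label: int = 1) -> Particle:
    """Wrap a boolean mask as a single Particle (test helper)."""
    pix = np.argwhere(mask)
    return Particle(
        label=label,
        pixels=pix,
        area_px=len(pix),
        bbox=(
            int(pix[:, 0].min()),
            int(pix[:, 0].max()),
            int(pix[:, 1].min()),
            int(pix[:, 1].max()),
        ),
    )


@pytest.fixture
def unit_cal() -> ScaleCalibration:
    """1 mm per pixel calibration."""
    return ScaleCalibration(mm_per_px=1.0, tag_length_mm=16.0, tag_length_px=16)


@pytest.fixture(scope="session")
def scene95():
    """One study-density scene: 95 non-overlapping seeds (~30x15 px
    semi-axes at 0.1 mm/px), a 160 px tag, ten 2 px noise specks."""
    params = sm.AccessionParams("ACC0000", 3.0, 1.5, cv_size=0.08, n_seeds=95)
    shapes = sm.sample_accession(params, rng_seed=11)
    spec = sm.build_scene(
        shapes, mm_per_px=0.1, image_size=(1400, 1800), n_specks=10, rng_seed=12
    )
    image, truth = sm.render_scene(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def table507():
    """Study-scale synthetic trait table: 507 lines, ~41-238 seeds each,
    drawn around the six planted cluster centers."""
    table, labels = sm.generate_trait_table(
        n_lines=507, seeds_per_line=None, rng_seed=1
    )
    return table, labels
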