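"""Shared fixtures: phantom studies at the sizes the tests need."""

from __future__ import annotations

import numpy as np
import pytest

import plaquemap as pm
from plaquemap.msi_data import MzAxis, SectionImage, Study


@pytest.fixture(scope="session")
def panel():
    return pm.generate_species_panel(3, seed=11)


@pytest.fixture(scope="session")
def noise_free_record(panel):
    """One deterministic section with every stochastic term off."""
    spec = pm.PhantomSpec(grid_shape=(48, 48)).noise_free()
    return pm.synthetic.generate_section(spec, panel, rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def small_study():
    """3 patients × 2–3 sections, default noise — for preprocessing tests."""
    spec = pm.PhantomSpec(grid_shape=(40, 40))
    return pm.generate_study(3, (2, 3), spec, seed=7, n_per_class=3)


@pytest.fixture(scope="session")
def study_12x8():
    """The full-scale recovery phantom: 12 patients × 8 sections, σ = 0.3."""
    spec = pm.PhantomSpec(grid_shape=(48, 48))
    study_raw, truth = pm.generate_study(12, (8, 8), spec, seed=42, n_per_class=3)
    study_raw, peaks = pm.msi_data.preprocess_study(study_raw)
    return study_raw, peaks, truth


def make_study(intensity_blocks, mz=None, grid=(2, 2)):
    """Hand-built study: one section per (n_pixels × n_peaks) block."""
    sections = []
    n_peaks = np.asarray(intensity_blocks[0]).shape[1]
    mz = np.asarray(mz, dtype=float) if mz is not None else 300.5 + np.arange(n_peaks)
    for i, block in enumerate(intensity_blocks):
        block = np.asarray(block, dtype=float)
        n = block.shape[0]
        coords = np.column_stack([np.arange(n) // grid[1], np.arange(n) % grid[1]])
        sections.append(SectionImage("P01", f"S{i + 1:02d}", coords, block,
                                     grid_shape=grid))
    return Study(sections, MzAxis(mz))
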