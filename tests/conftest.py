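"""Shared fixtures: synthetic mosaics, lattices, and the one scaled training
run that the learning-sanity and end-to-end detection tests both consume."""

from __future__ import annotations

import numpy as np
import pytest

from foveamap import fcn
from foveamap.core import ConeSet, ValidityMask
from foveamap.preprocess import PatchSet, distance_label, erode_mask, random_crops
from foveamap.synthetic_mosaic import MosaicSpec, generate_positions, make_dataset, render


def hex_lattice(spacing: float, nx: int, ny: int, origin: float = 0.0) -> np.ndarray:
    """Perfect hexagonal lattice: rows spaced by sqrt(3)/2 * spacing, odd rows
    shifted by spacing/2."""
    pts = []
    for row in range(ny):
        y = origin + row * spacing * np.sqrt(3) / 2
        xoff = (row % 2) * spacing / 2
        for col in range(nx):
            pts.append((origin + xoff + col * spacing, y))
    return np.asarray(pts)


@pytest.fixture(scope="session")
def flat_spec() -> MosaicSpec:
    """Flat-density mosaic spec: peak == base forces uniform density."""
    return MosaicSpec(field_size_px=(220, 220), scale_px_per_deg=600.0,
                      peak_density_deg2=8000.0, base_density_deg2=8000.0,
                      falloff_scale_deg=0.5, seed=7)


@pytest.fixture(scope="session")
def flat_positions(flat_spec) -> ConeSet:
    return generate_positions(flat_spec)


@pytest.fixture(scope="session")
def flat_sample(flat_spec, flat_positions):
    return render(flat_positions, flat_spec)


@pytest.fixture(scope="session")
def trained_state():
    """Scaled training run shared across tests.

    30 training mosaics + 5 held-out, ~200 crops of 64x64, 25 epochs. Returns
    (TrainState, held-out samples).
    """
    spec = MosaicSpec(field_size_px=(160, 160), seed=0)
    samples = make_dataset(35, spec, seed=123)
    train_samples, test_samples = samples[:30], samples[30:]
    patches = []
    for i, s in enumerate(train_samples):
        label = distance_label(s.cones, s.image.shape)
        mask = erode_mask(ValidityMask(np.ones(s.image.shape, bool)), 8)
        ps = random_crops(s.image, label, mask, n=7, size=64, seed=1000 + i)
        patches.extend(ps.patches)
    n_val = len(patches) // 5  # 80:20 split
    train_set = PatchSet(patches=patches[:-n_val], size=64)
    val_set = PatchSet(patches=patches[-n_val:], size=64)
    model = fcn.build_model(fcn.FCNConfig(in_size=64, base_filters=8), seed=0)
    state = fcn.train(model, train_set, val_set,
                      fcn.TrainConfig(epochs=25, seed=0))
    return state, test_samples
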