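import numpy as np
import pytest

from seedmorph import (
    SeedShapeParams,
    arc_band_silhouette,
    builtin_species_cards,
    sample_trait_table,
)

#: renderable parameter sets spanning the curvature range, reused across tests
ROUND_TRIP_PARAMS = [
    SeedShapeParams(600, 200, 0, n_pits=22, seed_id="straight"),
    SeedShapeParams(600, 200, 60, n_pits=10, seed_id="slight"),
    SeedShapeParams(600, 200, 150, n_pits=35, seed_id="curved"),
    SeedShapeParams(700, 180, 270, n_pits=22, seed_id="ushape"),
    SeedShapeParams(900, 100, 320, n_pits=15, seed_id="horseshoe"),
]


@pytest.fixture(scope="session")
def cards():
    return builtin_species_cards()


@pytest.fixture(scope="session")
def trait_table(cards):
    """Synthetic 10-species table, 30 seeds per species, fixed seed."""
    return sample_trait_table(cards, n_per_species=30, rng_seed=11)


@pytest.fixture(scope="session")
def rendered():
    """Rendered silhouettes for ROUND_TRIP_PARAMS at 2 µm/px."""
    return [arc_band_silhouette(p, pixel_size=2.0) for p in ROUND_TRIP_PARAMS]


def random_renderable_params(rng: np.random.Generator, margin: float = 1.15):
    """Draw arc-band parameters guaranteed renderable (with margin)."""
    while True:
        L = rng.uniform(420.0, 900.0)
        gamma = rng.uniform(0.0, 330.0)
        w_max = 0.45 * L
        if gamma >= 1.0:
            r = L * 180.0 / (gamma * np.pi)
            w_max = min(w_max, 2.0 * r / margin)
            if gamma > 180.0:
                chord = 2.0 * r * np.sin(np.radians((360.0 - gamma) / 2.0))
                w_max = min(w_max, chord / margin)
        if w_max < 0.15 * L:
            continue
        w = rng.uniform(0.15 * L, w_max)
        n_pits = int(rng.integers(1, max(int(L / 12.0), 2)))
        return SeedShapeParams(L, w, gamma, n_pits=min(n_pits, 40))
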