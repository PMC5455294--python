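"""Built-in reference data for the ten European *Elatine* species.

Three datasets from the published seed-morphometric survey of the genus are
shipped as plain Python structures:

* :func:`builtin_species_cards` — the per-species trait ranges of the printed
  species descriptions, in the "(outlier-min–)q25–q75(–outlier-max)"
  whisker convention (1.5·IQR outlier fences);
* :func:`builtin_populations` — the 28 studied populations with coordinates
  and sample sizes;
* :func:`reference_classification_counts` — the two published resubstitution
  classification matrices of the species-level discriminant analysis
  (variant "three_trait": rectangle a, angle, pits; variant "six_trait":
  all six descriptors).

Where a description prints no lower outlier bound (brochonii, triandra and
alsinastrum angles; gussonei pits), the card stores outlier_min = q25.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import SpeciesRangeCard

SPECIES = (
    "E. alsinastrum",
    "E. brochonii",
    "E. campylosperma",
    "E. gussonei",
    "E. hexandra",
    "E. hungarica",
    "E. hydropiper",
    "E. macropoda",
    "E. orthosperma",
    "E. triandra",
)

_CARDS = (
    SpeciesRangeCard(
        "E. alsinastrum",
        length=(708, 799, 859, 950),
        width=(230, 290, 330, 391),
        angle=(33, 33, 56, 91),
        pits=(18, 21, 23, 26),
        pit_shape="rectangular",
        membrane=False,
    ),
    SpeciesRangeCard(
        "E. brochonii",
        length=(365, 533, 645, 813),
        width=(217, 252, 276, 312),
        angle=(26, 26, 47, 79),
        pits=(12, 14, 15, 17),
        pit_shape="hexagonal",
        membrane=False,
    ),
    SpeciesRangeCard(
        "E. campylosperma",
        length=(439, 505, 549, 615),
        width=(274, 419, 517, 663),
        angle=(222, 265, 294, 337),
        pits=(15, 31, 42, 59),
        pit_shape="round",
        membrane=True,
    ),
    SpeciesRangeCard(
        "E. gussonei",
        length=(539, 627, 685, 774),
        width=(325, 436, 509, 620),
        angle=(80, 180, 247, 347),
        pits=(17, 17, 23, 32),
        pit_shape="hexagonal",
        membrane=True,
    ),
    SpeciesRangeCard(
        "E. hexandra",
        length=(593, 656, 697, 760),
        width=(223, 283, 322, 381),
        angle=(15, 77, 118, 180),
        pits=(16, 19, 21, 24),
        pit_shape="hexagonal",
        membrane=False,
    ),
    SpeciesRangeCard(
        "E. hungarica",
        length=(296, 459, 567, 730),
        width=(284, 357, 405, 477),
        angle=(161, 213, 247, 299),
        pits=(11, 20, 26, 35),
        pit_shape="hexagonal",
        membrane=True,
    ),
    SpeciesRangeCard(
        "E. hydropiper",
        length=(548, 602, 638, 693),
        width=(367, 454, 512, 599),
        angle=(246, 273, 291, 318),
        pits=(22, 37, 48, 62),
        pit_shape="rectangular",
        membrane=True,
    ),
    SpeciesRangeCard(
        "E. macropoda",
        length=(568, 666, 732, 830),
        width=(282, 329, 360, 407),
        angle=(78, 111, 134, 167),
        pits=(13, 19, 23, 29),
        pit_shape="rectangular",
        membrane=False,
    ),
    SpeciesRangeCard(
        "E. orthosperma",
        length=(658, 776, 854, 971),
        width=(242, 297, 334, 389),
        angle=(55, 61, 99, 156),
        pits=(23, 32, 38, 47),
        pit_shape="rectangular",
        membrane=False,
    ),
    SpeciesRangeCard(
        "E. triandra",
        length=(328, 467, 560, 700),
        width=(158, 201, 231, 274),
        angle=(58, 58, 89, 136),
        pits=(16, 20, 23, 28),
        pit_shape="network",
        membrane=False,
    ),
)


def builtin_species_cards() -> list[SpeciesRangeCard]:
    """The ten published species range cards, ordered alphabetically by species."""
    return list(_CARDS)


def card(species: str) -> SpeciesRangeCard:
    """Look up a built-in card by species name ("E. hydropiper" or "hydropiper")."""
    name = species if species.startswith("E.") else f"E. {species}"
    for c in _CARDS:
        if c.species == name:
            return c
    raise KeyError(f"no built-in card for {species!r}")


# acronym, species, latitude, longitude, n_seeds (published population table)
_POPULATIONS = [
    ("alsHU", "E. alsinastrum", 47.31, 21.67, 50),
    ("alsPL1", "E. alsinastrum", 50.80, 23.03, 50),
    ("alsPL2", "E. alsinastrum", 53.01, 14.54, 50),
    ("broMO", "E. brochonii", 33.62, -7.07, 44),
    ("broSP", "E. brochonii", 37.40, -7.36, 49),
    ("camIT", "E. campylosperma", 39.73, 9.03, 47),
    ("camSP", "E. campylosperma", 37.12, -6.49, 50),
    ("gusMAL", "E. gussonei", 36.01, 14.25, 50),
    ("gusSP", "E. gussonei", 39.33, -6.25, 50),
    ("gusIT", "E. gussonei", 36.76, 14.77, 50),
    ("hexPL1", "E. hexandra", 51.57, 14.96, 33),
    ("hexPL2", "E. hexandra", 51.55, 17.35, 50),
    ("hexPL3", "E. hexandra", 51.53, 17.34, 50),
    ("hunRUS", "E. hungarica", 49.76, 45.70, 42),
    ("hunSLO", "E. hungarica", 47.78, 17.88, 24),
    ("hunHU", "E. hungarica", 47.31, 21.67, 50),
    ("hydHU", "E. hydropiper", 47.36, 20.52, 39),
    ("hydPL1", "E. hydropiper", 51.38, 15.23, 45),
    ("hydPL2", "E. hydropiper", 54.02, 16.69, 43),
    ("macIT", "E. macropoda", 40.63, 8.41, 50),
    ("macSP1", "E. macropoda", 39.19, -6.29, 46),
    ("macSP2", "E. macropoda", 39.38, 2.77, 42),
    ("ortCZ", "E. orthosperma", 49.02, 15.15, 45),
    ("ortFI1", "E. orthosperma", 61.23, 22.23, 25),
    ("ortFI2", "E. orthosperma", 65.06, 25.47, 50),
    ("triHU", "E. triandra", 47.50, 20.50, 41),
    ("triPL1", "E. triandra", 51.57, 14.96, 47),
    ("triPL2", "E. triandra", 54.01, 16.82, 50),
]


def builtin_populations() -> pd.DataFrame:
    """The 28 studied populations: acronym, species, coordinates, seed count."""
    return pd.DataFrame(
        _POPULATIONS,
        columns=["acronym", "species", "latitude", "longitude", "n_seeds"],
    )


# Published species-level resubstitution classification counts
# (rows = true species, columns = assigned species, order = SPECIES).
_COUNTS_THREE_TRAIT = [
    # als bro cam gus hex hun hyd mac ort tri
    [144, 1, 0, 0, 3, 0, 0, 2, 0, 0],
    [1, 87, 0, 0, 5, 0, 0, 0, 0, 0],
    [0, 0, 55, 0, 0, 17, 25, 0, 0, 0],
    [0, 0, 1, 126, 0, 1, 4, 16, 0, 0],
    [1, 1, 0, 0, 105, 0, 0, 26, 0, 0],
    [0, 0, 1, 16, 0, 99, 0, 0, 0, 0],
    [0, 0, 6, 2, 0, 0, 119, 0, 0, 0],
    [5, 0, 0, 0, 17, 0, 0, 115, 0, 1],
    [4, 0, 0, 0, 1, 0, 0, 1, 114, 0],
    [0, 1, 0, 0, 15, 1, 0, 0, 0, 121],
]

_COUNTS_SIX_TRAIT = [
    [145, 1, 0, 0, 4, 0, 0, 0, 0, 0],
    [1, 86, 0, 0, 5, 0, 0, 0, 0, 1],
    [0, 0, 53, 0, 0, 16, 28, 0, 0, 0],
    [0, 0, 1, 115, 0, 3, 6, 23, 0, 0],
    [1, 2, 0, 0, 95, 0, 0, 35, 0, 0],
    [0, 0, 1, 20, 0, 95, 0, 0, 0, 0],
    [0, 0, 5, 1, 0, 0, 121, 0, 0, 0],
    [5, 0, 0, 1, 24, 0, 0, 107, 0, 1],
    [6, 0, 0, 0, 1, 0, 0, 1, 112, 0],
    [0, 1, 0, 0, 9, 1, 0, 2, 0, 125],
]


def reference_classification_counts(variant: str = "three_trait") -> pd.DataFrame:
    """Published species-level classification-count matrix.

    variant "three_trait": discriminants on rectangle a, curvature angle and
    pit count; "six_trait": all six descriptors. Rows are true species,
    columns assigned species; row sums are the per-species seed counts
    (1,260 seeds in total).
    """
    try:
        counts = {"three_trait": _COUNTS_THREE_TRAIT, "six_trait": _COUNTS_SIX_TRAIT}[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}") from None
    return pd.DataFrame(
        np.array(counts, dtype=int), index=list(SPECIES), columns=list(SPECIES)
    )
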