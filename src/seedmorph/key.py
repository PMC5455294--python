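"""Executable dichotomous identification key for European *Elatine* seeds.

The printed guide identifies the ten species from four seed descriptors —
curvature angle, middle-row pit count, length (rectangle a) and width
(rectangle b) — through ten numbered couplets. The key here is data, not
code: each couplet is a declarative record (trait, comparator, threshold,
outcomes), so alternative keys can be loaded and traversed by the same
engine.

One printed gap is handled explicitly: couplet 4 sends pits < 17 to
*E. brochonii* and pits >= 18 to *E. triandra*, leaving pits = 17
unassigned; consistently with couplet 5's "<= 17", 17 is routed to
*E. brochonii* and the decision path carries a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import KeyTraversalError
from .synthetic import SpeciesRangeCard

#: key-trait name -> trait-table column
KEY_TRAITS = {
    "angle": "angle_deg",
    "pits": "pits",
    "length": "rectangle_a_um",
    "width": "rectangle_b_um",
}

_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
}


@dataclass(frozen=True)
class KeyCouplet:
    """One couplet: a threshold predicate and its two outcomes.

    Outcomes are either a species name (str) or the number of the next
    couplet (int). `gap` optionally marks a half-open value interval the
    printed predicates leave unassigned, with the outcome it is routed to.
    """

    number: int
    trait: str  # one of KEY_TRAITS
    op: str
    threshold: float
    if_true: int | str
    if_false: int | str
    gap: tuple[float, float, int | str, str] | None = None  # (lo, hi, outcome, warning)

    def predicate_text(self) -> str:
        return f"{self.trait} {self.op} {self.threshold:g}"


@dataclass(frozen=True)
class IdKey:
    """Ordered couplets with entry point 1; validated acyclic and complete."""

    couplets: tuple[KeyCouplet, ...]
    entry: int = 1

    def __post_init__(self) -> None:
        by_num = {c.number: c for c in self.couplets}
        if len(by_num) != len(self.couplets):
            raise ValueError("duplicate couplet numbers")
        # acyclicity + reachability by DFS from the entry couplet
        seen_species: set[str] = set()
        stack: set[int] = set()

        def visit(num: int) -> None:
            if num in stack:
                raise ValueError(f"cycle through couplet {num}")
            if num not in by_num:
                raise ValueError(f"couplet {num} referenced but not defined")
            stack.add(num)
            c = by_num[num]
            outcomes = [c.if_true, c.if_false] + ([c.gap[2]] if c.gap else [])
            for out in outcomes:
                if isinstance(out, int):
                    visit(out)
                else:
                    seen_species.add(out)
            stack.discard(num)

        visit(self.entry)
        object.__setattr__(self, "_species", frozenset(seen_species))

    @property
    def species(self) -> frozenset[str]:
        return self._species

    def couplet(self, number: int) -> KeyCouplet:
        for c in self.couplets:
            if c.number == number:
                return c
        raise KeyError(number)


_BUILTIN = (
    KeyCouplet(1, "angle", "<", 150, 2, 8),
    KeyCouplet(2, "pits", ">=", 30, "E. orthosperma", 3),
    KeyCouplet(3, "length", "<", 600, 4, 5),
    KeyCouplet(
        4, "pits", "<", 17, "E. brochonii", "E. triandra",
        gap=(
            17.0, 18.0, "E. brochonii",
            "pits = 17 is unassigned by couplet 4; routed to E. brochonii "
            "consistently with couplet 5",
        ),
    ),
    KeyCouplet(5, "pits", "<=", 17, "E. brochonii", 6),
    KeyCouplet(6, "angle", "<=", 60, "E. alsinastrum", 7),
    KeyCouplet(7, "width", ">=", 320, "E. macropoda", "E. hexandra"),
    KeyCouplet(8, "pits", ">=", 30, 9, 10),
    KeyCouplet(9, "length", "<", 600, "E. campylosperma", "E. hydropiper"),
    KeyCouplet(10, "length", "<=", 600, "E. hungarica", "E. gussonei"),
)


def builtin_key() -> IdKey:
    """The printed ten-couplet key, thresholds exactly as published."""
    return IdKey(couplets=_BUILTIN)


# ---------------------------------------------------------------------------
# traversal
# ---------------------------------------------------------------------------


@dataclass
class KeyDecision:
    species: str
    path: list = field(default_factory=list)  # (couplet number, predicate text, bool)
    warnings: list = field(default_factory=list)


def _trait_values(tv) -> dict[str, float]:
    """Accept a TraitVector, mapping or Series; return the four key traits."""
    if hasattr(tv, "as_dict"):
        tv = tv.as_dict()
    elif isinstance(tv, pd.Series):
        tv = tv.to_dict()
    out = {}
    for name, col in KEY_TRAITS.items():
        val = tv.get(col, tv.get(name))
        if val is None or (isinstance(val, float) and np.isnan(val)):
            raise KeyTraversalError(f"trait {name!r} ({col}) missing or NaN")
        out[name] = float(val)
    return out


def classify_traits(tv, key: IdKey | None = None) -> KeyDecision:
    """Run one trait vector through the key; returns species + decision path."""
    key = key or builtin_key()
    vals = _trait_values(tv)
    decision = KeyDecision(species="")
    current: int | str = key.entry
    while isinstance(current, int):
        c = key.couplet(current)
        x = vals[c.trait]
        if c.gap is not None and c.gap[0] <= x < c.gap[1]:
            decision.path.append((c.number, f"{c.trait} = {x:g} (gap)", None))
            decision.warnings.append(c.gap[3])
            current = c.gap[2]
            continue
        result = bool(_OPS[c.op](x, c.threshold))
        decision.path.append((c.number, c.predicate_text(), result))
        current = c.if_true if result else c.if_false
    decision.species = current
    return decision


class KeyClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-compatible wrapper around the dichotomous key.

    `fit` only records the key and the class labels (the key itself is
    fixed, published knowledge); `predict` traverses it per row. X may be a
    trait-table DataFrame or an array with columns (length, width, angle,
    pits) in `feature_order`.
    """

    def __init__(self, key: IdKey | None = None):
        self.key = key

    feature_order = ("rectangle_a_um", "rectangle_b_um", "angle_deg", "pits")

    def fit(self, X=None, y=None):
        self.key_ = self.key or builtin_key()
        self.classes_ = np.array(sorted(self.key_.species))
        return self

    def predict(self, X):
        if not hasattr(self, "key_"):
            self.fit()
        if isinstance(X, pd.DataFrame):
            rows = (row for _, row in X.iterrows())
        else:
            X = np.asarray(X, dtype=float)
            rows = (dict(zip(self.feature_order, r)) for r in X)
        return np.array([classify_traits(r, self.key_).species for r in rows])


# ---------------------------------------------------------------------------
# key vs. description cross-checks
# ---------------------------------------------------------------------------


def key_selfconsistency(
    cards: list[SpeciesRangeCard] | None = None, key: IdKey | None = None
) -> pd.DataFrame:
    """Classify every card's core midpoints through the key.

    Returns one row per species (sorted by name) with the assigned species,
    a match flag and the decision path; the `matches` attribute-style count
    is the sum of the flag column.
    """
    from .datasets import builtin_species_cards

    cards = cards if cards is not None else builtin_species_cards()
    key = key or builtin_key()
    rows = []
    for card in sorted(cards, key=lambda c: c.species):
        decision = classify_traits(card.midpoints(), key)
        rows.append(
            {
                "species": card.species,
                "assigned": decision.species,
                "match": decision.species == card.species,
                "path": "->".join(str(step[0]) for step in decision.path),
            }
        )
    return pd.DataFrame(rows)


def range_compatibility(
    tv, cards: list[SpeciesRangeCard] | None = None
) -> pd.DataFrame:
    """Score a trait vector against every species' printed ranges.

    Per species each of the four key traits scores 1 inside the [q25, q75]
    core, 0.5 inside the outlier quartet but outside the core, else 0; the
    species score is the mean. Species are ranked descending; exact score
    ties are flagged, broken alphabetically. A seed outside every quartet
    everywhere gets an explicit no-match flag on all rows.
    """
    from .datasets import builtin_species_cards

    cards = cards if cards is not None else builtin_species_cards()
    vals = _trait_values(tv)
    rows = []
    for card in cards:
        per_trait = {}
        for trait in ("length", "width", "angle", "pits"):
            lo, q25, q75, hi = getattr(card, trait)
            x = vals[trait]
            if q25 <= x <= q75:
                per_trait[trait] = 1.0
            elif lo <= x <= hi:
                per_trait[trait] = 0.5
            else:
                per_trait[trait] = 0.0
        rows.append({"species": card.species, **per_trait,
                     "score": float(np.mean(list(per_trait.values())))})
    out = pd.DataFrame(rows).sort_values(
        ["score", "species"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = out["score"].rank(method="min", ascending=False).astype(int)
    out["tied"] = out.duplicated("score", keep=False)
    out["no_match"] = bool((out["score"] == 0).all())
    return out


def confused_pairs(truth, predicted) -> pd.DataFrame:
    """Unordered species-pair confusion counts, sorted descending.

    Counts every misclassified seed toward the unordered pair
    {true species, assigned species}; used to find which species the key
    (or a classifier) mixes up most.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    counts: dict[tuple[str, str], int] = {}
    for t, p in zip(truth, predicted):
        if t == p:
            continue
        pair = tuple(sorted((str(t), str(p))))
        counts[pair] = counts.get(pair, 0) + 1
    rows = [
        {"species_a": a, "species_b": b, "count": c}
        for (a, b), c in counts.items()
    ]
    return (
        pd.DataFrame(rows, columns=["species_a", "species_b", "count"])
        .sort_values(["count", "species_a", "species_b"], ascending=[False, True, True])
        .reset_index(drop=True)
    )
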