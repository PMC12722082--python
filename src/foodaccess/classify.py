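"""Rule-based coding of food outlets into five mutually exclusive groups.

Outlets are first typed as ``restaurant``, ``grocery`` or ``neither`` from
their category lists (with an ``excluded`` bucket for non-food or
location-less businesses), then labelled by content as majority-AAPI
(``aapi``) or ``non_aapi``. Categories that are generic enough to cover
either content (e.g. "grocery", "herbs & spices") are ``ambiguous`` and must
be resolved through an explicit per-outlet resolution map, which externalizes
the manual web review such a coding would otherwise require — making the
review auditable and reproducible.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

TYPE_LABELS = ("restaurant", "grocery", "neither", "excluded")
CONTENT_LABELS = ("aapi", "non_aapi", "ambiguous", "unset")
GROUP_NAMES = (
    "aapi_restaurants",
    "non_aapi_restaurants",
    "aapi_groceries",
    "non_aapi_groceries",
    "neither",
)

_REQUIRED_GROCERY_KEYWORDS = {
    "grocery",
    "farmer's market",
    "food market",
    "health market",
}


class ClassificationError(ValueError):
    pass


class UnresolvedAmbiguityError(ClassificationError):
    """Ambiguous outlets without a resolution entry; carries their ids."""

    def __init__(self, outlet_ids):
        self.outlet_ids = list(outlet_ids)
        super().__init__(
            "ambiguous outlets lack a resolution entry: "
            + ", ".join(map(str, self.outlet_ids))
        )


def normalize_category(cat: str) -> str:
    """Lowercase and collapse internal whitespace."""
    return re.sub(r"\s+", " ", cat.strip().lower())


@dataclass(frozen=True)
class Lexicon:
    restaurant_categories: frozenset
    grocery_keywords: frozenset
    aapi_categories: frozenset
    non_aapi_categories: frozenset
    ambiguous_categories: frozenset
    excluded_categories: frozenset = frozenset()

    def __post_init__(self):
        for name in (
            "restaurant_categories",
            "grocery_keywords",
            "aapi_categories",
            "non_aapi_categories",
            "ambiguous_categories",
            "excluded_categories",
        ):
            vals = frozenset(normalize_category(c) for c in getattr(self, name))
            object.__setattr__(self, name, vals)
        pairs = [
            ("aapi_categories", "non_aapi_categories"),
            ("aapi_categories", "ambiguous_categories"),
            ("non_aapi_categories", "ambiguous_categories"),
        ]
        for a, b in pairs:
            inter = getattr(self, a) & getattr(self, b)
            if inter:
                raise ClassificationError(
                    f"{a} and {b} overlap: {sorted(inter)}"
                )
        missing = _REQUIRED_GROCERY_KEYWORDS - self.grocery_keywords
        if missing:
            raise ClassificationError(
                f"grocery_keywords must include {sorted(missing)}"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "Lexicon":
        return cls(
            restaurant_categories=frozenset(d.get("restaurant_categories", ())),
            grocery_keywords=frozenset(d.get("grocery_keywords", ())),
            aapi_categories=frozenset(d.get("aapi_categories", ())),
            non_aapi_categories=frozenset(d.get("non_aapi_categories", ())),
            ambiguous_categories=frozenset(d.get("ambiguous_categories", ())),
            excluded_categories=frozenset(d.get("excluded_categories", ())),
        )

    @classmethod
    def from_json(cls, path) -> "Lexicon":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls) -> "Lexicon":
        """The shipped lexicon: covers common category vocabulary and the
        documented rule examples; users extend it for real registries."""
        ref = resources.files("foodaccess.data").joinpath("default_lexicon.json")
        return cls.from_dict(json.loads(ref.read_text()))

    def with_aapi_category(self, cat: str) -> "Lexicon":
        cat = normalize_category(cat)
        return Lexicon(
            restaurant_categories=self.restaurant_categories,
            grocery_keywords=self.grocery_keywords,
            aapi_categories=self.aapi_categories | {cat},
            non_aapi_categories=self.non_aapi_categories - {cat},
            ambiguous_categories=self.ambiguous_categories - {cat},
            excluded_categories=self.excluded_categories,
        )


def assign_type(categories: Iterable[str], lexicon: Lexicon) -> str:
    """Type label with precedence excluded > restaurant > grocery > neither.

    Restaurant/excluded matching is exact on the controlled category
    vocabulary; grocery matching is substring containment of any grocery
    keyword, so "asian grocery store" types as grocery.
    """
    cats = [normalize_category(c) for c in categories]
    if not cats:
        raise ClassificationError("empty category list")
    if any(c in lexicon.excluded_categories for c in cats):
        return "excluded"
    if any(c in lexicon.restaurant_categories for c in cats):
        return "restaurant"
    if any(kw in c for c in cats for kw in lexicon.grocery_keywords):
        return "grocery"
    return "neither"


def assign_content(categories: Iterable[str], lexicon: Lexicon) -> str:
    """Content label with precedence aapi > ambiguous > non_aapi.

    A single clearly AAPI category makes the outlet AAPI regardless of
    co-occurring general terms (majority-AAPI-food intent)."""
    cats = [normalize_category(c) for c in categories]
    if not cats:
        raise ClassificationError("empty category list")
    if any(c in lexicon.aapi_categories for c in cats):
        return "aapi"
    if any(c in lexicon.ambiguous_categories for c in cats):
        return "ambiguous"
    return "non_aapi"


def classify_outlets(
    outlets: pd.DataFrame,
    lexicon: Lexicon,
    resolutions: Mapping | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Partition outlets into the five mutually exclusive groups.

    Parameters
    ----------
    outlets
        DataFrame with at least ``outlet_id`` and ``categories`` (a list of
        strings per row, or a pipe-delimited string).
    resolutions
        outlet_id -> {"aapi", "non_aapi"} map for outlets whose categories
        are content-ambiguous. Required for every ambiguous outlet that is a
        restaurant or grocery.

    Returns
    -------
    (classified, counts)
        ``classified`` is a copy of the input with ``type_label``,
        ``content_label`` and ``group`` columns; ``counts`` maps each group
        name (plus ``excluded``) to its size.
    """
    resolutions = dict(resolutions or {})
    for oid, lab in resolutions.items():
        if lab not in ("aapi", "non_aapi"):
            raise ClassificationError(
                f"resolution for {oid!r} must be 'aapi' or 'non_aapi', got {lab!r}"
            )
    out = outlets.copy()
    cats = out["categories"].map(
        lambda c: c.split("|") if isinstance(c, str) else list(c)
    )
    out["type_label"] = cats.map(lambda c: assign_type(c, lexicon))
    out["content_label"] = cats.map(lambda c: assign_content(c, lexicon))

    # every non-excluded ambiguous outlet must be reviewed, mirroring the
    # mandatory manual step; excluded outlets are dropped before review
    needs_resolution = out["content_label"].eq("ambiguous") & out[
        "type_label"
    ].ne("excluded")
    unresolved = [
        oid
        for oid in out.loc[needs_resolution, "outlet_id"]
        if oid not in resolutions
    ]
    if unresolved:
        raise UnresolvedAmbiguityError(unresolved)
    resolved = out.loc[needs_resolution, "outlet_id"].map(resolutions)
    out.loc[needs_resolution, "content_label"] = resolved

    def _group(row):
        t, c = row["type_label"], row["content_label"]
        if t == "excluded":
            return "excluded"
        if t == "neither":
            return "neither"
        kind = "restaurants" if t == "restaurant" else "groceries"
        prefix = "aapi" if c == "aapi" else "non_aapi"
        return f"{prefix}_{kind}"

    out["group"] = out.apply(_group, axis=1)
    counts = {g: int((out["group"] == g).sum()) for g in GROUP_NAMES}
    counts["excluded"] = int((out["group"] == "excluded").sum())
    return out, counts


def read_resolutions(path) -> dict:
    """Two-column CSV (outlet_id, content_label) -> resolution map."""
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
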