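"""ADME screening of herbal-formula ingredient tables.

Each ingredient of a multi-herb formula carries two pharmacokinetic
screening axes: oral bioavailability (OB, in percent) and drug-likeness
(DL, a unitless index in [0, 1]).  Compounds passing both thresholds —
the conventional OB >= 33 % and DL >= 0.18 cut-offs used with TCMSP-style
ingredient exports — are considered "active ingredients" and feed the
downstream target-mapping stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

DEFAULT_OB_MIN = 33.0
DEFAULT_DL_MIN = 0.18


class ValidationError(ValueError):
    """Raised when an input record violates its schema or invariants."""


@dataclass(frozen=True)
class Ingredient:
    """One herbal compound with its ADME attributes.

    Parameters
    ----------
    mol_id : str
        Molecule identifier, e.g. ``"MOL000211"``.
    name : str
        Free-text molecule name.
    ob : float
        Oral bioavailability on the percent scale (33 means 33 %).
    dl : float
        Drug-likeness index, unitless in [0, 1].
    herb : str
        Label of the herb the record was listed under.  The same mol_id
        may recur under different herbs; (mol_id, herb) is the unit of
        identity within a formulary.
    """

    mol_id: str
    name: str
    ob: float
    dl: float
    herb: str

    def __post_init__(self) -> None:
        if not self.mol_id:
            raise ValidationError("ingredient with empty mol_id")
        for attr in ("ob", "dl"):
            v = getattr(self, attr)
            if not isinstance(v, (int, float)) or isinstance(v, bool) or not math.isfinite(v):
                raise ValidationError(f"{self.mol_id}: non-numeric {attr} value {v!r}")
            if v < 0:
                raise ValidationError(f"{self.mol_id}: negative {attr} value {v!r}")


@dataclass(frozen=True)
class Formulary:
    """An ordered collection of herbs and their ingredient records."""

    herbs: tuple[str, ...]
    ingredients: tuple[Ingredient, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        herb_set = set(self.herbs)
        seen: set[tuple[str, str]] = set()
        for ing in self.ingredients:
            if ing.herb not in herb_set:
                raise ValidationError(
                    f"{ing.mol_id}: herb {ing.herb!r} not declared in formulary"
                )
            key = (ing.mol_id, ing.herb)
            if key in seen:
                raise ValidationError(f"duplicate (mol_id, herb) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.ingredients)

    def for_herb(self, herb: str) -> tuple[Ingredient, ...]:
        if herb not in self.herbs:
            raise KeyError(f"unknown herb {herb!r}")
        return tuple(i for i in self.ingredients if i.herb == herb)


def screen_ingredients(
    formulary: Formulary,
    ob_min: float = DEFAULT_OB_MIN,
    dl_min: float = DEFAULT_DL_MIN,
) -> Formulary:
    """Apply the OB/DL ADME screen, keeping ingredients passing both.

    Both comparisons are inclusive (``ob >= ob_min and dl >= dl_min``).
    Input order is preserved; the input formulary is not modified.
    """
    for label, t in (("ob_min", ob_min), ("dl_min", dl_min)):
        if not math.isfinite(t) or t < 0:
            raise ValidationError(f"{label} must be finite and non-negative, got {t!r}")
    kept = tuple(i for i in formulary.ingredients if i.ob >= ob_min and i.dl >= dl_min)
    return replace(formulary, ingredients=kept)


def per_herb_counts(formulary: Formulary) -> dict[str, int]:
    """Count ingredient records per herb (shared molecules count once per herb)."""
    counts = {h: 0 for h in formulary.herbs}
    for ing in formulary.ingredients:
        counts[ing.herb] += 1
    return counts


def load_reference_formulary() -> Formulary:
    """Load the packaged YuPingFeng ingredient table (41 records, 3 herbs).

    These are the printed per-herb ingredient records of the formula's
    three herbs — Radix Astragali (Huangqi), Radix Saposhnikoviae
    (Fangfeng) and Rhizoma Atractylodis Macrocephalae (Baizhu) — already
    expressed in the screening dialect (OB in percent, DL unitless).
    """
    from .io import read_ingredient_table

    with resources.as_file(
        resources.files("netpharm.data").joinpath("ypf_ingredients.tsv")
    ) as p:
        return read_ingredient_table(p)
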