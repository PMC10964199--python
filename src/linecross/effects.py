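"""Composite genetic effect vocabulary.

A composite genetic effect aggregates, over all loci that differ between
the two crossed lines, the net contribution of one mode of gene action
(additive, dominance, or a digenic epistatic interaction) acting through
one part of the inheritance system (autosomes, the maternal parent's
genotype, or the cytoplasm).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CompositeEffect",
    "EFFECTS",
    "REDUCED_EFFECTS",
    "FULL_EFFECTS",
    "classify_effect",
]


@dataclass(frozen=True)
class CompositeEffect:
    """One composite genetic effect.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"Aa"`` (autosomal additive) or ``"AaAd"``
        (additive-by-dominance epistasis).
    effect_class : str
        ``"additive"``, ``"dominance"`` or ``"epistatic"``.
    scope : str
        ``"autosomal"``, ``"maternal"`` or ``"cytotype"``.
    """

    name: str
    effect_class: str
    scope: str

    def __post_init__(self) -> None:
        if self.effect_class not in {"additive", "dominance", "epistatic"}:
            raise ValueError(f"unknown effect class: {self.effect_class!r}")
        if self.scope not in {"autosomal", "maternal", "cytotype"}:
            raise ValueError(f"unknown effect scope: {self.scope!r}")
        # digenic interactions are epistatic by definition
        if _is_digenic(self.name) and self.effect_class != "epistatic":
            raise ValueError(f"digenic effect {self.name!r} must be epistatic")


def _is_digenic(name: str) -> bool:
    return name in {"AaAa", "AaAd", "AdAd"}


#: Full effect vocabulary (parent sexes known: maternal and cytoplasmic
#: effects are identifiable from reciprocal crosses).
EFFECTS: dict[str, CompositeEffect] = {
    e.name: e
    for e in (
        CompositeEffect("Aa", "additive", "autosomal"),
        CompositeEffect("Ad", "dominance", "autosomal"),
        CompositeEffect("AaAa", "epistatic", "autosomal"),
        CompositeEffect("AaAd", "epistatic", "autosomal"),
        CompositeEffect("AdAd", "epistatic", "autosomal"),
        CompositeEffect("Ma", "additive", "maternal"),
        CompositeEffect("Md", "dominance", "maternal"),
        CompositeEffect("Ca", "additive", "cytotype"),
    )
}

#: Reduced vocabulary used when parental sex is unreported: additive,
#: dominance, and the three digenic epistatic interactions.
REDUCED_EFFECTS: tuple[str, ...] = ("Aa", "Ad", "AaAa", "AaAd", "AdAd")

#: Full vocabulary in canonical column order.
FULL_EFFECTS: tuple[str, ...] = (
    "Aa",
    "Ad",
    "AaAa",
    "AaAd",
    "AdAd",
    "Ma",
    "Md",
    "Ca",
)


def classify_effect(name: str) -> str:
    """Return the pooling class (``additive``/``dominance``/``epistatic``).

    Maternal additive and cytotype effects pool with additive, maternal
    dominance with dominance, and every digenic interaction with epistasis:
    the pooling follows the mode of gene action, not the genomic scope.
    """
    try:
        return EFFECTS[name].effect_class
    except KeyError:
        raise ValueError(f"unknown composite effect: {name!r}") from None
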