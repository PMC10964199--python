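"""Reduce averaged effects to additive/dominance/epistasis proportions.

Composite effects take signs that depend on the arbitrary choice of which
parental line is P1, so effects are pooled by mode of gene action on their
absolute values: each class sum of |significant estimates| is divided by
the grand sum, giving per-dataset proportions on a common 0-1 scale (the
coordinates of the ternary "architecture" plot).  Datasets in which no
effect passes the significance gate are flagged uninformative and carry no
proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

from .effects import classify_effect

if TYPE_CHECKING:  # pragma: no cover
    from .engine import AveragedArchitecture

__all__ = ["ArchitectureSummary", "summarize", "summarize_effects"]

CLASSES = ("additive", "dominance", "epistatic")


@dataclass(frozen=True)
class ArchitectureSummary:
    """Per-dataset normalized architecture proportions."""

    prop_additive: float
    prop_dominance: float
    prop_epistatic: float
    informative: bool
    n_significant: int = 0

    def __post_init__(self) -> None:
        if self.informative:
            total = self.prop_additive + self.prop_dominance + self.prop_epistatic
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"proportions sum to {total}, expected 1")
        else:
            if not all(
                math.isnan(p)
                for p in (self.prop_additive, self.prop_dominance, self.prop_epistatic)
            ):
                raise ValueError("uninformative summaries carry no proportions")

    @classmethod
    def uninformative(cls) -> "ArchitectureSummary":
        nan = float("nan")
        return cls(nan, nan, nan, informative=False, n_significant=0)

    def as_dict(self) -> dict[str, float | bool | int]:
        return {
            "prop_additive": self.prop_additive,
            "prop_dominance": self.prop_dominance,
            "prop_epistatic": self.prop_epistatic,
            "informative": self.informative,
            "n_significant": self.n_significant,
        }


def summarize_effects(significant: Mapping[str, float]) -> ArchitectureSummary:
    """Summarize a mapping of significant effect name -> estimate.

    The grand mean (intercept) is never part of the mapping.  Absolute
    values are summed within each gene-action class and normalized by the
    grand sum, so the result is invariant to the P1/P2 labelling (sign
    flips) and to the trait's measurement scale (positive rescaling).
    """
    if not significant:
        return ArchitectureSummary.uninformative()
    sums = dict.fromkeys(CLASSES, 0.0)
    for name, estimate in significant.items():
        sums[classify_effect(name)] += abs(float(estimate))
    grand = sum(sums.values())
    if grand == 0.0:
        # significant effects with exactly zero estimates cannot occur
        # (a zero estimate has a CI containing zero); guard anyway
        return ArchitectureSummary.uninformative()
    return ArchitectureSummary(
        prop_additive=sums["additive"] / grand,
        prop_dominance=sums["dominance"] / grand,
        prop_epistatic=sums["epistatic"] / grand,
        informative=True,
        n_significant=len(significant),
    )


def summarize(arch: "AveragedArchitecture") -> ArchitectureSummary:
    """Summarize an :class:`~linecross.engine.AveragedArchitecture`."""
    return summarize_effects(arch.significant_effects)
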