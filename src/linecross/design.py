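"""Cross design: cohort pedigrees, genetic expectations and the C-matrix.

Every cohort of a line cross (P1, P2, F1, backcrosses, ...) has an expected
genetic composition that follows from its pedigree: the fraction of its
autosomal alleles that trace back to line 1 (the *source index*, theta_S)
and the expected fraction of loci heterozygous for line-1/line-2 alleles
(the *hybridity index*, theta_H).  The C-matrix translates these indices
into the coefficient each composite genetic effect receives in the linear
model for cohort means, ``y = C beta + e``.

Sign convention: ``Aa = 2*theta_S - 1`` so that P1 scores +1 and P2 scores
-1, and ``Ad = theta_H`` so that the F1 scores 1 and inbred parents score 0.
Digenic coefficients are products of the single-locus coefficients.  Which
line is called P1 is the user's choice; downstream summaries take absolute
values, so the choice cannot alter final additive/dominance/epistasis
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .effects import FULL_EFFECTS, REDUCED_EFFECTS

__all__ = [
    "CohortSpec",
    "GeneticExpectation",
    "CMatrix",
    "PedigreeError",
    "derive_expectations",
    "resolve_pedigree",
    "build_cmatrix",
    "STANDARD_PEDIGREES",
    "standard_cohorts",
]

BASE_LINES = ("P1", "P2")


class PedigreeError(ValueError):
    """A cohort references a parent that cannot be resolved."""


@dataclass
class CohortSpec:
    """One cross cohort: pedigree plus observed phenotype summary.

    ``sire``/``dam`` name previously defined cohorts (or are empty for the
    base lines P1/P2, which are taken to be fully inbred).  Crosses are
    written sire x dam.
    """

    label: str
    sire: str | None = None
    dam: str | None = None
    mean: float = float("nan")
    se: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.se is not None and not self.se > 0:
            raise ValueError(
                f"cohort {self.label!r}: se must be > 0 when reported, got {self.se}"
            )
        if self.n is not None and self.n < 1:
            raise ValueError(f"cohort {self.label!r}: n must be >= 1, got {self.n}")

    @property
    def is_base_line(self) -> bool:
        return self.label in BASE_LINES and not self.sire and not self.dam


@dataclass(frozen=True)
class GeneticExpectation:
    """Expected genetic composition of a cohort.

    theta_S: expected fraction of autosomal alleles from line 1, in [0, 1].
    theta_H: expected fraction of loci heterozygous line-1/line-2, in [0, 1].
    dam_theta_S, dam_theta_H: the same indices for the maternal parent
    (these drive maternal-effect coefficients).
    cyto: +1 if the cytoplasm descends from line 1, -1 if from line 2.
    """

    theta_S: float
    theta_H: float
    dam_theta_S: float
    dam_theta_H: float
    cyto: int

    def __post_init__(self) -> None:
        for v, lo, hi, what in (
            (self.theta_S, 0.0, 1.0, "theta_S"),
            (self.theta_H, 0.0, 1.0, "theta_H"),
        ):
            if not (lo - 1e-12 <= v <= hi + 1e-12):
                raise ValueError(f"{what}={v} outside [0, 1]")
        # hybridity cannot exceed twice the minor source fraction
        cap = 2.0 * min(self.theta_S, 1.0 - self.theta_S)
        if self.theta_H > cap + 1e-9:
            raise ValueError(
                f"theta_H={self.theta_H} exceeds 2*min(theta_S, 1-theta_S)={cap}"
            )
        if self.cyto not in (+1, -1):
            raise ValueError(f"cyto must be +1 or -1, got {self.cyto}")


#: Expectations of the fully inbred base lines.
P1_EXPECTATION = GeneticExpectation(1.0, 0.0, 1.0, 0.0, +1)
P2_EXPECTATION = GeneticExpectation(0.0, 0.0, 0.0, 0.0, -1)


def derive_expectations(
    cohort: CohortSpec,
    resolved_parents: Mapping[str, GeneticExpectation],
) -> GeneticExpectation:
    """Derive a cohort's genetic expectation from its parents'.

    Each parent transmits a line-1 allele with probability equal to its own
    source index, independently across loci; hence for a sire x dam cross

        theta_S = (theta_S_sire + theta_S_dam) / 2
        theta_H = theta_S_sire * (1 - theta_S_dam)
                  + (1 - theta_S_sire) * theta_S_dam

    The F1 x F1 intercross recovers the exact Mendelian F2 value
    (theta_H = 0.5) without a special case, and selfing a pure line
    returns that line unchanged.  The cytoplasm is inherited from the dam.
    """
    if cohort.is_base_line:
        return P1_EXPECTATION if cohort.label == "P1" else P2_EXPECTATION
    for role, parent in (("sire", cohort.sire), ("dam", cohort.dam)):
        if not parent or parent not in resolved_parents:
            raise PedigreeError(
                f"cohort {cohort.label!r}: {role} {parent!r} is not a "
                "previously defined cohort or base line"
            )
    sire = resolved_parents[cohort.sire]
    dam = resolved_parents[cohort.dam]
    theta_S = (sire.theta_S + dam.theta_S) / 2.0
    theta_H = sire.theta_S * (1.0 - dam.theta_S) + (1.0 - sire.theta_S) * dam.theta_S
    return GeneticExpectation(
        theta_S=theta_S,
        theta_H=theta_H,
        dam_theta_S=dam.theta_S,
        dam_theta_H=dam.theta_H,
        cyto=dam.cyto,
    )


#: Parents that resolve implicitly when referenced but not defined as
#: cohorts: many published designs report F2/backcross cohorts whose F1
#: parent was produced but never measured.
IMPLICIT_PARENTS: dict[str, tuple[str, str]] = {
    "F1": ("P1", "P2"),
    "rF1": ("P2", "P1"),
}


def resolve_pedigree(
    cohorts: Sequence[CohortSpec],
) -> dict[str, GeneticExpectation]:
    """Resolve expectations for every cohort, in definition order.

    Base lines P1/P2 are always available as parents even when they do not
    appear as cohorts, and an undefined F1/rF1 parent resolves implicitly
    (it is fully determined by the base lines).  Any other undefined parent
    label raises :class:`PedigreeError`.
    """
    resolved: dict[str, GeneticExpectation] = {
        "P1": P1_EXPECTATION,
        "P2": P2_EXPECTATION,
    }
    out: dict[str, GeneticExpectation] = {}
    for cohort in cohorts:
        if cohort.label in out:
            raise PedigreeError(f"duplicate cohort label {cohort.label!r}")
        if not cohort.is_base_line:
            for parent in (cohort.sire, cohort.dam):
                if parent in IMPLICIT_PARENTS and parent not in resolved:
                    sire, dam = IMPLICIT_PARENTS[parent]
                    resolved[parent] = derive_expectations(
                        CohortSpec(label=parent, sire=sire, dam=dam), resolved
                    )
        exp = derive_expectations(cohort, resolved)
        resolved[cohort.label] = exp
        out[cohort.label] = exp
    return out


@dataclass
class CMatrix:
    """Cohorts-by-effects coefficient matrix (intercept column first)."""

    cohort_labels: list[str]
    effect_names: list[str]  # excludes the leading intercept
    coefficients: np.ndarray  # shape (n_cohorts, 1 + n_effects)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n, m = self.coefficients.shape
        if n != len(self.cohort_labels) or m != len(self.effect_names) + 1:
            raise ValueError("C-matrix shape does not match labels")
        if not np.allclose(self.coefficients[:, 0], 1.0):
            raise ValueError("intercept column must be all ones")
        if np.any(np.abs(self.coefficients) > 1.0 + 1e-12):
            raise ValueError("C-matrix coefficients must lie in [-1, 1]")

    @property
    def n_cohorts(self) -> int:
        return len(self.cohort_labels)

    def columns(self, effects: Sequence[str]) -> np.ndarray:
        """Design submatrix: intercept plus the named effect columns."""
        idx = [0] + [self.effect_names.index(e) + 1 for e in effects]
        return self.coefficients[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coefficients,
            index=pd.Index(self.cohort_labels, name="cohort"),
            columns=["intercept", *self.effect_names],
        )


def _row(exp: GeneticExpectation, effect_names: Sequence[str]) -> list[float]:
    aa = 2.0 * exp.theta_S - 1.0
    ad = exp.theta_H
    coeff = {
        "Aa": aa,
        "Ad": ad,
        "AaAa": aa * aa,
        "AaAd": aa * ad,
        "AdAd": ad * ad,
        "Ma": 2.0 * exp.dam_theta_S - 1.0,
        "Md": exp.dam_theta_H,
        "Ca": float(exp.cyto),
    }
    return [1.0] + [coeff[name] for name in effect_names]


def build_cmatrix(
    cohorts: Sequence[CohortSpec],
    model_set: str = "full",
) -> CMatrix:
    """Build the C-matrix for a list of cohorts.

    ``model_set="full"`` uses the eight-effect vocabulary (autosomal,
    maternal, cytotype); ``"reduced"`` the five autosomal effects used when
    parental sex is unknown.  Reciprocal crosses differ only in maternal and
    cytotype columns, so under the reduced set they produce duplicated rows;
    that is expected and left to the collinearity screen downstream.
    """
    if len(cohorts) < 3:
        raise ValueError(
            f"need at least 3 cohorts, got {len(cohorts)} "
            "(no candidate model is scorable otherwise)"
        )
    if model_set == "full":
        effect_names = list(FULL_EFFECTS)
    elif model_set == "reduced":
        effect_names = list(REDUCED_EFFECTS)
    else:
        raise ValueError(f"model_set must be 'full' or 'reduced', got {model_set!r}")
    expectations = resolve_pedigree(cohorts)
    rows = [_row(expectations[c.label], effect_names) for c in cohorts]
    return CMatrix(
        cohort_labels=[c.label for c in cohorts],
        effect_names=effect_names,
        coefficients=np.array(rows, dtype=float),
    )


#: Pedigrees (sire, dam) for the standard cohort labels used in simulation
#: and in thinning experiments.  Crosses are sire x dam; the r-prefix marks
#: the reciprocal (parental roles exchanged); the .2 suffix a second-round
#: backcross; the S suffix an intercross within a backcross cohort.
STANDARD_PEDIGREES: dict[str, tuple[str | None, str | None]] = {
    "P1": (None, None),
    "P2": (None, None),
    "F1": ("P1", "P2"),
    "rF1": ("P2", "P1"),
    "F2": ("F1", "F1"),
    "rF2": ("rF1", "rF1"),
    "BC1": ("P1", "F1"),
    "rBC1": ("F1", "P1"),
    "BC2": ("P2", "F1"),
    "rBC2": ("F1", "P2"),
    "BC1.2": ("P1", "BC1"),
    "rBC1.2": ("BC1", "P1"),
    "BC2.2": ("P2", "BC2"),
    "rBC2.2": ("BC2", "P2"),
    "BC1S": ("BC1", "BC1"),
    "BC2S": ("BC2", "BC2"),
}

# dependency order for pedigree resolution
_STANDARD_ORDER = tuple(STANDARD_PEDIGREES)


def standard_cohorts(labels: Iterable[str]) -> list[CohortSpec]:
    """CohortSpec skeletons (no phenotype data) for standard labels.

    Labels are re-ordered so parents precede offspring.  Unknown labels, or
    labels whose ancestors (beyond the base lines and the implicit F1/rF1)
    are not themselves requested, raise :class:`PedigreeError`.
    """
    wanted = set(labels)
    unknown = wanted - set(STANDARD_PEDIGREES)
    if unknown:
        raise PedigreeError(f"unknown standard cohort labels: {sorted(unknown)}")
    available = wanted | {"P1", "P2"} | set(IMPLICIT_PARENTS)
    for lab in wanted:
        sire, dam = STANDARD_PEDIGREES[lab]
        for p in (sire, dam):
            if p is not None and p not in available:
                raise PedigreeError(
                    f"cohort {lab!r} needs parent {p!r}, which is not in the "
                    "requested cohort set"
                )
    ordered = [lab for lab in _STANDARD_ORDER if lab in wanted]
    return [
        CohortSpec(label=lab, sire=STANDARD_PEDIGREES[lab][0], dam=STANDARD_PEDIGREES[lab][1])
        for lab in ordered
    ]
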