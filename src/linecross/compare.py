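"""Cross-dataset synthesis: consolidation and permutation comparisons.

Datasets that share a species and trait are first consolidated (their
architecture proportions averaged) so that prolific study systems cannot
dominate group comparisons.  Groups of datasets (e.g. life-history versus
morphological traits) are then compared on a chosen proportion by a
Monte-Carlo permutation test of the difference in group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .summary import ArchitectureSummary

__all__ = [
    "DatasetRecord",
    "ComparisonResult",
    "consolidate",
    "permutation_test",
    "mean_effect_class_test",
]

TRAIT_CLASSES = {"life_history", "morphological"}
CLADES = {"plant", "animal"}
DIVERGENCES = {"within", "between"}


@dataclass(frozen=True)
class DatasetRecord:
    """One analyzed dataset with its metadata and architecture summary."""

    dataset_id: str
    species: str
    trait: str
    trait_class: str
    clade: str
    divergence: str
    summary: ArchitectureSummary

    def __post_init__(self) -> None:
        if self.trait_class not in TRAIT_CLASSES:
            raise ValueError(f"trait_class must be one of {sorted(TRAIT_CLASSES)}")
        if self.clade not in CLADES:
            raise ValueError(f"clade must be one of {sorted(CLADES)}")
        if self.divergence not in DIVERGENCES:
            raise ValueError(f"divergence must be one of {sorted(DIVERGENCES)}")

    def proportion(self, which: str) -> float:
        return getattr(self.summary, which)


@dataclass
class ComparisonResult:
    """Permutation comparison of one proportion between two groups."""

    group_labels: tuple[str, str]
    observed_diff: float
    null_diffs: np.ndarray = field(repr=False)
    p_empirical: float
    n_perm: int
    seed: int
    group_sizes: tuple[int, int] = (0, 0)
    counts_at_zero: tuple[int, int] = (0, 0)
    counts_at_one: tuple[int, int] = (0, 0)

    def as_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "observed_diff": self.observed_diff,
            "p_empirical": self.p_empirical,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "group_sizes": list(self.group_sizes),
            "counts_at_zero": list(self.counts_at_zero),
            "counts_at_one": list(self.counts_at_one),
        }


def consolidate(records: Sequence[DatasetRecord]) -> list[DatasetRecord]:
    """Average proportions of records sharing a (species, trait) pair.

    Only informative records may enter.  Metadata must agree within a
    group; a conflict raises, naming the group.  The operation is
    idempotent: consolidated records are singletons under their key.
    Output order follows first appearance of each (species, trait) pair.
    """
    for r in records:
        if not r.summary.informative:
            raise ValueError(
                f"record {r.dataset_id!r} is uninformative; filter before consolidating"
            )
    groups: dict[tuple[str, str], list[DatasetRecord]] = {}
    for r in records:
        groups.setdefault((r.species, r.trait), []).append(r)
    out: list[DatasetRecord] = []
    for (species, trait), members in groups.items():
        for meta in ("trait_class", "clade", "divergence"):
            values = {getattr(m, meta) for m in members}
            if len(values) > 1:
                raise ValueError(
                    f"conflicting {meta} within (species={species!r}, "
                    f"trait={trait!r}): {sorted(values)}"
                )
        if len(members) == 1:
            out.append(members[0])
            continue
        mean = lambda which: float(
            np.mean([m.proportion(which) for m in members])
        )
        summary = ArchitectureSummary(
            prop_additive=_renorm(mean, "prop_additive"),
            prop_dominance=_renorm(mean, "prop_dominance"),
            prop_epistatic=_renorm(mean, "prop_epistatic"),
            informative=True,
            n_significant=sum(m.summary.n_significant for m in members),
        )
        out.append(
            replace(
                members[0],
                dataset_id=f"{species}:{trait}",
                summary=summary,
            )
        )
    return out


def _renorm(mean, which: str) -> float:
    # means of compositions already sum to one up to float error; snap it
    total = sum(mean(w) for w in ("prop_additive", "prop_dominance", "prop_epistatic"))
    return mean(which) / total


def permutation_test(
    values1: Sequence[float],
    values2: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
    sidedness: str = "two-sided",
    group_labels: tuple[str, str] = ("group1", "group2"),
) -> ComparisonResult:
    """Monte-Carlo permutation test of a difference in group means.

    The observed statistic is ``mean(values1) - mean(values2)``.  Each
    permutation shuffles the pooled values into groups of the original
    sizes and recomputes the statistic; the empirical p-value uses the
    add-one correction ``(1 + #extreme) / (n_perm + 1)`` so it can never
    be exactly zero.  Two-sided by default (extreme = |null| >= |observed|).
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if v1.size == 0 or v2.size == 0:
        raise ValueError("both groups must be non-empty")
    observed = float(v1.mean() - v2.mean())
    pooled = np.concatenate([v1, v2])
    n1 = v1.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = perm[:n1].mean() - perm[n1:].mean()
    if sidedness == "two-sided":
        extreme = np.abs(null) >= abs(observed) - 1e-15
    elif sidedness == "greater":
        extreme = null >= observed - 1e-15
    elif sidedness == "less":
        extreme = null <= observed + 1e-15
    else:
        raise ValueError(f"bad sidedness: {sidedness!r}")
    p = (1 + int(extreme.sum())) / (n_perm + 1)
    return ComparisonResult(
        group_labels=group_labels,
        observed_diff=observed,
        null_diffs=null,
        p_empirical=p,
        n_perm=n_perm,
        seed=seed,
        group_sizes=(int(n1), int(v2.size)),
    )


def mean_effect_class_test(
    records: Sequence[DatasetRecord],
    field_name: str = "prop_epistatic",
    partition: str = "trait_class",
    n_perm: int = 10_000,
    seed: int = 0,
    sidedness: str = "two-sided",
) -> ComparisonResult:
    """Compare one architecture proportion between the two metadata groups.

    ``partition`` names a metadata key (``trait_class``, ``clade`` or
    ``divergence``) that must split the records into exactly two groups.
    Alongside the permutation test, the counts of records pinned at
    proportion 0 and at proportion 1 are reported per group.
    """
    if field_name not in {"prop_additive", "prop_dominance", "prop_epistatic"}:
        raise ValueError(f"bad proportion field: {field_name!r}")
    levels: dict[str, list[DatasetRecord]] = {}
    for r in records:
        if not r.summary.informative:
            continue
        levels.setdefault(getattr(r, partition), []).append(r)
    if len(levels) != 2:
        raise ValueError(
            f"partition {partition!r} yields {len(levels)} group(s): "
            f"{sorted(levels)}; exactly 2 required"
        )
    (lab1, grp1), (lab2, grp2) = sorted(levels.items())
    v1 = np.array([r.proportion(field_name) for r in grp1])
    v2 = np.array([r.proportion(field_name) for r in grp2])
    result = permutation_test(
        v1, v2, n_perm=n_perm, seed=seed, sidedness=sidedness,
        group_labels=(lab1, lab2),
    )
    result.counts_at_zero = (int(np.sum(v1 == 0.0)), int(np.sum(v2 == 0.0)))
    result.counts_at_one = (int(np.sum(v1 == 1.0)), int(np.sum(v2 == 1.0)))
    return result
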