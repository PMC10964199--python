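"""Synthetic line-cross data with known ground-truth architectures.

The generator draws individual phenotypes, cohort by cohort, around the
true cohort means implied by a chosen architecture through the C-matrix
(``mu = C beta_true``), then reports each cohort's sample mean and
standard error exactly as an empirical study would — so reported SEs carry
realistic sampling error.  Whole synthetic databases mix dataset designs,
trait classes, clades and divergence levels, and record every dataset's
true architecture in a truth table for recovery scoring.

Default study conditions: grand mean 10, within-cohort SD 1 (so effect
sizes are expressed in within-cohort SD units), 30 individuals per cohort,
design sizes weighted toward the small cohort sets that dominate the
published line-cross literature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CohortSpec, build_cmatrix, standard_cohorts
from .effects import FULL_EFFECTS, REDUCED_EFFECTS, classify_effect

__all__ = [
    "SimulationConfig",
    "DatabaseConfig",
    "simulate_dataset",
    "simulate_database",
    "thin_cohorts",
    "COHORT_DESIGNS",
]

#: Named cohort-set designs, from the minimal 3-cohort cross to the full
#: 16-cohort design used in thinning experiments.
COHORT_DESIGNS: dict[str, tuple[str, ...]] = {
    "minimal3": ("P1", "P2", "F2"),
    "basic4": ("P1", "P2", "F1", "F2"),
    "classic5": ("P1", "P2", "F1", "BC1", "BC2"),
    "classic6": ("P1", "P2", "F1", "F2", "BC1", "BC2"),
    "solanum7": ("P1", "P2", "F2", "BC1", "rBC1", "BC2", "rBC2"),
    "recip8": ("P1", "P2", "F1", "rF1", "F2", "rF2", "BC1", "BC2"),
    "recip10": ("P1", "P2", "F1", "rF1", "F2", "rF2", "BC1", "rBC1", "BC2", "rBC2"),
    "full16": (
        "P1", "P2", "F1", "rF1", "F2", "rF2",
        "BC1", "rBC1", "BC2", "rBC2",
        "BC1.2", "rBC1.2", "BC2.2", "rBC2.2", "BC1S", "BC2S",
    ),
}


@dataclass
class SimulationConfig:
    """One synthetic dataset: design, true architecture and noise."""

    cohort_set: Sequence[str] = COHORT_DESIGNS["classic6"]
    beta_true: Mapping[str, float] = field(
        default_factory=lambda: {"mean": 10.0, "Aa": 2.0}
    )
    sigma_within: float = 1.0
    n_per_cohort: int = 30
    seed: int = 0
    model_set: str = "reduced"
    means_only: bool = False  # skip individual draws; report exact means

    def __post_init__(self) -> None:
        if self.sigma_within < 0:
            raise ValueError("sigma_within must be >= 0")
        if self.n_per_cohort < 2:
            raise ValueError("n_per_cohort must be >= 2")
        vocab = {"mean"} | set(
            FULL_EFFECTS if self.model_set == "full" else REDUCED_EFFECTS
        )
        bad = set(self.beta_true) - vocab
        if bad:
            raise ValueError(
                f"beta_true names effects outside the {self.model_set} "
                f"vocabulary: {sorted(bad)}"
            )


SE_FLOOR = 1e-6


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one dataset; returns a cohort,sire,dam,mean,se,n DataFrame.

    True cohort means are ``C @ beta_true``; each cohort reports the sample
    mean and SE of ``n_per_cohort`` Gaussian individual values.  A zero
    sample SD (e.g. ``sigma_within = 0``) is replaced by a small floor so
    the error covariance stays invertible.  Deterministic given the seed.
    """
    cohorts = standard_cohorts(config.cohort_set)
    cmatrix = build_cmatrix(cohorts, model_set=config.model_set)
    beta = np.array(
        [config.beta_true.get("mean", 0.0)]
        + [config.beta_true.get(e, 0.0) for e in cmatrix.effect_names]
    )
    mu = cmatrix.coefficients @ beta
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for cohort, true_mean in zip(cohorts, mu):
        if config.means_only or config.sigma_within == 0.0:
            mean, se = float(true_mean), SE_FLOOR
        else:
            values = rng.normal(true_mean, config.sigma_within, config.n_per_cohort)
            mean = float(values.mean())
            sd = float(values.std(ddof=1))
            se = max(sd / np.sqrt(config.n_per_cohort), SE_FLOOR)
        rows.append(
            {
                "cohort": cohort.label,
                "sire": cohort.sire or "",
                "dam": cohort.dam or "",
                "mean": mean,
                "se": se,
                "n": config.n_per_cohort,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DatabaseConfig:
    """A whole synthetic database of line-cross datasets.

    ``clade_weights``/``divergence_weights``/``trait_class_weights`` give
    the mixture over metadata labels; ``design_weights`` the mixture over
    named cohort-set designs; ``presence`` the per-class probability that
    an effect of that gene-action class enters a dataset's true
    architecture; ``effect_sd`` the scale of the half-normal effect-size
    draw (sign random).  Group-level architecture shifts are injected via
    ``presence_overrides``, e.g. ``{("trait_class", "life_history"):
    {"epistatic": 0.8}}``.
    """

    n_datasets: int = 100
    clade_weights: Mapping[str, float] = field(
        default_factory=lambda: {"plant": 0.75, "animal": 0.25}
    )
    divergence_weights: Mapping[str, float] = field(
        default_factory=lambda: {"within": 0.8, "between": 0.2}
    )
    trait_class_weights: Mapping[str, float] = field(
        default_factory=lambda: {"life_history": 0.5, "morphological": 0.5}
    )
    design_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "basic4": 0.15,
            "classic5": 0.2,
            "classic6": 0.25,
            "solanum7": 0.15,
            "recip8": 0.1,
            "recip10": 0.1,
            "full16": 0.05,
        }
    )
    presence: Mapping[str, float] = field(
        default_factory=lambda: {"additive": 0.9, "dominance": 0.5, "epistatic": 0.5}
    )
    presence_overrides: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=dict
    )
    effect_sd: float = 2.0
    grand_mean: float = 10.0
    sigma_within: float = 1.0
    n_per_cohort: int = 30
    parent_sex_known_prob: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("clade_weights", "divergence_weights", "trait_class_weights",
                     "design_weights"):
            w = getattr(self, name)
            total = sum(w.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"{name} must sum to 1, got {total}")


def _choice(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    keys = list(weights)
    return keys[rng.choice(len(keys), p=np.array([weights[k] for k in keys]))]


def simulate_database(
    config: DatabaseConfig,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict[str, dict]]:
    """Simulate a database of datasets with metadata and a truth table.

    Returns ``(datasets, metadata, truth)`` where ``datasets`` maps
    dataset_id to its cohort table, ``metadata`` is the companion metadata
    table, and ``truth`` records each dataset's true architecture.  When
    ``out_dir`` is given, everything is also written to disk (one CSV per
    dataset, ``metadata.csv``, ``truth.json``).

    Per-dataset random streams are spawned from the master seed, so a
    database is reproducible as a whole and each dataset independently.
    """
    master = np.random.SeedSequence(config.seed)
    meta_rng = np.random.default_rng(master.spawn(1)[0])
    dataset_seeds = master.spawn(config.n_datasets)
    datasets: dict[str, pd.DataFrame] = {}
    meta_rows = []
    truth: dict[str, dict] = {}
    for i, seedseq in enumerate(dataset_seeds):
        rng = np.random.default_rng(seedseq)
        dataset_id = f"ds{i:04d}"
        clade = _choice(meta_rng, config.clade_weights)
        divergence = _choice(meta_rng, config.divergence_weights)
        trait_class = _choice(meta_rng, config.trait_class_weights)
        design = _choice(meta_rng, config.design_weights)
        parent_sex_known = bool(meta_rng.random() < config.parent_sex_known_prob)
        model_set = "full" if parent_sex_known else "reduced"
        vocab = FULL_EFFECTS if model_set == "full" else REDUCED_EFFECTS
        presence = dict(config.presence)
        for (key, value), override in config.presence_overrides.items():
            chosen = {"clade": clade, "divergence": divergence,
                      "trait_class": trait_class}[key]
            if chosen == value:
                presence.update(override)
        beta_true: dict[str, float] = {"mean": config.grand_mean}
        # one presence draw per gene-action class; within a present class,
        # each effect of that class gets an independent half-normal size
        present_classes = {
            cls for cls, prob in presence.items() if rng.random() < prob
        }
        for effect in vocab:
            if classify_effect(effect) in present_classes:
                size = abs(rng.normal(0.0, config.effect_sd))
                sign = -1.0 if rng.random() < 0.5 else 1.0
                beta_true[effect] = sign * size
        sim = SimulationConfig(
            cohort_set=COHORT_DESIGNS[design],
            beta_true=beta_true,
            sigma_within=config.sigma_within,
            n_per_cohort=config.n_per_cohort,
            model_set=model_set,
        )
        datasets[dataset_id] = simulate_dataset(sim, rng=rng)
        # species/trait names embed the metadata labels so that datasets
        # sharing a (species, trait) pair never disagree on metadata
        n_species = max(config.n_datasets // 3, 1)
        meta_rows.append(
            {
                "dataset_id": dataset_id,
                "species": f"{clade[:2]}_{divergence[:3]}_sp{i % n_species:03d}",
                "trait": f"{trait_class[:4]}_trait{i % 7}",
                "trait_class": trait_class,
                "clade": clade,
                "divergence": divergence,
                "parent_sex_known": parent_sex_known,
                "weighted": True,
            }
        )
        truth[dataset_id] = {
            "beta_true": beta_true,
            "design": design,
            "model_set": model_set,
            "present_classes": sorted(present_classes),
        }
    metadata = pd.DataFrame(meta_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for dataset_id, frame in datasets.items():
            frame.to_csv(out / f"{dataset_id}.csv", index=False)
        metadata.to_csv(out / "metadata.csv", index=False)
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return datasets, metadata, truth


def thin_cohorts(dataset: pd.DataFrame, keep: Sequence[str]) -> pd.DataFrame:
    """Restrict a dataset to the named cohorts, preserving row order."""
    present = set(dataset["cohort"])
    missing = [lab for lab in keep if lab not in present]
    if missing:
        raise ValueError(f"cohorts not in dataset: {missing}")
    return dataset[dataset["cohort"].isin(set(keep))].reset_index(drop=True)
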