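"""Statsmodels-style front end: ``LineCrossModel`` and ``LineCrossResults``.

The model object holds one dataset (cohorts with means and standard
errors, the C-matrix, and configuration); ``fit()`` enumerates candidate
architectures, screens collinear ones, fits the rest by weighted least
squares, and returns a results object with AICc-model-averaged estimates,
unconditional standard errors, variable importances, the architecture
proportions and a printable summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .design import CMatrix, CohortSpec, build_cmatrix
from .engine import (
    AveragedArchitecture,
    DatasetObservations,
    ModelFit,
    akaike_weights,
    confidence_set,
    drop_collinear,
    enumerate_models,
    fit_wls,
    model_average,
)
from .summary import ArchitectureSummary, summarize
from scipy.stats import norm

__all__ = ["LineCrossModel", "LineCrossResults"]


class LineCrossModel:
    """Line cross analysis of one dataset.

    Parameters
    ----------
    cohorts : sequence of CohortSpec
        Cross cohorts with pedigree, mean and (optionally) SE.
    model_set : {"full", "reduced"}
        Effect vocabulary.  ``"reduced"`` (additive, dominance and the
        three digenic epistatic terms) is the appropriate choice when the
        sex of the parents in each cross is unknown, since maternal and
        cytoplasmic effects are then unidentifiable.
    config : PipelineConfig, optional
        Analysis constants (parameter cap, thresholds, levels).

    Examples
    --------
    >>> model = LineCrossModel.from_csv("dataset.csv", model_set="reduced")
    >>> res = model.fit()
    >>> print(res.summary())          # doctest: +SKIP
    >>> res.architecture.prop_epistatic  # doctest: +SKIP
    """

    def __init__(
        self,
        cohorts: Sequence[CohortSpec],
        model_set: str = "full",
        config: PipelineConfig | None = None,
        weighted: bool | None = None,
    ) -> None:
        self.config = config or PipelineConfig()
        if model_set == "auto":
            model_set = "full"
        self.model_set = model_set
        self.cohorts = list(cohorts)
        self.cmatrix: CMatrix = build_cmatrix(self.cohorts, model_set=model_set)
        if any(math.isnan(c.mean) for c in self.cohorts):
            raise ValueError("every cohort needs a phenotype mean")
        if weighted is None:
            weighted = all(c.se is not None for c in self.cohorts)
        y = np.array([c.mean for c in self.cohorts])
        if weighted:
            v = np.array([max(c.se, self.config.se_floor) ** 2 for c in self.cohorts])
        else:
            v = np.ones_like(y)
        self.observations = DatasetObservations(y=y, v=v, weighted=weighted)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        model_set: str = "full",
        config: PipelineConfig | None = None,
    ) -> "LineCrossModel":
        """Build from a DataFrame with columns cohort, sire, dam, mean[, se, n]."""
        from .io import cohorts_from_frame

        cohorts, weighted = cohorts_from_frame(frame)
        return cls(cohorts, model_set=model_set, config=config, weighted=weighted)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        model_set: str = "full",
        config: PipelineConfig | None = None,
    ) -> "LineCrossModel":
        from .io import read_dataset

        cohorts, weighted = read_dataset(path)
        return cls(cohorts, model_set=model_set, config=config, weighted=weighted)

    # ------------------------------------------------------------------
    def fit(self) -> "LineCrossResults":
        cfg = self.config
        subsets = enumerate_models(
            self.cmatrix.effect_names,
            n_cohorts=self.cmatrix.n_cohorts,
            max_params=cfg.max_params,
        )
        v = self.observations.v if self.observations.weighted else None
        fits: list[ModelFit] = []
        skipped: list[dict] = []
        for subset in subsets:
            if drop_collinear(
                self.cmatrix, subset, cond_threshold=cfg.cond_threshold, v=v
            ):
                skipped.append({"effects": list(subset), "reason": "collinear"})
                continue
            fit = fit_wls(self.observations, self.cmatrix, subset)
            if fit is None:
                skipped.append({"effects": list(subset), "reason": "singular"})
                continue
            if not math.isfinite(fit.aicc):
                skipped.append({"effects": list(subset), "reason": "unscorable"})
                continue
            fits.append(fit)
        if fits:
            akaike_weights(fits)
            confset = confidence_set(
                fits,
                level=cfg.confidence_level,
                renormalize=cfg.renormalize_confidence_set,
            )
            z = float(norm.ppf(0.5 + cfg.ci_level / 2.0))
            averaged = model_average(
                confset,
                self.cmatrix.effect_names,
                ci_multiplier=z,
                vi_threshold=cfg.vi_threshold,
                n_models=len(fits),
            )
        else:
            confset = []
            averaged = model_average([], self.cmatrix.effect_names, n_models=0)
        return LineCrossResults(
            model=self,
            fits=fits,
            confset=confset,
            averaged=averaged,
            skipped=skipped,
            model_space_size=len(subsets),
        )


@dataclass
class LineCrossResults:
    """Results of a fitted :class:`LineCrossModel`."""

    model: LineCrossModel
    fits: list[ModelFit]
    confset: list[ModelFit]
    averaged: AveragedArchitecture
    skipped: list[dict] = field(default_factory=list)
    model_space_size: int = 0

    # -- convenience views ---------------------------------------------
    @property
    def effects(self) -> pd.DataFrame:
        """Per-effect table: estimate, se, ci, importance, significance."""
        return self.averaged.table

    @property
    def params(self) -> pd.Series:
        return self.averaged.table["estimate"]

    @property
    def bse(self) -> pd.Series:
        return self.averaged.table["se"]

    @property
    def importance(self) -> pd.Series:
        return self.averaged.table["importance"]

    @property
    def architecture(self) -> ArchitectureSummary:
        """Additive/dominance/epistasis proportions of significant effects."""
        return summarize(self.averaged)

    @property
    def informative(self) -> bool:
        return self.architecture.informative

    @property
    def n_models(self) -> int:
        return len(self.fits)

    @property
    def n_confidence(self) -> int:
        return len(self.confset)

    # ------------------------------------------------------------------
    def model_table(self) -> pd.DataFrame:
        """One row per evaluated candidate, ranked by Akaike weight."""
        rows = [
            {
                "effects": "+".join(f.effects) or "(intercept)",
                "k": f.k,
                "loglik": f.loglik,
                "aicc": f.aicc,
                "delta": f.delta,
                "weight": f.weight,
            }
            for f in sorted(self.fits, key=lambda f: f.aicc)
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable per-effect summary."""
        obs = self.model.observations
        arch = self.architecture
        lines = [
            "Line Cross Analysis (AICc model averaging)",
            "=" * 66,
            f"Cohorts: {', '.join(self.model.cmatrix.cohort_labels)}",
            f"Model set: {self.model.model_set}   "
            f"Weighted: {obs.weighted}   "
            f"Models: {self.model_space_size} enumerated / "
            f"{len(self.fits)} fitted / {len(self.confset)} in "
            f"{self.model.config.confidence_level:.0%} set",
            "-" * 66,
        ]
        table = self.averaged.table.copy()
        table["significant"] = np.where(table["significant"], "*", "")
        lines.append(
            table.to_string(
                float_format=lambda x: f"{x: .4f}",
                columns=["estimate", "se", "ci_low", "ci_high", "importance", "significant"],
            )
        )
        lines.append("-" * 66)
        if arch.informative:
            lines.append(
                "Architecture proportions  "
                f"additive: {arch.prop_additive:.3f}  "
                f"dominance: {arch.prop_dominance:.3f}  "
                f"epistatic: {arch.prop_epistatic:.3f}"
            )
        else:
            lines.append(
                "No effect passed the significance gate "
                "(VI >= {:.2f} and CI excluding 0): dataset uninformative".format(
                    self.model.config.vi_threshold
                )
            )
        return "\n".join(lines)

    def to_effect_records(self) -> pd.DataFrame:
        """Flat per-effect TSV-ready table."""
        out = self.averaged.table.reset_index()
        return out

    def report(self) -> dict:
        """JSON-ready sidecar: model-space bookkeeping and skip log."""
        return {
            "model_space_size": self.model_space_size,
            "n_fitted": len(self.fits),
            "confidence_set_size": len(self.confset),
            "skipped": self.skipped,
            "informative": self.informative,
        }
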