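"""Pipeline configuration.

Every analysis constant (variable-importance cutoff 0.5, confidence levels
0.95, parameter cap 7, 10,000 permutations, ...) lives here rather than
being hard-coded, and can be loaded from a flat ``key = value`` text file.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    max_params: int = 7
    vi_threshold: float = 0.5
    ci_level: float = 0.95
    confidence_level: float = 0.95  # cumulative-weight level of the model set
    cond_threshold: float = 1e8
    model_set: str = "auto"  # auto: full when parent sex known, else reduced
    renormalize_confidence_set: bool = True
    sidedness: str = "two-sided"
    n_perm: int = 10_000
    seed: int = 0
    se_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.max_params < 1:
            raise ValueError("max_params must be >= 1")
        for name in ("vi_threshold", "ci_level", "confidence_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.model_set not in {"auto", "full", "reduced"}:
            raise ValueError(f"bad model_set policy: {self.model_set!r}")
        if self.sidedness not in {"two-sided", "greater", "less"}:
            raise ValueError(f"bad sidedness: {self.sidedness!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat ``key = value`` config file ('#' starts a comment)."""
        kinds = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str,
                 "bool": lambda s: s.strip().lower() in {"1", "true", "yes"}}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in kinds:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = casts[kinds[key]](value)
        return cls(**kwargs)

    def resolve_model_set(self, parent_sex_known: bool) -> str:
        if self.model_set != "auto":
            return self.model_set
        return "full" if parent_sex_known else "reduced"
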