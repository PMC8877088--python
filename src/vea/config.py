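"""Validated run configuration for the end-to-end workflow.

Precedence is CLI flag > config file > default; relative paths in a config
file are resolved against the file's own directory.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import ConfigError
from .types import ImportantVarPolicy


class ExpressionConfig(BaseModel):
    path: Path
    tissue: str = "skin"
    rna_threshold: float = 1.0
    protein_levels: list[str] = ["Low", "Medium", "High"]


class ImportantVarConfig(BaseModel):
    min_damaging: int = Field(default=1, ge=1)
    cadd_cutoff: float = 20.0
    functional_classes: list[str] = [
        "nonsynonymous_SNV",
        "stopgain",
        "stoploss",
        "startloss",
    ]

    def to_policy(self) -> ImportantVarPolicy:
        return ImportantVarPolicy(
            score_cutoffs={"CADD": self.cadd_cutoff},
            min_damaging=self.min_damaging,
            functional_classes=frozenset(self.functional_classes),
        )


class RunConfig(BaseModel):
    groups: dict[str, list[Path]]
    dialect: Literal["annotator_tsv", "vcf"] = "annotator_tsv"
    pathways: Path
    background: Path
    expression: Optional[ExpressionConfig] = None
    deg: Optional[Path] = None
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    or_threshold: float = Field(default=1.5, ge=0.0)
    important_var: ImportantVarConfig = ImportantVarConfig()
    out: Path = Path("vea_out")

    @field_validator("groups")
    @classmethod
    def _nonempty_groups(cls, v):
        if not v:
            raise ValueError("at least one group is required")
        for label, files in v.items():
            if not files:
                raise ValueError(f"group {label!r} has no member files")
        return v

    def resolve_paths(self, base: Path) -> "RunConfig":
        """Resolve every relative path against ``base``."""
        def res(p: Optional[Path]) -> Optional[Path]:
            if p is None:
                return None
            return p if p.is_absolute() else base / p

        data = self.model_dump()
        data["groups"] = {
            g: [res(Path(f)) for f in files] for g, files in self.groups.items()
        }
        data["pathways"] = res(self.pathways)
        data["background"] = res(self.background)
        if self.expression is not None:
            data["expression"]["path"] = res(self.expression.path)
        data["deg"] = res(self.deg)
        data["out"] = res(self.out)
        return RunConfig.model_validate(data)

    def check_files(self) -> None:
        """Verify every input file exists; errors name the offending field."""
        for label, files in self.groups.items():
            for f in files:
                if not Path(f).exists():
                    raise ConfigError(f"groups[{label}]: file not found: {f}")
        if not Path(self.pathways).exists():
            raise ConfigError(f"pathways: file not found: {self.pathways}")
        if not Path(self.background).exists():
            raise ConfigError(f"background: file not found: {self.background}")
        if self.expression is not None and not Path(self.expression.path).exists():
            raise ConfigError(f"expression: file not found: {self.expression.path}")
        if self.deg is not None and not Path(self.deg).exists():
            raise ConfigError(f"deg: file not found: {self.deg}")


def load_run_config(path: str | Path, overrides: Optional[dict] = None) -> RunConfig:
    """Load a YAML run config, apply CLI overrides, resolve paths."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    try:
        cfg = RunConfig.model_validate(data)
    except Exception as exc:
        raise ConfigError(f"invalid run config: {exc}") from exc
    return cfg.resolve_paths(path.parent.resolve())
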