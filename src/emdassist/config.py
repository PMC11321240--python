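"""Run configuration: a YAML-serializable bundle of all pipeline knobs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .errors import ParameterError
from .synthetic import ConditionEffect, GeneratorParams, null_condition_effects


@dataclass
class RunConfig:
    """Everything a simulate/analyze/pipeline run needs.

    generator holds the synthetic-cohort parameters; alpha is the
    significance level of the contrast family; null forces all condition
    effects off (for type-I calibration runs).
    """

    generator: GeneratorParams = field(default_factory=GeneratorParams)
    alpha: float = 0.05
    null: bool = False
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")

    def effective_generator(self) -> GeneratorParams:
        """Generator parameters with the null switch applied."""
        if self.null:
            return replace(self.generator, condition_effects=null_condition_effects())
        return self.generator

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"]["condition_effects"] = {
            k: asdict(v) for k, v in self.generator.condition_effects.items()
        }
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        gen_data = dict(data.pop("generator", {}))
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        gen_known = {f.name for f in fields(GeneratorParams)}
        gen_unknown = set(gen_data) - gen_known
        if gen_unknown:
            raise ParameterError(f"unknown generator key(s): {sorted(gen_unknown)}")
        effects = gen_data.pop("condition_effects", None)
        gen = GeneratorParams(**gen_data)
        if effects is not None:
            gen.condition_effects = {k: ConditionEffect(**v) for k, v in effects.items()}
        return cls(generator=gen, **data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
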