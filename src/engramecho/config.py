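"""Run configuration: schema-validated YAML, unknown keys rejected."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engramnet import ClassifierSpec
from .synthgen import CalciumModel, GeneratorConfig, StimulationPattern

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class SpikesSection:
    use_calcium: bool = False  # render + re-infer instead of using the raster
    decay_tau: float = 0.5
    threshold_sd: float = 4.0
    rise_time_threshold: float = 1.0


@dataclass(frozen=True)
class ParadigmSection:
    min_response_frac: float = 0.5
    response_window: float = 0.1
    which: str = "test1"


@dataclass(frozen=True)
class IsiSection:
    min_matches: int = 2


@dataclass(frozen=True)
class EngramSection:
    enabled: bool = True
    null_kind: str = "mixed"
    window_cycles: int = 1
    window_step: float = 0.05
    threshold: float = 0.5
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)


@dataclass(frozen=True)
class PopulationSection:
    measure: str = "jaccard"


@dataclass(frozen=True)
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    pattern: StimulationPattern = field(
        default_factory=lambda: StimulationPattern(kind="single", frequency=8.0)
    )
    calcium: CalciumModel = field(default_factory=CalciumModel)
    spikes: SpikesSection = field(default_factory=SpikesSection)
    paradigm: ParadigmSection = field(default_factory=ParadigmSection)
    isistats: IsiSection = field(default_factory=IsiSection)
    engramnet: EngramSection = field(default_factory=EngramSection)
    population: PopulationSection = field(default_factory=PopulationSection)
    exposure: float = 0.02
    seed: int = 0
    outdir: str = "results"


def _build(cls, data, path: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config section {path!r} must be a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(
            f"unknown key(s) in config section {path!r}: {sorted(unknown)}"
        )
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if dataclasses.is_dataclass(f.type) or f.name in ("classifier",):
            kwargs[key] = _build(ClassifierSpec, value, f"{path}.{key}")
        else:
            kwargs[key] = value
    return cls(**kwargs)


_SECTIONS = {
    "generator": GeneratorConfig,
    "pattern": StimulationPattern,
    "calcium": CalciumModel,
    "spikes": SpikesSection,
    "paradigm": ParadigmSection,
    "isistats": IsiSection,
    "engramnet": EngramSection,
    "population": PopulationSection,
}
_SCALARS = {"exposure", "seed", "outdir"}


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name], name)
    for name in _SCALARS:
        if name in data:
            kwargs[name] = data[name]
    cfg = RunConfig(**kwargs)
    # a single top-level seed overrides the generator/classifier seeds
    if "seed" in data:
        cfg = apply_seed(cfg, int(data["seed"]))
    return cfg


def apply_seed(cfg: RunConfig, seed: int) -> RunConfig:
    gen = dataclasses.replace(cfg.generator, seed=seed)
    cal = dataclasses.replace(cfg.calcium, seed=seed)
    clf = dataclasses.replace(cfg.engramnet.classifier, seed=seed)
    eng = dataclasses.replace(cfg.engramnet, classifier=clf)
    return dataclasses.replace(
        cfg, generator=gen, calcium=cal, engramnet=eng, seed=seed
    )


def load_config(path) -> RunConfig:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)
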