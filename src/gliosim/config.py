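"""Simulation configuration: schema, defaults, YAML round-trip, hashing."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, fields as dc_fields

import yaml

from .fields import Grid3D
from .phantom import PhantomSpec
from .nutrients import NutrientParams
from .macro import MacroParams
from .treatment import TherapyParams
from .seeding import SeedingSpec
from .boundary import BoundaryMicroParams


@dataclass(frozen=True)
class FibreConfig:
    micro_n: int = 5
    fill: float = 0.35
    library_size: int = 64
    realloc_gain: float = 0.1  # displacement per unit rearrangement flux
    update_every: int = 1  # stages between micro-fibre rearrangements
    deposition: str = "trilinear"  # or "nearest"


@dataclass(frozen=True)
class TimelineConfig:
    protocol: str = "stupp"  # "stupp" or "none"
    total_days: int = 900
    fraction_dose: float = 2.0
    n_fractions: int = 30
    concurrent_dose: float = 130.0
    adjuvant_dose: float = 265.0
    stages_per_day: int = 5


@dataclass(frozen=True)
class RunConfig:
    stages: int = 45
    seed: int = 0
    treatment: bool = True
    boundary_micro: bool = True
    fibre_rearrangement: bool = True
    snapshot_every: int = 0  # 0 disables periodic snapshots
    output_dir: str = "outputs"


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumour_radius: float = 3.0
    oedema_radius: float = 11.0
    centred: bool = True  # centre the tumour so a wide oedema shell fits
    seed: int = 0

    def to_spec(self) -> PhantomSpec:
        grid = Grid3D(tuple(self.shape), tuple(self.spacing))
        centre = None
        if self.centred:
            import numpy as np

            centre = tuple(
                o + 0.5 * n * h
                for n, h, o in zip(grid.shape, grid.spacing, grid.origin)
            )
        return PhantomSpec(
            grid=grid,
            tumour_centre=centre,
            tumour_radius=self.tumour_radius,
            oedema_radius=self.oedema_radius,
            seed=self.seed,
        )


@dataclass
class SimulationConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    nutrients: NutrientParams = field(default_factory=NutrientParams)
    macro: MacroParams = field(default_factory=MacroParams)
    therapy: TherapyParams = field(default_factory=TherapyParams)
    timeline: TimelineConfig = field(default_factory=TimelineConfig)
    seeding: SeedingSpec = field(default_factory=SeedingSpec)
    fibre: FibreConfig = field(default_factory=FibreConfig)
    boundary: BoundaryMicroParams = field(default_factory=BoundaryMicroParams)
    run: RunConfig = field(default_factory=RunConfig)

    def to_dict(self) -> dict:
        d = {}
        for f in dc_fields(self):
            sub = asdict(getattr(self, f.name))
            d[f.name] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in sub.items()}
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = {}
        section_types = {f.name: f.default_factory for f in dc_fields(cls)}
        for name, factory in section_types.items():
            typ = type(factory())
            sub = dict(d.get(name, {}) or {})
            allowed = {f.name for f in dc_fields(typ)}
            unknown = set(sub) - allowed
            if unknown:
                raise ValueError(f"unknown keys in config section {name}: {unknown}")
            for k, v in list(sub.items()):
                if isinstance(v, list):
                    sub[k] = tuple(v)
            kwargs[name] = typ(**sub)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def replace(self, **section_updates) -> "SimulationConfig":
        """New config with dataclass sections replaced by keyword."""
        import dataclasses

        out = dataclasses.replace(self)
        for name, updates in section_updates.items():
            cur = getattr(out, name)
            setattr(out, name, dataclasses.replace(cur, **updates))
        return out
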