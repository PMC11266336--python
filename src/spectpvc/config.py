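"""Run configuration: a single YAML document drives end-to-end runs.

The bundled default configuration reproduces the full reference study
layout (3 phantoms x 6 concentration rows) and carries every default
parameter; re-running an identical config with an identical seed
reproduces all tabular outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import reference
from .phantom import NoiseSettings


class ConfigError(ValueError):
    pass


@dataclass
class PhantomConfig:
    name: str
    kidney_set: str | None = None
    #: explicit (volume cm^3, S:V cm^-1) targets for (left, right); overrides kidney_set
    kidney_targets: list | None = None
    background_MBq_per_L: list = field(default_factory=list)
    target_MBq_per_L: list = field(default_factory=list)

    def resolved_kidney_targets(self) -> list[tuple[float, float]]:
        if self.kidney_targets:
            return [tuple(map(float, pair)) for pair in self.kidney_targets]
        if self.kidney_set is None:
            raise ConfigError(
                f"phantom {self.name!r}: missing kidney targets — set either "
                "'kidney_set' or 'kidney_targets'"
            )
        if self.kidney_set not in reference.KIDNEY_GEOMETRY:
            raise ConfigError(
                f"phantom {self.name!r}: unknown kidney_set {self.kidney_set!r}; "
                f"known sets: {sorted(reference.KIDNEY_GEOMETRY)}"
            )
        geometry = reference.KIDNEY_GEOMETRY[self.kidney_set]
        return [(geometry["L"][0], geometry["L"][2]), (geometry["R"][0], geometry["R"][2])]


@dataclass
class SweepConfig:
    psf_deltas_mm: list = field(default_factory=lambda: [-6, -4, -2, 0, 2, 4, 6])
    registration_max_offset_voxels: int = 3
    registration_axes: list = field(default_factory=lambda: [0, 1, 2])
    heterogeneity_ratios: list = field(
        default_factory=lambda: [1.0 + 0.25 * k for k in range(13)]
    )


@dataclass
class RunConfig:
    phantoms: list[PhantomConfig]
    spacing_mm: float = reference.WORKING_SPACING_MM
    psf_fwhm_mm: tuple = reference.PSF_FWHM_MM
    methods: list = field(
        default_factory=lambda: ["gtm", "labbe", "gtm+mtc", "labbe+mtc", "gtm+rbv", "labbe+rbv", "iy"]
    )
    iy_n_iter: int = 10
    iy_tol: float = 1e-5
    boundary: str = "fractional"
    noise: NoiseSettings | None = None
    sweeps: SweepConfig = field(default_factory=SweepConfig)
    output_dir: str = "results"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        phantoms_raw = raw.pop("phantoms", None)
        if not phantoms_raw:
            raise ConfigError("config field 'phantoms' is missing or empty")
        phantoms = []
        for entry in phantoms_raw:
            if "name" not in entry:
                raise ConfigError("every phantom entry needs a 'name' field")
            known = {f for f in PhantomConfig.__dataclass_fields__}
            unknown = set(entry) - known
            if unknown:
                raise ConfigError(f"phantom {entry['name']!r}: unknown fields {sorted(unknown)}")
            phantom = PhantomConfig(**entry)
            if not phantom.background_MBq_per_L or not phantom.target_MBq_per_L:
                schedule = reference.CONCENTRATION_SCHEDULE.get(phantom.name)
                if schedule is None:
                    raise ConfigError(
                        f"phantom {phantom.name!r}: missing field "
                        "'background_MBq_per_L'/'target_MBq_per_L' and no bundled schedule"
                    )
                phantom.background_MBq_per_L = list(schedule["background"])
                phantom.target_MBq_per_L = list(schedule["target"])
            if len(phantom.background_MBq_per_L) != len(phantom.target_MBq_per_L):
                raise ConfigError(
                    f"phantom {phantom.name!r}: background/target tables differ in length"
                )
            phantom.resolved_kidney_targets()  # validates kidney fields
            phantoms.append(phantom)

        noise_raw = raw.pop("noise", None)
        noise = NoiseSettings(**noise_raw) if noise_raw else None
        sweeps_raw = raw.pop("sweeps", None)
        sweeps = SweepConfig(**sweeps_raw) if sweeps_raw else SweepConfig()

        known = {f for f in cls.__dataclass_fields__} - {"phantoms", "noise", "sweeps"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields {sorted(unknown)}")
        config = cls(phantoms=phantoms, noise=noise, sweeps=sweeps, **raw)
        if config.boundary not in ("fractional", "labels"):
            raise ConfigError("config field 'boundary' must be 'fractional' or 'labels'")
        if config.spacing_mm <= 0:
            raise ConfigError("config field 'spacing_mm' must be > 0")
        return config

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))

    @classmethod
    def bundled(cls) -> "RunConfig":
        """The default configuration shipped with the package."""
        text = resources.files("spectpvc").joinpath("data/iec_study.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))

    def to_dict(self) -> dict:
        return asdict(self)
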