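"""Screen run configuration.

A :class:`ScreenConfig` captures the plate design of a 384-well organoid
viability screen: an eight-point serial dilution dosed in technical
quadruplicate across three biological replicates, with 16 day-0 seeding
control wells on a separate plate and a 96 h drug exposure.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml


@dataclasses.dataclass
class ScreenConfig:
    """Design parameters of one dose-response screen.

    Parameters
    ----------
    n_doses:
        Number of points in the serial dilution (>= 2).
    dilution_factor:
        Fold step between consecutive doses (> 1). The default 10**0.5
        gives a half-log series.
    top_dose:
        Highest tested concentration, in µM.
    n_tech_rep, n_bio_rep:
        Technical replicates per dose within a biological replicate, and
        number of biological replicates. The defaults give the usual
        12 wells per dose.
    exposure_h:
        Drug exposure time in hours between dosing and the endpoint read.
    n_day0_wells:
        Seeding-control wells assayed at dosing time (the T0 baseline).
    n_vehicle_wells:
        DMSO vehicle wells per biological replicate (the endpoint control C).
    rng_seed:
        Seed for any randomness downstream (simulation, subsampling).
    """

    n_doses: int = 8
    dilution_factor: float = 10.0 ** 0.5
    top_dose: float = 10.0
    n_tech_rep: int = 4
    n_bio_rep: int = 3
    exposure_h: float = 96.0
    n_day0_wells: int = 16
    n_vehicle_wells: int = 16
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_doses < 2:
            raise ValueError("n_doses must be >= 2")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if self.top_dose <= 0:
            raise ValueError("top_dose must be positive")
        for name in ("n_tech_rep", "n_bio_rep", "n_day0_wells", "n_vehicle_wells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.exposure_h <= 0:
            raise ValueError("exposure_h must be positive")

    @property
    def doses(self):
        """Descending-to-ascending dose ladder in µM (length ``n_doses``)."""
        import numpy as np

        steps = np.arange(self.n_doses)[::-1]
        return self.top_dose / self.dilution_factor ** steps

    @classmethod
    def from_file(cls, path: str | Path) -> "ScreenConfig":
        """Load from a JSON or YAML file mirroring the field names."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path
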