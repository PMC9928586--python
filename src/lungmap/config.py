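"""Run configuration: every threshold used by the pipeline, with published defaults.

The defaults reproduce the filtering and scoring constants of the embryonic-lung
atlas workflows: Visium spot QC (300 UMIs / 100 genes / 5 spots per gene),
co-localization edge threshold (Pearson r > 0.04), transition-probability
pruning (10^-4), ISS binning (20 um bins, EPCAM > 3, 140 um radial cutoff) and
SCRINSHOT hex binning (7 um circumradius, SOX2/EPCAM > 3, NE sum >= 12,
ASCL1 > 10, Leiden resolution 0.1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # Visium spot QC
    min_umi: int = 300
    min_genes: int = 100
    min_spots_per_gene: int = 5
    # co-localization
    r_min: float = 0.04
    # cluster-transition graph
    p_min: float = 1e-4
    # ISS zonation
    bin_radius: float = 20.0
    airway_gene: str = "EPCAM"
    airway_min: int = 3
    max_radial: float = 140.0
    # ST zonation
    st_airway_min: int = 8
    pd_bin: float = 0.1
    # SCRINSHOT hex binning
    hex_radius: float = 7.0
    sox2_min: int = 3
    epcam_min: int = 3
    ne_sum_min: int = 12
    ascl1_min: int = 10
    leiden_resolution: float = 0.1
    # simulation
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
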