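"""Run configuration: every tunable of the pipeline with validated bounds.

Loadable from YAML or TOML; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class RunConfig(BaseModel):
    """All pipeline tunables with their defaults.

    The defaults encode the study conditions: 5-residue fusion windows,
    8 Å designable/packable shells, Sc pose filter at 0.6, equal metric
    weights, FSC threshold 0.143, 3-residue B-factor smoothing.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # fusion sampling
    window: int = Field(5, ge=3)
    clash_overlap: float = Field(0.6, gt=0, le=1)
    contact_cutoff: float = Field(8.0, gt=0)
    max_clashes: int = Field(0, ge=0)
    min_contacts: int = Field(1, ge=0)
    flex_max_bend: float = Field(10.0, ge=0, le=45)
    flex_max_twist: float = Field(3.0, ge=0, le=10)

    # interface metrics
    shell_cutoff: float = Field(8.0, gt=0)
    sc_threshold: float = Field(0.6, ge=-1, le=1)
    sc_w: float = Field(0.5, gt=0)
    sc_trim: float = Field(1.5, ge=0)
    sasa_probe: float = Field(1.4, gt=0)
    sasa_n_dots: int = Field(960, ge=32)
    hbond_dist: float = Field(3.5, gt=0)
    buried_sasa_thresh: float = Field(0.1, ge=0)
    normalization: str = Field("minmax", pattern="^(minmax|zscore)$")
    weight_sc: float = 1.0
    weight_buried_unsats: float = 1.0
    weight_interface_energy: float = 1.0
    weight_solvation: float = 1.0
    select_k: int = Field(12, ge=1)

    # rigidity analytics
    fsc_threshold: float = Field(0.143, gt=0, lt=1)
    qscore_sigma: float = Field(0.6, gt=0)
    mask_radius: float = Field(3.0, gt=0)
    mask_soft_edge: float = Field(5.0, gt=0)
    bfactor_window: int = Field(3, ge=1)

    @property
    def weights(self) -> dict[str, float]:
        return {"sc": self.weight_sc,
                "buried_unsats": self.weight_buried_unsats,
                "interface_energy": self.weight_interface_energy,
                "solvation": self.weight_solvation}

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix.lower() == ".toml":
            data = tomllib.loads(path.read_text())
        else:
            data = yaml.safe_load(path.read_text()) or {}
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True))
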