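"""Pipeline configuration: every threshold in one round-trippable object."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .simulate import SimulationConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All thresholds, paths and flags for an end-to-end run.

    Defaults are the conventional values for this analysis: detection at
    Ct <= 35 in at least half of one state group, 2-fold cell-type enrichment,
    1.5-fold down / 2-fold up activation cut-offs, p <= 0.05 t-tests,
    FDR < 0.05, p_database < 0.05, and a panel threshold of > 6 targets.
    """

    # detection
    max_detect_ct: float = 35.0
    undetermined_policy: str = "ct"  # "ct": undetermined wells = undetermined_ct
    undetermined_ct: float = 40.0
    min_detect_samples: int | None = None  # None -> ceil(group/2)
    # classification
    gene_enrichment_fc: float = 2.0
    gene_q_down_fc: float = 1.5
    mirna_q_fc: float = 1.5
    mirna_a_fc: float = 2.0
    p_cut: float = 0.05
    paired: bool = False
    # integration
    fdr_cut: float = 0.05
    pdb_cut: float = 0.05
    # panel
    panel_min: int = 6
    panel_strict: bool = True
    # inputs: either file paths or an embedded simulation
    ct_path: str | None = None
    expr_path: str | None = None
    sheet_path: str | None = None
    predictions_path: str | None = None
    truth_path: str | None = None
    reference_assay: str = "RNU6"
    simulation: SimulationConfig | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_cut", "fdr_cut", "pdb_cut"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("gene_enrichment_fc", "gene_q_down_fc", "mirna_q_fc", "mirna_a_fc"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1 (linear fold change)")
        if self.panel_min < 0:
            raise ValueError("panel_min must be >= 0")
        if self.undetermined_policy not in ("ct", "missing"):
            raise ValueError(f"unknown undetermined_policy {self.undetermined_policy!r}")
        if self.simulation is not None:
            self.simulation.validate()

    # -- file round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.get("simulation")
        if sim is not None and not isinstance(sim, SimulationConfig):
            d["simulation"] = SimulationConfig.from_dict(sim)
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
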