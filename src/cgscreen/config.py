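"""Run configuration: thresholds, bins, seeds and paths, with YAML IO.

Defaults reproduce the published analysis settings: spot-score bins with
classification cuts final score >= 3 (sensitive) / <= -2 (resistant),
NTGV cuts 0.7 / 1.2, significance level 0.05, and the screen design of
3 drug concentrations x 2 replicates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synth import SimConfig


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    bins: tuple[tuple[float, int], ...] = (
        (0.10, 3),
        (0.35, 2),
        (0.60, 1),
        (1.30, 0),
        (1.75, -1),
    )
    sensitive_cut: int = 3
    resistant_cut: int = -2
    ntgv_sensitive_cut: float = 0.7
    ntgv_resistant_cut: float = 1.2
    wt_reference: str = "batch"
    min_term_size: int = 3
    max_term_size: int = 500
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["bins"] = [list(b) for b in self.bins]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            if "concentrations" in sim:
                sim["concentrations"] = tuple(sim["concentrations"])
            sim = SimConfig(**sim)
        if "bins" in d:
            d["bins"] = tuple((float(b), int(s)) for b, s in d["bins"])
        return cls(sim=sim, **d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))
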