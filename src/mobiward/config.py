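"""Pipeline configuration, loadable from YAML.

Flat config keys follow the module they configure, e.g.::

    filter:
      cutoff_hz: 0.8
      order: 4
      zero_phase: true
    window:
      samples: 256
      overlap_train: 0.5
      overlap_classify: 0.0
    spectral:
      band_edges_hz: [0.5, 5, 10, 15, 20, 25]
      taper: hamming
    nca:
      threshold: 0.1
      max_iterations: 30
      max_samples: 500
    ann:
      hidden_nodes: 18
      max_epochs: 500
    balance:
      static_dynamic_ratio: null
    input_units: g
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .features import SpectralSpec
from .preprocessing import FilterSpec


@dataclass
class WindowConfig:
    samples: int = 256
    overlap_train: float = 0.5
    overlap_classify: float = 0.0


@dataclass
class NcaConfig:
    threshold: float = 0.1
    max_iterations: int = 30
    lambda_reg: Optional[float] = None
    learning_rate: float = 0.1
    decay: float = 1e-4
    max_samples: Optional[int] = 500


@dataclass
class AnnConfig:
    hidden_nodes: int = 18
    max_epochs: int = 500


@dataclass
class BalanceConfig:
    # None: down-sample every class to the smallest; a number: cap static
    # classes at ratio x the smallest dynamic class instead
    static_dynamic_ratio: Optional[float] = None


@dataclass
class PipelineConfig:
    filter: FilterSpec = field(default_factory=FilterSpec)
    window: WindowConfig = field(default_factory=WindowConfig)
    spectral: SpectralSpec = field(default_factory=SpectralSpec)
    nca: NcaConfig = field(default_factory=NcaConfig)
    ann: AnnConfig = field(default_factory=AnnConfig)
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    #: select features once on the full dataset instead of per CV fold
    select_once: bool = False
    input_units: str = "g"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spectral"]["band_edges_hz"] = list(d["spectral"]["band_edges_hz"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        if "filter" in d:
            cfg.filter = FilterSpec(**d["filter"])
        if "window" in d:
            cfg.window = WindowConfig(**d["window"])
        if "spectral" in d:
            sd = dict(d["spectral"])
            if "band_edges_hz" in sd:
                sd["band_edges_hz"] = tuple(sd["band_edges_hz"])
            cfg.spectral = SpectralSpec(**sd)
        if "nca" in d:
            cfg.nca = NcaConfig(**d["nca"])
        if "ann" in d:
            cfg.ann = AnnConfig(**d["ann"])
        if "balance" in d:
            cfg.balance = BalanceConfig(**d["balance"])
        cfg.select_once = bool(d.get("select_once", cfg.select_once))
        cfg.input_units = d.get("input_units", cfg.input_units)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
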