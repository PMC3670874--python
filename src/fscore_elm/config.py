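"""JSON run configuration for the end-to-end pipeline.

A run config has four nested sections mirroring the pipeline stages plus a
single master seed that fans out deterministically to the simulator, the
inner-CV shuffles and every ELM hidden-layer draw::

    {
      "seed": 7,
      "sim":        { ... SimConfig fields ... },
      "preprocess": { "group_size": 5, "baseline": true },
      "features":   { "burg_order": 20, "n_freq": 512, "band_lo": 0.1,
                      "band_hi": 3.9, "wavelet": "db8", "level": 6,
                      "mode": "zero" },
      "search":     { "selector": "fscore", "k_span": 20, "inner_folds": 10,
                      "parsimony": 0.5, "global_ranking": false }
    }

Every key is optional (defaults above and in :class:`~fscore_elm.simulate.SimConfig`);
unknown keys are rejected.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .simulate import SimConfig

__all__ = ["RunConfig", "PreprocessConfig", "FeatureConfig", "SearchConfig"]


def _check_keys(section: str, d: dict, known: set[str]) -> None:
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {section} config keys: {sorted(unknown)}")


@dataclass(frozen=True)
class PreprocessConfig:
    group_size: int = 5
    baseline: bool = True


@dataclass(frozen=True)
class FeatureConfig:
    burg_order: int = 20
    n_freq: int = 512
    band_lo: float = 0.1
    band_hi: float = 3.9
    wavelet: str = "db8"
    level: int = 6
    mode: str = "zero"


@dataclass(frozen=True)
class SearchConfig:
    selector: str = "fscore"
    k_span: int = 20
    inner_folds: int = 10
    parsimony: float = 0.5
    global_ranking: bool = False


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    search: SearchConfig = field(default_factory=SearchConfig)

    def sim_seed(self) -> int:
        """Simulator sub-seed derived from the master seed."""
        ss = np.random.SeedSequence(entropy=int(self.seed), spawn_key=(10,))
        return int(ss.generate_state(1)[0] % (2**31))

    def search_seed(self) -> int:
        ss = np.random.SeedSequence(entropy=int(self.seed), spawn_key=(20,))
        return int(ss.generate_state(1)[0] % (2**31))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys("run", d, {"seed", "sim", "preprocess", "features", "search"})
        sim_d = dict(d.get("sim", {}))
        pre_d = dict(d.get("preprocess", {}))
        fea_d = dict(d.get("features", {}))
        sea_d = dict(d.get("search", {}))
        _check_keys("preprocess", pre_d, {"group_size", "baseline"})
        _check_keys(
            "features",
            fea_d,
            {"burg_order", "n_freq", "band_lo", "band_hi", "wavelet", "level", "mode"},
        )
        _check_keys(
            "search",
            sea_d,
            {"selector", "k_span", "inner_folds", "parsimony", "global_ranking"},
        )
        cfg = cls(
            seed=int(d.get("seed", 0)),
            sim=SimConfig.from_dict(sim_d),
            preprocess=PreprocessConfig(**pre_d),
            features=FeatureConfig(**fea_d),
            search=SearchConfig(**sea_d),
        )
        # the master seed drives the simulator unless the sim section pins one
        if "seed" not in sim_d:
            object.__setattr__(cfg, "sim", cfg.sim.replace(seed=cfg.sim_seed()))
        return cfg

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "sim": asdict(self.sim),
            "preprocess": asdict(self.preprocess),
            "features": asdict(self.features),
            "search": asdict(self.search),
        }
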