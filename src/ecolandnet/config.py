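"""Pipeline configuration: one YAML file drives every stage.

Keys (all optional, shown with defaults) govern the study window, DEA
options, gravity/binarization options, QAP options and the random seed.
Every CLI run logs the config digest and seed so outputs are traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    year_start: int = 2010
    year_end: int = 2020
    seed: int = 0
    # DEA
    rts: str = "crs"                  # crs | vrs
    frontier_scope: str = "per-year"  # per-year | pooled
    # gravity
    attenuation_b: float = 2.0
    binarize_rule: str = "global-mean"  # global-mean | row-mean
    network_year: int | None = None     # defaults to year_end
    # CONCOR
    concor_depth: int = 2
    # QAP
    n_permutations: int = 5000
    qap_method: str = "y-permutation"   # y-permutation | dsp

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path=None, **overrides) -> PipelineConfig:
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = PipelineConfig.__dataclass_fields__
    unknown = [k for k in data if k not in known]
    if unknown:
        raise ValueError(f"unknown config keys {unknown}")
    return PipelineConfig(**data)
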