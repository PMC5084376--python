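"""Pipeline configuration: every tunable threshold in one place."""

from __future__ import annotations


from dataclasses import dataclass, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # signal detection
    min_wrap: int = 1000
    min_repeat_len: int = 1000
    repeat_identity: float = 0.9
    # breaking
    alpha: float = 0.05
    merge_dist: int = 100
    exhaust_limit: int = 20
    # read mapping
    read_min_len: int = 300
    read_min_identity: float = 0.5
    # merging
    end_window: int = 5000
    min_span: int = 2
    rel_tol: float = 0.25
    runner_margin: float = 0.25
    q: float = 0.1
    em_max_iter: int = 10
    method: str = "heuristic"  # or "em"
    # general
    aligner: str = "internal"  # or "external"
    threads: int = 1
    seed: int = 0

    _RANGES = {
        "min_wrap": (1, None),
        "min_repeat_len": (1, None),
        "repeat_identity": (0.0, 1.0),
        "alpha": (0.0, 1.0),
        "merge_dist": (0, None),
        "exhaust_limit": (0, None),
        "read_min_len": (1, None),
        "read_min_identity": (0.0, 1.0),
        "end_window": (1, None),
        "min_span": (1, None),
        "rel_tol": (0.0, 1.0),
        "runner_margin": (0.0, 1.0),
        "q": (0.0, 0.5),
        "em_max_iter": (1, None),
        "threads": (1, None),
    }

    def __post_init__(self):
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if lo is not None and v < lo:
                raise ValueError(f"{name}={v} below minimum {lo}")
            if hi is not None and v > hi:
                raise ValueError(f"{name}={v} above maximum {hi}")
        if self.method not in ("heuristic", "em"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.aligner not in ("internal", "external"):
            raise ValueError(f"unknown aligner {self.aligner!r}")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls) if not f.name.startswith("_")]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must hold a key-value mapping")
        unknown = set(data) - set(cls.field_names())
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in self.field_names()}
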