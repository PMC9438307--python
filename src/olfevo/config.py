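"""Run configuration: every tunable of the pipeline with its default.

Configs serialize to a plain ``key: value`` text file so that each run
records exactly the settings it used.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Union


@dataclass
class RunConfig:
    # translated homology search
    e_value_threshold: float = 1e-10
    gap_open: int = 11
    gap_extend: int = 1
    # candidate region assembly
    flank: int = 5000
    # locus status classification
    edge_distance: int = 30
    completeness_fraction: float = 0.8
    # family assignment
    margin_bits: float = 5.0
    tree_curation: bool = True
    # gene-tree handling
    support_collapse: float = 90.0
    # rate estimation
    min_branch_my: float = 2.0
    # randomness
    seed: int = 0

    def validate(self) -> None:
        if self.e_value_threshold <= 0:
            raise ValueError("e_value_threshold must be > 0")
        if self.flank < 0 or self.edge_distance < 0:
            raise ValueError("flank and edge_distance must be >= 0")
        if not (0.0 < self.completeness_fraction <= 1.0):
            raise ValueError("completeness_fraction must be in (0, 1]")
        if not (0.0 <= self.support_collapse <= 100.0):
            raise ValueError("support_collapse must be in [0, 100]")
        if self.min_branch_my < 0:
            raise ValueError("min_branch_my must be >= 0")

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name}: {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    def save(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w") as handle:
            handle.write(self.to_text())

    @classmethod
    def load(cls, path: Union[str, os.PathLike]) -> "RunConfig":
        values = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with open(path) as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if ":" not in line:
                    raise ValueError(f"{path}: expected 'key: value' at line {lineno}")
                key, _, raw = line.partition(":")
                key, raw = key.strip(), raw.strip()
                if key not in types:
                    raise ValueError(f"{path}: unknown config key {key!r} at line {lineno}")
                current = getattr(defaults, key)
                if isinstance(current, bool):
                    values[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    values[key] = int(raw)
                elif isinstance(current, float):
                    values[key] = float(raw)
                else:
                    values[key] = raw
        cfg = cls(**values)
        cfg.validate()
        return cfg
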