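"""Run configuration: serialisable parameters embedded in every analysis output."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of an analysis run; round-trips losslessly through YAML/JSON."""

    n_points: int = 50
    index_mode: str = "raw_sum"  # or "arc_integral"
    scale: float = 1.0
    unit: str = "px"
    smooth_window: int = 1
    padj_max: float = 0.05
    lfc_min: float = 0.75
    p_column: str = "padj"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def dump(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def write_sidecar(self, output_path: str | Path) -> Path:
        """Write the config next to an analysis output as ``<output>.config.json``."""
        side = Path(str(output_path) + ".config.json")
        side.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return side
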