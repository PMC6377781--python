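"""Run configuration: defaults, flat key=value round-trip, and hashing.

Every output file names the configuration hash so result files can be traced
back to the exact parameter set that produced them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    fc_scale: str = "linear_signed"
    fc_threshold: float = 1.0  # log2 magnitude (linear two-fold)
    p_threshold: float = 0.05
    use_pvalues: bool = True
    trend_mode: str = "baseline_inclusive"
    zero_band: float = 0.0
    merge_cut: float = 0.15
    max_pathway_size: int = 1000
    min_pathway_size: int = 3
    universe: str = "measured"
    correction: str = "BH"
    seed: int = 0

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            t = types[key]
            if t == "bool":
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif t == "int":
                kwargs[key] = int(value)
            elif t == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def hash(self) -> str:
        canon = "\x1f".join(f"{f.name}={getattr(self, f.name)}" for f in fields(self))
        return hashlib.sha1(canon.encode()).hexdigest()[:10]

    def provenance(self) -> dict[str, str]:
        return {"config": self.hash()}
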