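"""Run configuration: analysis thresholds and their defaults.

Defaults are the screen and pipeline constants: Z > 2 hit threshold, CV
< 20% and 60 rfu QC floors, 50,000-read sampling cap, 25/15 bp paired
truncation, 1000 bp maximum fragment, 100 bp windows with 2 unique
reads, edit distance 6, 8 bp cut-site offset, NTTN PAM, top-10 candidate
assays, 0.2% limit of detection. A flat ``key = value`` config file can
override any field; command-line flags win over the file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigError


@dataclass
class RunConfig:
    z_threshold: float = 2.0
    cv_max: float = 20.0
    rfu_min: float = 60.0
    read_cap: int = 50_000
    trim_forward: int = 25
    trim_reverse: int = 15
    max_fragment: int = 1000
    window_size: int = 100
    min_unique_reads: int = 2
    max_edit_distance: int = 6
    max_cut_offset: int = 8
    pam: str = "NTTN"
    top_n: int = 10
    lod: float = 0.002
    min_mean_quality: float = 20.0
    anchor_k: int = 10
    seed: int = 0

    def provenance(self) -> dict:
        """Full parameter echo for embedding in output headers."""
        from . import __version__
        block = {"cutscan_version": __version__}
        block.update(dataclasses.asdict(self))
        return block

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a flat key = value file; ``overrides`` (CLI flags) win."""
        values: dict = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"float": float, "int": int, "str": str}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"line {lineno}: expected key = value")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in fields:
                    raise ConfigError(f"line {lineno}: unknown key {key!r}")
                try:
                    values[key] = casts[fields[key]](raw)
                except ValueError as exc:
                    raise ConfigError(
                        f"line {lineno}: bad value for {key!r}: {exc}")
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)
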