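"""Run configuration: defaults < YAML/JSON config file < command-line flags."""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import yaml

from .errors import MissingFileError, ValidationError
from .qct import DEFAULT_LAA_THRESHOLD, DEFAULT_WAL_WINDOW, HU_MAX, HU_MIN


@dataclass
class RunConfig:
    ct_path: str | None = None
    lobes_path: str | None = None
    cohort_path: str | None = None
    out_dir: str = "."
    wal_lo: int = DEFAULT_WAL_WINDOW[0]
    wal_hi: int = DEFAULT_WAL_WINDOW[1]
    laa_threshold: int = DEFAULT_LAA_THRESHOLD
    noise_radius: int = 0
    icc_variant: str = "ICC(2,1) absolute agreement"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.wal_lo < self.wal_hi:
            raise ValidationError(
                f"WAL window requires lo < hi, got [{self.wal_lo}, {self.wal_hi}]"
            )
        for name in ("wal_lo", "wal_hi", "laa_threshold"):
            v = getattr(self, name)
            if not HU_MIN <= v <= HU_MAX:
                raise ValidationError(f"{name}={v} outside HU range [{HU_MIN}, {HU_MAX}]")
        if self.noise_radius < 0:
            raise ValidationError(f"noise_radius must be >= 0, got {self.noise_radius}")

    @classmethod
    def load(cls, config_file=None, **overrides) -> "RunConfig":
        """Build a config: defaults, then the file, then non-None overrides."""
        values: dict = {}
        if config_file is not None:
            if not os.path.exists(config_file):
                raise MissingFileError(f"no such config file: {config_file}")
            with open(config_file) as fh:
                loaded = yaml.safe_load(fh) or {}
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(loaded) - known
            if unknown:
                raise ValidationError(f"unknown config keys {sorted(unknown)}")
            values.update(loaded)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_manifest(config: RunConfig, path) -> None:
    """Provenance manifest (config + package versions) next to the outputs.

    Content is a pure function of the config so repeated runs are
    byte-identical.
    """
    import nibabel
    import numpy
    import pandas
    import scipy

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "versions": {
            "walppo": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "nibabel": nibabel.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
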