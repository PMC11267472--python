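"""Run configuration, seed derivation and provenance hashing.

Every stochastic stage receives its own seed derived deterministically
from the master seed: ``stage_seed(master, name)`` feeds the master seed
and the CRC-32 of the stage name into a ``numpy.random.SeedSequence`` and
returns a 31-bit integer.  Re-running a single stage therefore reproduces
its stream without replaying earlier stages.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    crc = zlib.crc32(stage.encode())
    ss = np.random.SeedSequence([int(master_seed), crc])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Parameters of a pipeline run; round-trips losslessly via YAML/JSON."""

    seed: int = 0
    out_dir: str = "matescan_out"
    # synthetic inputs
    n_lines: int = 40
    n_variants: int = 1000
    aip_generations: int = 8
    # analysis parameters
    maf_threshold: float = 0.02
    gene_window: int = 1000
    z_mode: str = "literal"
    report_threshold: float = 1e-5
    assay_window: int = 60
    adjust_inversions: bool = True
    # file paths (optional; simulation fills them in)
    paths: dict = field(default_factory=dict)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded, so runs of
        the same analysis in different directories are recognisably the
        same configuration)."""
        data = asdict(self)
        data.pop("out_dir", None)
        data.pop("paths", None)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.seed, stage)
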