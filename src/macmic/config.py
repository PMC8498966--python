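"""Run configuration shared by the library pipeline and the CLI."""
from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .intervals import PROMOTER_DOWNSTREAM, PROMOTER_UPSTREAM


@dataclass
class RunConfig:
    """All tunables of a scoring run; serialised into output metadata.

    Defaults: promoter window -3000/+10000 bp around the TSS, natural-log
    product-Poisson mutual information with the self-calibrating
    promoter-mean Poisson rate, gene groups of 500, enhancer stitching at
    12 500 bp. The uniform-background (global) rate is available but
    needs a genome_length matched to where the signal actually lives.
    """

    promoter_upstream: int = PROMOTER_UPSTREAM
    promoter_downstream: int = PROMOTER_DOWNSTREAM
    joint_mode: str = "product-poisson"
    lambda_mode: str = "promoter-mean"
    assoc: str = "mi"  # mi | abs-pearson
    coloc_mode: str = "pairs"  # pairs | merged
    group_size: int = 500
    stitch_distance: int = 12_500
    genome_length: float | None = None  # inferred from tracks when None
    bins: int = 16
    seed: int = 0
    allow_degenerate_signals: bool = False

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def metadata_header(self) -> str:
        pairs = " ".join(f"{k}={v}" for k, v in sorted(self.as_dict().items()))
        return f"# macmic run config: {pairs}"
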