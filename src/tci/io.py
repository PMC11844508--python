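"""File formats and run configuration.

Plain-text formats tie the pipeline stages together: JSON manifests for
segment libraries and presentation sequences (see `tci.design`), TSV spike
event tables (neuron_id, sequence_id, repetition, spike_time_s), TSV
noiseless rate tables, and long-format CSV for CCC profiles and window
fits.  Every artifact written through this module embeds the hash of the
run configuration and the master seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["RunConfig", "write_spikes", "read_spikes", "write_table",
           "read_table"]

SPIKE_COLUMNS = ["neuron_id", "sequence_id", "repetition", "spike_time_s"]


@dataclass
class RunConfig:
    """Configuration of one analysis run; YAML round-trips exactly."""

    out_dir: str = "tci-out"
    master_seed: int = 0
    bin_width: float = 0.005
    lag_before: float = 0.1
    lag_after: float = 0.25          # added to the segment duration
    reliability_threshold: float = 0.1
    reliability_alpha: float = 1e-5
    n_permutations: int = 1000
    pool_context_types: bool = True
    include_embedded: bool = False
    n_sources: int = 8
    top_tier: float = 0.5
    n_tiers: int = 5
    n_reps: int = 8
    rate_factors: list = field(default_factory=lambda: [1.0])
    n_neurons_per_group: int = 10
    grid_widths: int = 100
    grid_centers: int = 100
    grid_shapes: list = field(default_factory=lambda: [1, 2, 3, 4, 5])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def lag_range(self, duration: float) -> tuple[float, float]:
        return (-self.lag_before, duration + self.lag_after)


def _header(config: RunConfig | None) -> str:
    if config is None:
        return ""
    return (f"# config_hash={config.config_hash} "
            f"seed={config.master_seed}\n")


def write_spikes(spikes: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """Spike event table as TSV (with a provenance comment header)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config))
        spikes.to_csv(fh, sep="\t", index=False)


def read_spikes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path, config: RunConfig | None = None) -> None:
    """Generic CSV writer with the provenance header."""
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
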