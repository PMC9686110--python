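"""Configuration objects for simulation and site calling.

Two dataclasses carry every tunable knob of the pipeline:

* :class:`SimConfig` — the synthetic-data generator (transcriptome shape,
  planted methylation, bisulfite chemistry, sequencing depth, spike-in).
* :class:`FilterThresholds` — the sequential site-calling filter cascade
  (coverage, level, methylated depth, signal/noise, FDR, per-read 3C rule).

Both can be loaded from / dumped to YAML so a run is fully described by a
single config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field is out of range; names the field."""


def _check(ok: bool, field_name: str, message: str) -> None:
    if not ok:
        raise ConfigError(f"{field_name}: {message}")


@dataclass
class SimConfig:
    """Parameters of the synthetic bisulfite-seq study.

    Defaults emulate the study conditions: per-cytosine bisulfite conversion
    rate 0.999 estimated from a 0.5% unmethylated spike-in, planted m5C
    levels drawn from Beta(2, 8.2) (median ~0.19, mostly <0.30) with a
    downstream (A/G)GGG-rich context, 50x mean coverage, two biological
    replicates for each of three folate conditions (LF/MF/HF).
    """

    seed: int = 0
    n_transcripts: int = 100
    utr5_mean: int = 150
    cds_mean: int = 900
    utr3_mean: int = 450
    length_jitter: float = 0.2  # uniform +/- fraction around each mean
    ncrna_fraction: float = 0.03
    pseudogene_fraction: float = 0.01
    n_true_sites: int = 50
    level_alpha: float = 2.0
    level_beta: float = 8.2
    motif_fraction: float = 0.7
    conversion_rate: float = 0.999
    incomplete_read_fraction: float = 0.01
    incomplete_read_conversion: float = 0.5
    substitution_error_rate: float = 0.0
    read_length: int = 100
    mean_coverage: float = 50.0
    spike_in_fraction: float = 0.005
    spike_in_length: int = 1850
    n_replicates: int = 2
    conditions: Sequence[str] = ("LF", "MF", "HF")

    def validate(self) -> "SimConfig":
        _check(self.seed >= 0, "seed", "must be non-negative")
        _check(self.n_transcripts >= 0, "n_transcripts", "must be >= 0")
        for name in ("utr5_mean", "cds_mean", "utr3_mean"):
            _check(getattr(self, name) > 0, name, "region length must be > 0")
        for name in (
            "ncrna_fraction",
            "pseudogene_fraction",
            "motif_fraction",
            "conversion_rate",
            "incomplete_read_fraction",
            "incomplete_read_conversion",
            "substitution_error_rate",
            "spike_in_fraction",
            "length_jitter",
        ):
            value = getattr(self, name)
            _check(0.0 <= value <= 1.0, name, "probability must be in [0, 1]")
        _check(self.n_true_sites >= 0, "n_true_sites", "must be >= 0")
        _check(self.level_alpha > 0, "level_alpha", "Beta shape must be > 0")
        _check(self.level_beta > 0, "level_beta", "Beta shape must be > 0")
        _check(self.read_length >= 50, "read_length",
               "post-trim read length must be >= 50 nt")
        _check(self.mean_coverage > 0, "mean_coverage", "must be > 0")
        _check(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _check(len(self.conditions) >= 1, "conditions", "need >= 1 label")
        return self

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["conditions"] = list(self.conditions)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.conditions = tuple(cfg.conditions)
        return cfg.validate()


@dataclass
class FilterThresholds:
    """Thresholds of the sequential m5C filter cascade.

    Defaults are the published rule set: reads with more than 3 unconverted
    cytosines are discarded (3C filter); a candidate site must then have
    coverage >= 20, methylation level >= 0.1, methylated depth >= 6,
    signal/noise > 0.9 and BH-adjusted p < 0.05.
    """

    min_coverage: int = 20
    min_level: float = 0.1
    min_meth_depth: int = 6
    min_signal_noise: float = 0.9
    max_fdr: float = 0.05
    max_unconverted_per_read: int = 3

    def validate(self) -> "FilterThresholds":
        _check(self.min_coverage >= 1, "min_coverage", "must be >= 1")
        _check(0 <= self.min_level <= 1, "min_level", "must be in [0, 1]")
        _check(self.min_meth_depth >= 0, "min_meth_depth", "must be >= 0")
        _check(0 <= self.min_signal_noise <= 1, "min_signal_noise",
               "must be in [0, 1]")
        _check(0 < self.max_fdr <= 1, "max_fdr", "must be in (0, 1]")
        _check(self.max_unconverted_per_read >= 0,
               "max_unconverted_per_read", "must be >= 0")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterThresholds":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data).validate()
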