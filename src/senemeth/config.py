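"""Analysis thresholds and their defaults.

Every cutoff used by the pipeline lives in one dataclass so that a single
YAML file (or CLI flag) can override it.  The defaults are the values used
throughout the study design this package implements:

* ``delta_beta`` — |Δβ| ≥ 0.2 calls a CpG site hyper-/hypomethylated.
* ``fc`` — ≥ 2-fold / ≤ 0.5-fold calls a gene up-/down-regulated.
* ``fc_go`` — ≥ 3-fold selects the reduced gene set used for functional
  (GO-style) summaries.
* ``mirna_fc`` — ±1.5-fold cutoff for miRNA expression change.
* ``tss_window`` — CpG sites are linked to a gene only within 8 kb of its TSS.
* ``gc_min`` / ``oe_min`` — CGI promoter criteria: GC ≥ 50 % and
  observed/expected CpG ≥ 0.6.
* ``detection_p_max`` — probes with detection p > 0.05 are discarded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class Thresholds:
    delta_beta: float = 0.2
    fc: float = 2.0
    fc_go: float = 3.0
    mirna_fc: float = 1.5
    tss_window: int = 8000
    gc_min: float = 0.5
    oe_min: float = 0.6
    detection_p_max: float = 0.05
    epsilon: float = 0.0          # tolerance for sequential (stepwise) change
    low_cutoff: float = 1.0       # expression low-signal replacement value
    expr_percentile: float = 75.0
    mirna_percentile: float = 90.0
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    bin_width: int = 250          # TSS-distance histogram bin width (bp)
    min_mirnas: int = 2           # triad filter: minimum supporting miRNAs

    def __post_init__(self) -> None:
        if not 0 < self.delta_beta <= 1:
            raise ConfigError(f"delta_beta must be in (0, 1], got {self.delta_beta}")
        if self.fc <= 1 or self.mirna_fc <= 1 or self.fc_go <= 1:
            raise ConfigError("fold-change cutoffs must exceed 1")
        if self.tss_window <= 0 or self.bin_width <= 0:
            raise ConfigError("tss_window and bin_width must be positive")
        if not 0 <= self.detection_p_max <= 1:
            raise ConfigError("detection_p_max must be in [0, 1]")

    def replace(self, **kwargs) -> "Thresholds":
        return dataclasses.replace(self, **kwargs)


def load_thresholds(path: str | Path | None = None, **overrides) -> Thresholds:
    """Build a :class:`Thresholds` from an optional YAML file plus overrides.

    Unknown keys in the YAML file are rejected rather than silently ignored.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(Thresholds)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
    return Thresholds(**values)


DEFAULTS = Thresholds()
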