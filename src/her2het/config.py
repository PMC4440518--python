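"""Run configuration shared by every pipeline stage.

All tunable thresholds of the analysis live in one :class:`RunConfig` so a
whole run is reproducible from a single YAML/JSON file plus a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Thresholds and algorithm parameters for the paired-component pipeline.

    Attributes
    ----------
    gain_threshold, loss_threshold, amp_threshold:
        Cutoffs on CBS-smoothed log2 ratios for calling gain, loss and
        high-level amplification. Conventional BAC-array values; inequalities
        are strict (a value exactly at a cutoff takes the less extreme state).
    cbs_alpha:
        Significance level for accepting a candidate split during recursive
        segmentation.
    cbs_nperm:
        Number of permutations for the split p-value (``p`` resolution is
        ``1/(nperm+1)``; must be >= 100 so that ``p <= cbs_alpha`` is
        attainable at the default alpha).
    cbs_min_width:
        Minimum number of probes on each side of a candidate arc.
    merge_sd_units:
        Adjacent segments whose means differ by less than this many residual
        standard deviations are merged after segmentation.
    presence_vaf, candidate_vaf:
        Variant allele fraction cutoffs: presence in a component (with
        adequate depth) and exome candidate status, respectively.
    clonal_ccf_cut:
        Cancer-cell-fraction point estimate above which a mutation is called
        clonal even when its confidence interval excludes 1.
    fdr_q:
        Benjamini-Hochberg q-value cutoff used by the prioritization filter.
    """

    gain_threshold: float = 0.12
    loss_threshold: float = -0.12
    amp_threshold: float = 0.45
    cbs_alpha: float = 0.01
    cbs_nperm: int = 1000
    cbs_min_width: int = 2
    merge_sd_units: float = 1.5
    presence_vaf: float = 0.02
    candidate_vaf: float = 0.15
    clonal_ccf_cut: float = 0.9
    fdr_q: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.loss_threshold < 0 < self.gain_threshold < self.amp_threshold):
            raise ValueError(
                "thresholds must satisfy loss < 0 < gain < amp; got "
                f"loss={self.loss_threshold}, gain={self.gain_threshold}, "
                f"amp={self.amp_threshold}"
            )
        if not (0 < self.cbs_alpha < 1):
            raise ValueError(f"cbs_alpha must be in (0, 1); got {self.cbs_alpha}")
        if self.cbs_nperm < 100:
            raise ValueError(f"cbs_nperm must be >= 100; got {self.cbs_nperm}")
        if self.cbs_min_width < 1:
            raise ValueError(f"cbs_min_width must be >= 1; got {self.cbs_min_width}")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(data)
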