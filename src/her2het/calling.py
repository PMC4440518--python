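"""Categorical copy-number state calling from CBS-smoothed log2 ratios.

Each probe is assigned one of LOSS / NEUTRAL / GAIN / AMP (numeric encoding
-1 / 0 / 1 / 2) by strict thresholding of its segment mean; a value exactly at
a cutoff takes the less extreme state. AMP is a refinement of GAIN, so
"gained-or-amplified" is encoding >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import ComponentLabel
from .segmentation import SegmentProfile

__all__ = ["State", "StateProfile", "call_states", "states_to_frame"]


class State(IntEnum):
    LOSS = -1
    NEUTRAL = 0
    GAIN = 1
    AMP = 2


@dataclass
class StateProfile:
    """Per-probe categorical copy-number states for one component."""

    sample_id: str
    component_label: ComponentLabel
    encoding: np.ndarray = field(repr=False)  # int8, values in {-1, 0, 1, 2}
    chrom: np.ndarray = field(repr=False)
    missing: np.ndarray = field(repr=False)
    probes: pd.DataFrame = field(repr=False)  # probe coordinates (1-based)

    @property
    def n_probes(self) -> int:
        return self.encoding.size

    @property
    def states(self) -> list[State]:
        return [State(int(v)) for v in self.encoding]

    @property
    def label(self) -> str:
        return f"{self.sample_id}:{self.component_label.value}"


def call_states(profile: SegmentProfile, config: RunConfig) -> StateProfile:
    """Threshold the smoothed vector of a segment profile into states.

    AMP if smoothed > amp_threshold; GAIN if gain_threshold < smoothed <=
    amp_threshold; LOSS if smoothed < loss_threshold; NEUTRAL otherwise.
    Probes with no smoothed value (whole chromosome unobserved) stay NEUTRAL
    and are marked missing.
    """
    config.validate()
    sm = profile.smoothed
    enc = np.zeros(sm.size, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        enc[sm > config.gain_threshold] = State.GAIN
        enc[sm > config.amp_threshold] = State.AMP
        enc[sm < config.loss_threshold] = State.LOSS
    missing = profile.missing | np.isnan(sm)
    return StateProfile(
        sample_id=profile.sample_id,
        component_label=profile.component_label,
        encoding=enc,
        chrom=profile.chrom.copy(),
        missing=missing,
        probes=profile.track.probes[["probe_id", "chrom", "start", "end"]].copy(),
    )


def states_to_frame(profiles: list[StateProfile]) -> pd.DataFrame:
    """Probes x samples matrix of numeric state encodings (TSV-ready)."""
    if not profiles:
        raise ValueError("no profiles given")
    base = profiles[0].probes
    out = base.copy()
    for p in profiles:
        if p.n_probes != len(base):
            raise ValueError("profiles are not on a common probe grid")
        out[p.label] = p.encoding
    return out
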