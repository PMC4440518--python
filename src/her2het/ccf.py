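"""Cancer-cell-fraction estimation and clonal/shared classification.

A mutation observed at allele fraction ``f`` in a tumor of purity ``alpha``
at a locus with tumor copy number ``q_t`` (normal copy number fixed at 2,
autosomes) and mutation multiplicity ``m`` satisfies

    E[f] = ccf * m * alpha / (alpha * q_t + (1 - alpha) * 2)

so the point estimate is the inverse adjustment of the allele fraction for
cellularity and local copy number. Multiplicity is estimated by rounding the
purity/CN-adjusted allele count; uncertainty comes from an exact binomial
(Clopper-Pearson) interval on ``f`` mapped through the (monotone) adjustment.
This is a deliberately single-solution model: purity and local copy number
are inputs, not estimated, and no multi-modal purity/ploidy search is
performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import RunConfig

__all__ = [
    "SharingStatus",
    "CCFEstimate",
    "expected_vaf",
    "estimate_multiplicity",
    "ccf_point",
    "ccf_interval",
    "estimate_ccf",
    "classify_sharing",
    "annotate_mutations",
]

_NORMAL_CN = 2  # autosomal normal-cell locus copy number


class SharingStatus(str, Enum):
    SHARED = "SHARED"
    RESTRICTED = "RESTRICTED"
    UNDETERMINED = "UNDETERMINED"


def _adjustment(alpha: float, q_t: int) -> float:
    """Average locus copies per cell: alpha*q_t + (1-alpha)*2."""
    if not (0 < alpha <= 1):
        raise ValueError(f"purity must be in (0, 1]; got {alpha}")
    if q_t < 1 or int(q_t) != q_t:
        raise ValueError(f"local tumor copy number must be an integer >= 1; got {q_t}")
    return alpha * q_t + (1 - alpha) * _NORMAL_CN


def expected_vaf(ccf: float, alpha: float, q_t: int, m: int) -> float:
    """Forward model: expected allele fraction of a mutation with the given
    cancer-cell fraction, purity, local copy number and multiplicity."""
    if not (0 <= ccf <= 1):
        raise ValueError(f"ccf must be in [0, 1]; got {ccf}")
    if not (1 <= m <= q_t) and ccf > 0:
        raise ValueError(f"multiplicity {m} outside [1, {q_t}]")
    return ccf * m * alpha / _adjustment(alpha, q_t)


def estimate_multiplicity(f: float, alpha: float, q_t: int) -> int:
    """m = round(f * (alpha*q_t + (1-alpha)*2) / alpha), clamped to [1, q_t];
    half-way ties round down."""
    raw = f * _adjustment(alpha, q_t) / alpha
    m = int(np.ceil(raw - 0.5))  # round half down
    return int(min(max(m, 1), q_t))


def ccf_point(f: float, alpha: float, q_t: int, m: int) -> tuple[float, float]:
    """CCF point estimate; returns ``(clamped, raw)`` where raw is the
    pre-clamp value kept for diagnostics."""
    if not (1 <= m <= q_t):
        raise ValueError(f"multiplicity {m} outside [1, {q_t}]")
    raw = f * _adjustment(alpha, q_t) / (alpha * m)
    return float(min(max(raw, 0.0), 1.0)), float(raw)


def ccf_interval(alt_reads: int, total_reads: int, alpha: float, q_t: int,
                 m: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval on the allele fraction mapped through the
    CCF adjustment (monotone), then clamped to [0, 1]."""
    if not (0 <= alt_reads <= total_reads) or total_reads < 1:
        raise ValueError(f"invalid read counts {alt_reads}/{total_reads}")
    tail = (1 - level) / 2
    lo = 0.0 if alt_reads == 0 else float(sps.beta.ppf(tail, alt_reads, total_reads - alt_reads + 1))
    hi = 1.0 if alt_reads == total_reads else float(
        sps.beta.ppf(1 - tail, alt_reads + 1, total_reads - alt_reads))
    return ccf_point(lo, alpha, q_t, m)[0], ccf_point(hi, alpha, q_t, m)[0]


@dataclass
class CCFEstimate:
    multiplicity: int
    ccf: float
    ccf_raw: float
    ci_low: float
    ci_high: float
    clonal: bool


def estimate_ccf(alt_reads: int, total_reads: int, alpha: float, q_t: int,
                 config: RunConfig | None = None, level: float = 0.95) -> CCFEstimate:
    """Full single-mutation estimate: multiplicity, CCF, interval, clonal flag.

    A mutation is clonal when its interval reaches 1 or its point estimate
    exceeds ``clonal_ccf_cut``.
    """
    config = config or RunConfig()
    f = alt_reads / total_reads
    m = estimate_multiplicity(f, alpha, q_t)
    ccf, raw = ccf_point(f, alpha, q_t, m)
    lo, hi = ccf_interval(alt_reads, total_reads, alpha, q_t, m, level=level)
    clonal = bool(hi >= 1.0 or ccf >= config.clonal_ccf_cut)
    return CCFEstimate(multiplicity=m, ccf=ccf, ccf_raw=raw, ci_low=lo,
                       ci_high=hi, clonal=clonal)


def classify_sharing(calls: dict, config: RunConfig | None = None) -> SharingStatus:
    """Shared-vs-restricted call for one variant across the two components.

    ``calls`` maps component label -> ``(alt_reads, total_reads)``; a missing
    component is treated as 0 alt reads at 0 depth. A variant is a candidate
    when its allele fraction exceeds ``candidate_vaf`` in at least one
    component. SHARED: allele fraction >= ``presence_vaf`` at depth >= 50 in
    both components. RESTRICTED: candidate in one component and below
    ``presence_vaf`` at depth >= 50 in the other. UNDETERMINED otherwise
    (insufficient depth to distinguish).
    """
    config = config or RunConfig()
    if not calls:
        raise ValueError("no component calls given")
    stats = {}
    for comp, (alt, total) in calls.items():
        f = alt / total if total > 0 else 0.0
        stats[comp] = (f, total)
    comps = sorted(stats)
    if len(comps) == 1:
        stats["__absent__"] = (0.0, 0)
        comps.append("__absent__")
    (f1, d1), (f2, d2) = stats[comps[0]], stats[comps[1]]
    candidate1 = f1 > config.candidate_vaf
    candidate2 = f2 > config.candidate_vaf
    present1 = f1 >= config.presence_vaf and d1 >= 50
    present2 = f2 >= config.presence_vaf and d2 >= 50
    absent1 = f1 < config.presence_vaf and d1 >= 50
    absent2 = f2 < config.presence_vaf and d2 >= 50
    if present1 and present2:
        return SharingStatus.SHARED
    if (candidate1 and absent2) or (candidate2 and absent1):
        return SharingStatus.RESTRICTED
    return SharingStatus.UNDETERMINED


def annotate_mutations(table: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Add multiplicity, CCF, interval, clonal flag and sharing status to a
    mutation table (columns as written by the IO layer).

    Sharing is classified per (case, chrom, pos, ref, alt) across the
    components carrying that variant; the status is replicated onto every
    component row of the variant.
    """
    config = config or RunConfig()
    out = table.copy()
    ests = [
        estimate_ccf(int(r.alt_reads), int(r.total_reads), float(r.purity),
                     int(r.local_cn), config)
        for r in out.itertuples()
    ]
    out["vaf"] = out["alt_reads"] / out["total_reads"]
    out["multiplicity"] = [e.multiplicity for e in ests]
    out["ccf"] = [e.ccf for e in ests]
    out["ccf_ci_low"] = [e.ci_low for e in ests]
    out["ccf_ci_high"] = [e.ci_high for e in ests]
    out["clonal"] = [e.clonal for e in ests]
    status = pd.Series(index=out.index, dtype=object)
    for _, grp in out.groupby(["case", "chrom", "pos", "ref", "alt"], sort=False):
        calls = {
            r.component: (int(r.alt_reads), int(r.total_reads))
            for r in grp.itertuples()
        }
        s = classify_sharing(calls, config).value
        status.loc[grp.index] = s
    out["status"] = status
    return out
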