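"""Differential CNA frequency between component groups, within-case
discordance, and extraction of component-restricted amplifications.

The group comparison builds, for every probe, a 2x2 table of component group
versus event presence ("gained/amplified" = encoding >= 1, "lost" =
encoding == -1, or high-level "amp" = encoding == 2), applies the two-tailed
Fisher's exact test, and controls the FDR by Benjamini-Hochberg across
probes. Restricted amplifications are maximal probe runs amplified in one
component of a case and not amplified in the partner component, annotated
with every gene whose interval overlaps the run by at least one base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .calling import StateProfile
from .io import GeneAnnotation, chrom_sort_key
from .stats import bh_adjust, fisher_two_tailed

__all__ = [
    "EVENT_KINDS",
    "AmpliconEvent",
    "per_probe_differential",
    "pair_discordance",
    "restricted_amplifications",
]

EVENT_KINDS = ("gain_or_amp", "loss", "amp")


def _event_matrix(profiles: list[StateProfile], event: str) -> tuple[np.ndarray, np.ndarray]:
    """(has_event, observed) boolean matrices, samples x probes."""
    if event not in EVENT_KINDS:
        raise ValueError(f"event must be one of {EVENT_KINDS}; got {event!r}")
    enc = np.stack([p.encoding for p in profiles])
    obs = ~np.stack([p.missing for p in profiles])
    if event == "gain_or_amp":
        has = enc >= 1
    elif event == "loss":
        has = enc == -1
    else:
        has = enc == 2
    return has & obs, obs


@lru_cache(maxsize=100_000)
def _cached_fisher(a: int, b: int, c: int, d: int) -> float:
    if a + b + c + d == 0:
        return 1.0
    return fisher_two_tailed([[a, b], [c, d]])


def per_probe_differential(group_a: list[StateProfile], group_b: list[StateProfile],
                           event: str = "gain_or_amp") -> pd.DataFrame:
    """Per-probe event frequencies in each group with Fisher p and BH q.

    Frequencies are proportions among the probes observed in each group;
    tables count observed samples only. Requires a common probe grid and at
    least two samples per group.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    n = group_a[0].n_probes
    for p in group_a + group_b:
        if p.n_probes != n:
            raise ValueError("mismatched probe grids")
    has_a, obs_a = _event_matrix(group_a, event)
    has_b, obs_b = _event_matrix(group_b, event)
    ka, na = has_a.sum(axis=0), obs_a.sum(axis=0)
    kb, nb = has_b.sum(axis=0), obs_b.sum(axis=0)
    pvals = np.array([
        _cached_fisher(int(ka[i]), int(na[i] - ka[i]), int(kb[i]), int(nb[i] - kb[i]))
        for i in range(n)
    ])
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_a = np.where(na > 0, ka / np.maximum(na, 1), np.nan)
        freq_b = np.where(nb > 0, kb / np.maximum(nb, 1), np.nan)
    out = group_a[0].probes[["probe_id", "chrom", "start", "end"]].copy()
    out["freq_a"] = freq_a
    out["freq_b"] = freq_b
    out["p"] = pvals
    out["q"] = bh_adjust(pvals)
    out["neglog10_p"] = -np.log10(pvals)
    return out


def pair_discordance(pos: StateProfile, neg: StateProfile):
    """Maximal runs of probes whose states differ between the two components
    of a case, excluding probes missing in either.

    Returns a list of ``(chrom, lo, hi, states_pos, states_neg)`` with
    half-open probe-index intervals relative to the common grid; the probe
    count of the intervals is symmetric in argument order.
    """
    if pos.n_probes != neg.n_probes:
        raise ValueError("mismatched probe grids")
    usable = ~(pos.missing | neg.missing)
    differ = (pos.encoding != neg.encoding) & usable
    chrom = pos.chrom
    out = []
    i, n = 0, differ.size
    while i < n:
        if differ[i]:
            j = i
            while j + 1 < n and differ[j + 1] and chrom[j + 1] == chrom[i]:
                j += 1
            out.append((str(chrom[i]), i, j + 1,
                        pos.encoding[i: j + 1].tolist(),
                        neg.encoding[i: j + 1].tolist()))
            i = j + 1
        else:
            i += 1
    return out


@dataclass
class AmpliconEvent:
    """A maximal run of probes amplified in one component only."""

    case_id: str
    component_label: str
    chrom: str
    probe_lo: int  # half-open grid indices
    probe_hi: int
    genomic_start: int  # 1-based inclusive, from member probes
    genomic_end: int
    genes: list[str] = field(default_factory=list)


def _overlapping_genes(annotation: list[GeneAnnotation], chrom: str,
                       start0: int, end0: int) -> list[str]:
    """Genes overlapping a 0-based half-open interval by >= 1 bp."""
    return sorted({g.gene for g in annotation
                   if g.chrom == chrom and g.start < end0 and start0 < g.end})


def restricted_amplifications(pairs, annotation: list[GeneAnnotation],
                              direction: str = "neg_only"):
    """Amplifications present in one component of a case and absent from the
    partner component, with gene annotation and per-gene recurrence.

    ``pairs`` is a list of ``(case_id, pos_profile, neg_profile)`` (or
    objects with ``case_id``/``pos``/``neg`` attributes holding state
    profiles). ``direction='neg_only'`` extracts runs amplified in the
    negative component with the positive strictly non-AMP (gain allowed);
    ``'pos_only'`` is the symmetric direction. Returns ``(events,
    recurrence)`` where recurrence counts distinct cases per gene.
    """
    if direction not in ("neg_only", "pos_only"):
        raise ValueError(f"direction must be 'neg_only' or 'pos_only'; got {direction!r}")
    ann_chroms = {g.chrom for g in annotation}
    events: list[AmpliconEvent] = []
    gene_cases: dict[str, set] = {}
    for item in pairs:
        if isinstance(item, tuple):
            case_id, pos, neg = item
        else:
            case_id, pos, neg = item.case_id, item.pos, item.neg
        if pos.n_probes != neg.n_probes:
            raise ValueError(f"case {case_id}: mismatched probe grids")
        track_chroms = set(np.unique(pos.chrom))
        if annotation and not (track_chroms & ann_chroms):
            raise ValueError("annotation and profiles share no chromosome names "
                             "(genome mismatch?)")
        target, partner = (neg, pos) if direction == "neg_only" else (pos, neg)
        usable = ~(target.missing | partner.missing)
        hit = (target.encoding == 2) & (partner.encoding != 2) & usable
        chrom = target.chrom
        starts = target.probes["start"].to_numpy()
        ends = target.probes["end"].to_numpy()
        i, n = 0, hit.size
        while i < n:
            if hit[i]:
                j = i
                while j + 1 < n and hit[j + 1] and chrom[j + 1] == chrom[i]:
                    j += 1
                g_start, g_end = int(starts[i]), int(ends[j])
                genes = _overlapping_genes(annotation, str(chrom[i]),
                                           g_start - 1, g_end)
                ev = AmpliconEvent(
                    case_id=case_id,
                    component_label=target.component_label.value,
                    chrom=str(chrom[i]),
                    probe_lo=i,
                    probe_hi=j + 1,
                    genomic_start=g_start,
                    genomic_end=g_end,
                    genes=genes,
                )
                events.append(ev)
                for g in genes:
                    gene_cases.setdefault(g, set()).add(case_id)
                i = j + 1
            else:
                i += 1
    recurrence = pd.DataFrame(
        sorted(((g, len(cases)) for g, cases in gene_cases.items()),
               key=lambda r: (-r[1], r[0])),
        columns=["gene", "n_cases"],
    )
    return events, recurrence
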