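"""Prioritization of component-restricted amplified genes.

A gene amplified only in the HER2-negative component of one or more cases is
promoted to candidate driver when its expression in a reference cohort is
copy-number regulated (amplified samples overexpress it), and candidates are
ordered by recurrence across case-pairs, mutual exclusivity with a reference
amplification, and regulation strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import RunConfig
from .stats import bh_adjust, fisher_one_tailed_under, odds_ratio

__all__ = [
    "CNRegulationResult",
    "cn_regulation_test",
    "exclusivity_test",
    "rank_candidates",
]


@dataclass
class CNRegulationResult:
    gene: str
    p: float
    direction: int  # sign of median(amplified) - median(rest)
    n_amp: int
    n_rest: int
    testable: bool


def cn_regulation_test(expr: pd.DataFrame, gene: str, min_group: int = 3,
                       all_states: bool = False) -> CNRegulationResult:
    """Is a gene overexpressed when amplified in the reference cohort?

    One-sided rank-sum test (normal approximation with tie correction) of
    expression in amplified (state 2) versus non-amplified samples,
    alternative "amplified greater". With fewer than ``min_group`` samples in
    either group the gene is untestable (p = NaN), not an error.
    ``all_states=True`` switches to a Kruskal-Wallis test across the four
    states (direction still reported from the amplified-vs-rest medians).
    """
    sub = expr.loc[expr["gene"] == gene]
    if sub.empty:
        raise ValueError(f"gene {gene!r} not in expression cohort")
    amp = sub.loc[sub["state"] == 2, "expression"].to_numpy()
    rest = sub.loc[sub["state"] != 2, "expression"].to_numpy()
    if amp.size < min_group or rest.size < min_group:
        return CNRegulationResult(gene, float("nan"), 0, amp.size, rest.size, False)
    direction = int(np.sign(np.median(amp) - np.median(rest)))
    pooled = np.concatenate((amp, rest))
    if np.all(pooled == pooled[0]):
        return CNRegulationResult(gene, 1.0, 0, amp.size, rest.size, True)
    if all_states:
        groups = [sub.loc[sub["state"] == s, "expression"].to_numpy()
                  for s in (-1, 0, 1, 2)]
        groups = [g for g in groups if g.size > 0]
        p = float(sps.kruskal(*groups)[1]) if len(groups) > 1 else 1.0
    else:
        p = float(sps.mannwhitneyu(amp, rest, alternative="greater",
                                   method="asymptotic")[1])
    return CNRegulationResult(gene, p, direction, amp.size, rest.size, True)


def exclusivity_test(gene_amp, ref_amp) -> tuple[float, float]:
    """Under-representation test of co-amplification with a reference gene.

    Both arguments are boolean indicator vectors over the same samples.
    Returns ``(p, odds ratio)`` where p = P(co-amplified count <= observed)
    under the hypergeometric null with fixed margins.
    """
    g = np.asarray(gene_amp, dtype=bool)
    r = np.asarray(ref_amp, dtype=bool)
    if g.shape != r.shape:
        raise ValueError("indicator vectors must cover the same samples")
    a = int(np.sum(g & r))
    b = int(np.sum(g & ~r))
    c = int(np.sum(~g & r))
    d = int(np.sum(~g & ~r))
    table = [[a, b], [c, d]]
    return fisher_one_tailed_under(table), odds_ratio(table)


def rank_candidates(recurrence: pd.DataFrame,
                    regulation: list[CNRegulationResult],
                    exclusivity: dict | None = None,
                    config: RunConfig | None = None) -> pd.DataFrame:
    """Filter and order candidate driver genes.

    Keeps genes whose copy-number-regulation BH q-value is <= ``fdr_q`` with
    positive direction (overexpressed when amplified); orders by recurrence
    (descending), exclusivity p (ascending), regulation q (ascending), then
    gene name. ``recurrence`` has columns gene / n_cases; ``exclusivity``
    maps gene -> (p, odds ratio).
    """
    config = config or RunConfig()
    exclusivity = exclusivity or {}
    tested = [r for r in regulation if r.testable and np.isfinite(r.p)]
    qmap: dict[str, float] = {}
    if tested:
        qs = bh_adjust([r.p for r in tested])
        qmap = {r.gene: float(q) for r, q in zip(tested, qs)}
    rec_map = dict(zip(recurrence["gene"], recurrence["n_cases"])) if len(recurrence) else {}
    rows = []
    for r in regulation:
        q = qmap.get(r.gene, float("nan"))
        overexpressed = bool(r.testable and r.direction > 0)
        keep = bool(r.testable and np.isfinite(q) and q <= config.fdr_q and overexpressed)
        exc_p, exc_or = exclusivity.get(r.gene, (float("nan"), float("nan")))
        rows.append({
            "gene": r.gene,
            "recurrence": int(rec_map.get(r.gene, 0)),
            "cn_regulation_p": r.p,
            "cn_regulation_q": q,
            "overexpressed_when_amp": overexpressed,
            "exclusivity_p": exc_p,
            "exclusivity_or": exc_or,
            "selected": keep,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        df["rank"] = []
        return df
    df = df[df["selected"]].drop(columns="selected")
    # NaN exclusivity sorts last within a recurrence level
    sort_exc = df["exclusivity_p"].fillna(np.inf)
    df = (
        df.assign(_exc=sort_exc)
        .sort_values(by=["recurrence", "_exc", "cn_regulation_q", "gene"],
                     ascending=[False, True, True, True], kind="mergesort")
        .drop(columns="_exc")
        .reset_index(drop=True)
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df
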