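"""Synthetic paired-component cohorts with known ground truth.

Emulates the data structure of a BAC-array study of tumors whose HER2-positive
and HER2-negative components were profiled separately: each case carries a set
of truncal copy-number segments identical in both components, a smaller set of
component-restricted amplicons, and one cohort-wide differential amplicon
planted in every positive component (the HER2-amplicon analog). Per-probe
log2 = truncal level + component-restricted level + Gaussian noise.

Also generates a reference expression cohort in which a chosen subset of genes
is copy-number regulated (expression = N(0,1) + beta * dosage), and paired
mutation tables whose read counts follow the clonality forward model
(alt ~ Binomial(depth, expected VAF)).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .ccf import expected_vaf
from .io import ComponentLabel, GeneAnnotation, ProbeTrack

__all__ = [
    "CohortParams",
    "CasePair",
    "SyntheticTruth",
    "generate_paired_cohort",
    "default_gene_annotation",
    "generate_expression_cohort",
    "generate_mutation_data",
    "write_cohort",
]

PROBE_BP = 50_000  # emulated array resolution

_LEVEL_STATE = {"loss": -1, "gain": 1, "amp": 2}


@dataclass
class CohortParams:
    """Simulation design for the paired copy-number cohort."""

    n_cases: int = 12
    chroms: int = 22
    probes_per_chrom: int = 250
    noise_sd: float = 0.15
    truncal_events_per_case: int = 6
    level_loss: float = -0.6
    level_gain: float = 0.3
    level_amp: float = 1.0
    shared_fraction: float = 0.7
    # "auto" places the HER2-amplicon analog on chr17; None disables it;
    # otherwise a (chrom, probe_lo, probe_hi) half-open probe interval.
    planted_differential_locus: object = "auto"
    truncal_len: tuple[int, int] = (8, 50)
    restricted_len: tuple[int, int] = (8, 30)
    min_gap: int = 5  # probes between planted events, keeping amplicons discrete
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.shared_fraction <= 1):
            raise ValueError(f"shared_fraction must be in (0, 1]; got {self.shared_fraction}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0; got {self.noise_sd}")
        if self.n_cases < 1 or self.chroms < 1 or self.probes_per_chrom < 4:
            raise ValueError("cohort dimensions too small")

    def resolve_locus(self):
        if self.planted_differential_locus is None:
            return None
        if self.planted_differential_locus == "auto":
            chrom = "chr17" if self.chroms >= 17 else f"chr{self.chroms}"
            length = 15
            lo = min(100, max(0, self.probes_per_chrom - length))
            return (chrom, lo, lo + length)
        chrom, lo, hi = self.planted_differential_locus
        valid_chroms = {f"chr{i}" for i in range(1, self.chroms + 1)}
        if chrom not in valid_chroms or not (0 <= lo < hi <= self.probes_per_chrom):
            raise ValueError(f"planted locus {self.planted_differential_locus} outside genome")
        return (chrom, int(lo), int(hi))


@dataclass
class CasePair:
    case_id: str
    pos: ProbeTrack
    neg: ProbeTrack


@dataclass
class SyntheticTruth:
    """Planted events and per-probe truth for recovery testing."""

    probe_grid: pd.DataFrame = field(repr=False)
    planted_locus: tuple | None = None
    # case_id -> [(chrom, lo, hi, level, state_encoding)], probe-index half-open
    truncal_segments: dict = field(default_factory=dict)
    # (case_id, component value) -> [(chrom, lo, hi)]
    restricted_events: dict = field(default_factory=dict)
    # (case_id, component value) -> per-probe arrays over the whole grid
    truth_levels: dict = field(default_factory=dict, repr=False)
    truth_states: dict = field(default_factory=dict, repr=False)
    regulated_genes: dict = field(default_factory=dict)
    mutation_truth: pd.DataFrame | None = None


def _named_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def _build_probe_grid(params: CohortParams) -> pd.DataFrame:
    rows = []
    for c in range(1, params.chroms + 1):
        chrom = f"chr{c}"
        for j in range(params.probes_per_chrom):
            rows.append(
                (f"P_{chrom}_{j:04d}", chrom, j * PROBE_BP + 1, (j + 1) * PROBE_BP)
            )
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end"])


_EDGE_MARGIN = 2  # probes kept clear of chromosome ends


def _place_event(rng, occupied: dict, chroms: list[str], probes: int,
                 length_range: tuple[int, int], forbidden: tuple | None,
                 min_gap: int = 5):
    """Draw a (chrom, lo, hi) interval at least ``min_gap`` probes from every
    previously placed event and clear of chromosome ends, by rejection
    sampling."""
    for _ in range(2000):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if length + 2 * _EDGE_MARGIN > probes:
            continue
        lo = int(rng.integers(_EDGE_MARGIN, probes - length - _EDGE_MARGIN + 1))
        hi = lo + length
        if forbidden and chrom == forbidden[0] and lo < forbidden[2] + min_gap \
                and forbidden[1] - min_gap < hi:
            continue
        if any(lo < e + min_gap and s - min_gap < hi
               for s, e in occupied.get(chrom, [])):
            continue
        occupied.setdefault(chrom, []).append((lo, hi))
        return chrom, lo, hi
    raise RuntimeError("could not place event; genome too crowded")


def generate_paired_cohort(params: CohortParams):
    """Generate paired tracks for ``n_cases`` cases plus their ground truth.

    Planted events never overlap one another or the differential locus, so
    every probe's truth level is the level of at most one event and the truth
    state follows directly from it.
    """
    rng = _named_rng(params.seed, "cohort")
    grid = _build_probe_grid(params)
    locus = params.resolve_locus()
    chrom_names = [f"chr{c}" for c in range(1, params.chroms + 1)]
    chrom_offset = {ch: i * params.probes_per_chrom for i, ch in enumerate(chrom_names)}
    n_grid = len(grid)
    levels = {"loss": params.level_loss, "gain": params.level_gain, "amp": params.level_amp}

    n_truncal = params.truncal_events_per_case
    n_total = max(n_truncal, int(round(n_truncal / params.shared_fraction)))
    n_restricted = n_total - n_truncal

    truth = SyntheticTruth(probe_grid=grid, planted_locus=locus)
    pairs: list[CasePair] = []
    for case_idx in range(params.n_cases):
        case_id = f"T{case_idx + 1}"
        occupied: dict[str, list] = {}
        level_pos = np.zeros(n_grid)
        level_neg = np.zeros(n_grid)
        truncal = []
        for _ in range(n_truncal):
            chrom, lo, hi = _place_event(rng, occupied, chrom_names,
                                         params.probes_per_chrom,
                                         params.truncal_len, locus, params.min_gap)
            kind = rng.choice(["loss", "gain", "amp"], p=[0.4, 0.4, 0.2])
            off = chrom_offset[chrom]
            level_pos[off + lo: off + hi] += levels[kind]
            level_neg[off + lo: off + hi] += levels[kind]
            truncal.append((chrom, lo, hi, levels[kind], _LEVEL_STATE[kind]))
        truth.truncal_segments[case_id] = truncal
        restricted = {ComponentLabel.HER2_POS.value: [], ComponentLabel.HER2_NEG.value: []}
        for _ in range(n_restricted):
            chrom, lo, hi = _place_event(rng, occupied, chrom_names,
                                         params.probes_per_chrom,
                                         params.restricted_len, locus, params.min_gap)
            comp = ComponentLabel.HER2_POS if rng.random() < 0.5 else ComponentLabel.HER2_NEG
            off = chrom_offset[chrom]
            target = level_pos if comp is ComponentLabel.HER2_POS else level_neg
            target[off + lo: off + hi] += params.level_amp
            restricted[comp.value].append((chrom, lo, hi))
        if locus is not None:
            chrom, lo, hi = locus
            off = chrom_offset[chrom]
            level_pos[off + lo: off + hi] += params.level_amp
        for comp_value, evs in restricted.items():
            truth.restricted_events[(case_id, comp_value)] = evs

        for comp, level in (
            (ComponentLabel.HER2_POS, level_pos),
            (ComponentLabel.HER2_NEG, level_neg),
        ):
            state = np.zeros(n_grid, dtype=np.int8)
            for lev, enc in ((params.level_loss, -1), (params.level_gain, 1),
                             (params.level_amp, 2)):
                state[np.isclose(level, lev)] = enc
            truth.truth_levels[(case_id, comp.value)] = level
            truth.truth_states[(case_id, comp.value)] = state
            noise = rng.normal(0.0, params.noise_sd, n_grid) if params.noise_sd > 0 else 0.0
            df = grid.copy()
            df["log2ratio"] = level + noise
            track = ProbeTrack(sample_id=case_id, component_label=comp, probes=df)
            if comp is ComponentLabel.HER2_POS:
                pos_track = track
            else:
                neg_track = track
        pairs.append(CasePair(case_id=case_id, pos=pos_track, neg=neg_track))
    return pairs, truth


def default_gene_annotation(params: CohortParams) -> list[GeneAnnotation]:
    """One synthetic gene per probe window (0-based half-open BED intervals)."""
    genes = []
    for c in range(1, params.chroms + 1):
        chrom = f"chr{c}"
        for j in range(params.probes_per_chrom):
            genes.append(GeneAnnotation(gene=f"g_{chrom}_{j:04d}", chrom=chrom,
                                        start=j * PROBE_BP, end=(j + 1) * PROBE_BP))
    return genes


def generate_expression_cohort(
    n_samples: int,
    genes: list[str],
    regulated: Mapping[str, float],
    seed: int = 0,
    amp_prob: float = 0.1,
    gain_prob: float = 0.15,
    loss_prob: float = 0.15,
    exclusive_pair: tuple[str, str, float] | None = None,
) -> pd.DataFrame:
    """Reference cohort of per-sample gene CN states and expression values.

    Expression is N(0, 1) plus ``beta * dosage(state)`` for regulated genes
    with dosage (loss, neutral, gain, amp) = (-1, 0, 1, 2) and beta = 0 for
    all other genes. ``exclusive_pair = (geneA, geneB, multiplier)`` scales
    the probability that geneB is amplified in samples where geneA is
    amplified (multiplier 0 forbids co-amplification).
    """
    unknown = set(regulated) - set(genes)
    if unknown:
        raise ValueError(f"regulated genes not in gene list: {sorted(unknown)}")
    if any(b <= 0 for b in regulated.values()):
        raise ValueError("regulation coefficients beta must be > 0")
    rng = _named_rng(seed, "expression")
    states = np.array([-1, 0, 1, 2], dtype=np.int8)
    base_p = np.array([loss_prob, 1 - loss_prob - gain_prob - amp_prob, gain_prob, amp_prob])
    if base_p[1] < 0:
        raise ValueError("state probabilities exceed 1")
    drawn = {
        g: rng.choice(states, size=n_samples, p=base_p) for g in genes
    }
    if exclusive_pair is not None:
        g_a, g_b, mult = exclusive_pair
        if g_a not in drawn or g_b not in drawn:
            raise ValueError(f"exclusive pair {g_a}/{g_b} not in gene list")
        amp_b = min(1.0, mult * amp_prob)
        rest = base_p[:3] / base_p[:3].sum() * (1 - amp_b)
        cond_p = np.array([rest[0], rest[1], rest[2], amp_b])
        mask = drawn[g_a] == 2
        drawn[g_b][mask] = rng.choice(states, size=int(mask.sum()), p=cond_p)
    rows = []
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    for g in genes:
        beta = float(regulated.get(g, 0.0))
        expr = rng.normal(0.0, 1.0, n_samples) + beta * drawn[g].astype(float)
        for s_id, st, e in zip(sample_ids, drawn[g], expr):
            rows.append((s_id, g, int(st), float(e)))
    return pd.DataFrame(rows, columns=["sample", "gene", "state", "expression"])


def generate_mutation_data(
    n_truncal: int,
    n_restricted: int,
    depth_range: tuple[int, int] = (100, 400),
    purity_per_component: tuple[float, float] = (0.7, 0.6),
    seed: int = 0,
    case_id: str = "T1",
    local_cn_choices: tuple[int, ...] = (1, 2, 3, 4),
):
    """Paired mutation tables with known cancer-cell fractions.

    Truncal mutations are clonal (CCF 1) in both components and may sit on
    multiple copies (multiplicity up to the local copy number); restricted
    mutations have CCF ~ Uniform(0.1, 1) in one component, CCF 0 in the
    other, and multiplicity 1 (subclonal point mutations are assumed to
    postdate copy-number events). Read counts are Binomial(depth, expected
    VAF) under the clonality forward model.

    Returns ``(mutation table, truth table)``.
    """
    lo_d, hi_d = depth_range
    if lo_d < 30:
        raise ValueError(f"depths must be >= 30; got range {depth_range}")
    if not all(0 < a <= 1 for a in purity_per_component):
        raise ValueError(f"purities must be in (0, 1]: {purity_per_component}")
    rng = _named_rng(seed, "mutations")
    comps = (ComponentLabel.HER2_POS, ComponentLabel.HER2_NEG)
    purity = dict(zip((c.value for c in comps), purity_per_component))
    rows, truth_rows = [], []
    for idx in range(n_truncal + n_restricted):
        gene = f"MUT{idx:03d}"
        q_t = int(rng.choice(local_cn_choices))
        if idx < n_truncal:
            m = int(rng.integers(1, q_t + 1))
            ccfs = {c.value: 1.0 for c in comps}
            clonal = True
        else:
            m = 1
            carrier = comps[int(rng.integers(2))]
            ccfs = {c.value: 0.0 for c in comps}
            ccfs[carrier.value] = float(rng.uniform(0.1, 1.0))
            clonal = False
        for comp in comps:
            alpha = purity[comp.value]
            depth = int(rng.integers(lo_d, hi_d + 1))
            vaf = expected_vaf(ccfs[comp.value], alpha, q_t, m)
            alt = int(rng.binomial(depth, vaf))
            rows.append((case_id, comp.value, gene, "chr1", 1000 * (idx + 1), "A", "G",
                         alt, depth, alpha, q_t))
            truth_rows.append((case_id, comp.value, gene, ccfs[comp.value], m, q_t,
                               clonal, vaf))
    table = pd.DataFrame(rows, columns=[
        "case", "component", "gene", "chrom", "pos", "ref", "alt",
        "alt_reads", "total_reads", "purity", "local_cn"])
    truth = pd.DataFrame(truth_rows, columns=[
        "case", "component", "gene", "true_ccf", "multiplicity", "local_cn",
        "clonal", "expected_vaf"])
    return table, truth


def write_cohort(pairs, truth: SyntheticTruth, out_dir, params: CohortParams) -> None:
    """Serialize a cohort: probe TSVs per component, gene BED, truth JSON."""
    from .io import write_gene_bed, write_probe_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pair in pairs:
        for comp, track in (("pos", pair.pos), ("neg", pair.neg)):
            write_probe_table(track, out / f"{pair.case_id}_{comp}.tsv")
    write_gene_bed(default_gene_annotation(params), out / "genes.bed")
    payload = {
        "planted_locus": truth.planted_locus,
        "truncal_segments": truth.truncal_segments,
        "restricted_events": {f"{k[0]}|{k[1]}": v for k, v in truth.restricted_events.items()},
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2) + "\n")
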