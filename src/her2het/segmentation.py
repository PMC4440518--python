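"""Binary segmentation of log2-ratio tracks into constant copy-number segments.

The change-point statistic is the classic two-sample t-like arc statistic of
circular binary segmentation, searched over linear (non-wrap-around) arcs:

    T(i, j) = (mean(x[i:j]) - mean(complement)) / (sigma * sqrt(1/k + 1/(n-k)))

with ``k = j - i`` and ``sigma`` the sample SD of the current window. Writing
``g[t] = c[t] - t * total / n`` for the centered cumulative sum ``c``, the
statistic reduces to

    T(i, j) = (g[j] - g[i]) * sqrt(n / (k * (n - k))) / sigma,

which is what both the exact search and the vectorized permutation null use.
Split significance is assessed by permutation, recursion proceeds on the up to
three runs induced by a significant arc, and a final merge pass removes
adjacent segments whose means are closer than ``merge_sd_units`` residual
standard deviations.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .io import ComponentLabel, ProbeTrack

logger = logging.getLogger(__name__)

__all__ = [
    "Segment",
    "SegmentProfile",
    "max_arc_statistic",
    "permutation_pvalue",
    "segment_chromosome",
    "smooth_track",
]

# permutations are evaluated in blocks of this many shuffles
_PERM_BLOCK = 64


def _arc_weights(n: int, sigma: float, min_width: int) -> np.ndarray:
    """w[k] = sqrt(n / (k*(n-k))) / sigma for valid arc lengths, else 0."""
    k = np.arange(n + 1, dtype=float)
    w = np.zeros(n + 1)
    valid = (k >= min_width) & (k <= n - min_width)
    kk = k[valid]
    w[valid] = np.sqrt(n / (kk * (n - kk))) / sigma
    return w


def max_arc_statistic(values, min_width: int = 2):
    """Locate the arc maximizing the absolute change-point statistic.

    Returns ``(i, j, T)`` over all arcs ``values[i:j]`` with
    ``min_width <= j - i <= n - min_width``; ties in ``|T|`` are broken by
    smallest ``i``, then smallest ``j``. Returns ``None`` when the window is
    too short for any split ("no split possible"), and ``T = 0`` with the
    smallest valid arc for a constant window.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 * min_width:
        return None
    sigma = float(np.std(x, ddof=1))
    if sigma == 0.0 or not np.isfinite(sigma):
        return (0, min_width, 0.0)
    c = np.concatenate(([0.0], np.cumsum(x)))
    g = c - np.arange(n + 1) * (c[-1] / n)
    best_abs = -1.0
    best = (0, min_width, 0.0)
    w = _arc_weights(n, sigma, min_width)
    # scan by arc length; record first (lexicographically smallest) argmax
    for k in range(min_width, n - min_width + 1):
        t = (g[k:] - g[: n + 1 - k]) * w[k]
        at = np.abs(t)
        m = float(at.max())
        if m > best_abs * (1 + 1e-13):
            i = int(np.argmax(at >= m * (1 - 1e-13)))
            cand = (i, i + k, float(t[i]))
            if m > best_abs or (cand[0], cand[1]) < (best[0], best[1]):
                best_abs, best = m, cand
        elif m >= best_abs * (1 - 1e-13):
            i = int(np.argmax(at >= best_abs * (1 - 1e-13)))
            if (i, i + k) < (best[0], best[1]):
                best = (i, i + k, float(t[i]))
    return best


def _perm_max_abs(g_like: np.ndarray, w: np.ndarray, n: int) -> np.ndarray:
    """Max |T| over arcs for each row of a block of centered cumulative sums."""
    block = g_like.shape[0]
    out = np.zeros(block)
    for k in range(n + 1):
        if w[k] == 0.0:
            continue
        d = g_like[:, k:] - g_like[:, : n + 1 - k]
        np.abs(d, out=d)
        np.maximum(out, d.max(axis=1) * w[k], out=out)
    return out


def permutation_pvalue(values, i: int, j: int, nperm: int, seed=None,
                       min_width: int = 2, alpha: float | None = None,
                       rng: np.random.Generator | None = None) -> float:
    """Permutation p-value for the arc ``values[i:j]``.

    ``p = (1 + #{permutations with max-arc |T| >= |T_obs|}) / (1 + nperm)``,
    shuffling the window uniformly with the given seed (or generator). When
    ``alpha`` is supplied, evaluation stops as soon as the p-value provably
    exceeds ``alpha``; the returned value is then a conservative lower-count
    estimate on the correct side of the decision.
    """
    if nperm < 100:
        raise ValueError(f"nperm must be >= 100; got {nperm}")
    x = np.asarray(values, dtype=float)
    n = x.size
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma = float(np.std(x, ddof=1))
    if sigma == 0.0:
        return 1.0
    k_obs = j - i
    mean_in = float(x[i:j].mean())
    mean_out = float(np.concatenate((x[:i], x[j:])).mean())
    t_obs = abs(mean_in - mean_out) / (sigma * np.sqrt(1.0 / k_obs + 1.0 / (n - k_obs)))
    thresh = t_obs * (1 - 1e-12)
    w = _arc_weights(n, sigma, min_width)
    offset = np.arange(n + 1) * (float(x.sum()) / n)
    exceed = 0
    done = 0
    while done < nperm:
        block = min(_PERM_BLOCK, nperm - done)
        perms = np.empty((block, n))
        for b in range(block):
            perms[b] = rng.permutation(x)
        c = np.concatenate((np.zeros((block, 1)), np.cumsum(perms, axis=1)), axis=1)
        g = c - offset
        exceed += int(np.count_nonzero(_perm_max_abs(g, w, n) >= thresh))
        done += block
        if alpha is not None and (1 + exceed) / (1 + nperm) > alpha:
            return (1 + exceed) / (1 + done)
    return (1 + exceed) / (1 + nperm)


def _split_parts(lo: int, hi: int, i: int, j: int, min_width: int):
    """Probe-index runs induced by a significant arc; flanks shorter than
    ``min_width`` are absorbed into the arc run."""
    a, b = lo + i, lo + j
    if a - lo < min_width:
        a = lo
    if hi - b < min_width:
        b = hi
    parts = [(lo, a), (a, b), (b, hi)]
    return [(s, e) for s, e in parts if e > s]


def segment_chromosome(values, config: RunConfig,
                       rng: np.random.Generator | None = None):
    """Recursively segment one chromosome's ordered log2 values.

    Returns a list of ``(start, end, mean)`` tuples (half-open probe-index
    intervals) partitioning the input. A candidate arc is accepted when its
    permutation p-value is <= ``config.cbs_alpha``; afterwards adjacent
    segments whose means differ by less than ``merge_sd_units`` times the
    residual SD (the SD of values around their segment means) are merged to a
    fixpoint.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("segment_chromosome expects no missing values")
    n = x.size
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mw = config.cbs_min_width
    boundaries: list[tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        win = x[lo:hi]
        res = max_arc_statistic(win, min_width=mw)
        if res is None or res[2] == 0.0:
            boundaries.append((lo, hi))
            continue
        i, j, _ = res
        p = permutation_pvalue(win, i, j, config.cbs_nperm, min_width=mw,
                               alpha=config.cbs_alpha, rng=rng)
        if p <= config.cbs_alpha:
            parts = _split_parts(lo, hi, i, j, mw)
            if len(parts) == 1:
                boundaries.append(parts[0])
            else:
                # depth-first, left to right, for deterministic rng consumption
                stack.extend(reversed(parts))
        else:
            boundaries.append((lo, hi))
    boundaries.sort()
    segs = [(lo, hi, float(x[lo:hi].mean())) for lo, hi in boundaries]

    # merge pass: residual SD around the initial segment means
    fitted = np.empty(n)
    for lo, hi, m in segs:
        fitted[lo:hi] = m
    resid = x - fitted
    sigma_res = float(np.std(resid, ddof=1)) if n > 1 else 0.0
    cut = config.merge_sd_units * sigma_res
    changed = True
    while changed and len(segs) > 1:
        changed = False
        diffs = [abs(segs[t + 1][2] - segs[t][2]) for t in range(len(segs) - 1)]
        t = int(np.argmin(diffs))
        if diffs[t] < cut:
            lo, _, _ = segs[t]
            _, hi, _ = segs[t + 1]
            segs[t: t + 2] = [(lo, hi, float(x[lo:hi].mean()))]
            changed = True
    return segs


@dataclass
class Segment:
    chrom: str
    istart: int  # global probe row index, half-open
    iend: int
    genomic_start: int  # 1-based inclusive, from member probe coordinates
    genomic_end: int
    seg_mean: float
    n_probes: int  # observed (non-missing) probes


@dataclass
class SegmentProfile:
    """Per-chromosome constant segments plus the per-probe smoothed vector."""

    sample_id: str
    component_label: ComponentLabel
    segments: list[Segment]
    smoothed: np.ndarray = field(repr=False)
    track: ProbeTrack = field(repr=False)

    @property
    def chrom(self) -> np.ndarray:
        return self.track.probes["chrom"].to_numpy()

    @property
    def missing(self) -> np.ndarray:
        return self.track.missing


def _track_rng(track: ProbeTrack, config: RunConfig) -> np.random.Generator:
    tag = zlib.crc32(f"{track.sample_id}/{track.component_label.value}".encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag]))


def smooth_track(track: ProbeTrack, config: RunConfig) -> SegmentProfile:
    """Segment every chromosome of a track and assemble the smoothed vector.

    Missing probes are excluded from the statistics and re-attached to the
    enclosing segment (segment of the preceding observed probe) for the
    smoothed vector. Chromosomes too short to split become single segments.
    """
    rng = _track_rng(track, config)
    n = track.n_probes
    smoothed = np.full(n, np.nan)
    segments: list[Segment] = []
    probes = track.probes
    starts = probes["start"].to_numpy()
    ends = probes["end"].to_numpy()
    log2 = probes["log2ratio"].to_numpy()
    for chrom, sl in track.chrom_slices().items():
        lo, hi = sl.start, sl.stop
        vals = log2[lo:hi]
        obs_rel = np.flatnonzero(~np.isnan(vals))
        obs = vals[obs_rel]
        if obs.size == 0:
            logger.warning("%s %s: no observed probes; skipped", track.sample_id, chrom)
            continue
        if obs.size < 2 * config.cbs_min_width:
            logger.warning("%s %s: too few probes to split (%d)", track.sample_id,
                           chrom, obs.size)
            segs = [(0, obs.size, float(obs.mean()))]
        else:
            segs = segment_chromosome(obs, config, rng=rng)
        # map observed-index boundaries back onto the full probe grid
        full_bounds = [lo]
        for s, _, _ in segs[1:]:
            full_bounds.append(lo + int(obs_rel[s]))
        full_bounds.append(hi)
        for (olo, ohi, mean), flo, fhi in zip(segs, full_bounds, full_bounds[1:]):
            smoothed[flo:fhi] = mean
            segments.append(
                Segment(
                    chrom=chrom,
                    istart=flo,
                    iend=fhi,
                    genomic_start=int(starts[flo]),
                    genomic_end=int(ends[fhi - 1]),
                    seg_mean=mean,
                    n_probes=ohi - olo,
                )
            )
    return SegmentProfile(
        sample_id=track.sample_id,
        component_label=track.component_label,
        segments=segments,
        smoothed=smoothed,
        track=track,
    )
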