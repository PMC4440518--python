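"""Readers and writers for the on-disk formats of the pipeline.

Probe tables are tab-separated with 1-based inclusive coordinates (array
convention); gene annotations are BED4 (0-based half-open); segments are
exported in SEG format. All interval arithmetic inside the package is 0-based
half-open; the converters at this boundary are the only place coordinate
dialects are translated.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentLabel",
    "ProbeTrack",
    "GeneAnnotation",
    "chrom_sort_key",
    "read_probe_table",
    "write_probe_table",
    "read_gene_bed",
    "write_gene_bed",
    "write_seg",
    "read_seg",
    "read_mutation_table",
    "write_mutation_table",
]

_MISSING_TOKENS = {"", "na", "nan", "n/a", "."}

_CANON_CHROMS = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
_CANON_RANK = {c: i for i, c in enumerate(_CANON_CHROMS)}


def chrom_sort_key(chrom: str):
    """Natural chromosome order chr1..chr22, chrX, chrY; unknown names after,
    lexicographically."""
    rank = _CANON_RANK.get(chrom)
    if rank is not None:
        return (0, rank, "")
    return (1, 0, chrom)


class ComponentLabel(str, Enum):
    HER2_POS = "HER2_POS"
    HER2_NEG = "HER2_NEG"
    UNSPECIFIED = "UNSPECIFIED"


@dataclass
class GeneAnnotation:
    """A gene interval in 0-based half-open coordinates."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene}: start must be < end ({self.start} >= {self.end})"
            )


@dataclass
class ProbeTrack:
    """Ordered per-probe log2 ratios for one tumor component.

    ``probes`` holds columns probe_id, chrom, start, end (1-based inclusive)
    and log2ratio; rows are sorted by (chrom natural order, start) and starts
    are strictly increasing within a chromosome. Missing log2 values are
    carried as NaN (flagged via :attr:`missing`), never dropped.
    """

    sample_id: str
    component_label: ComponentLabel
    probes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.component_label = ComponentLabel(self.component_label)
        self.probes = _validate_probe_frame(self.probes)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def missing(self) -> np.ndarray:
        return self.probes["log2ratio"].isna().to_numpy()

    @property
    def chroms(self) -> list[str]:
        """Chromosomes present, in natural order."""
        seen = self.probes["chrom"].unique().tolist()
        return sorted(seen, key=chrom_sort_key)

    def values_for(self, chrom: str) -> np.ndarray:
        return self.probes.loc[self.probes["chrom"] == chrom, "log2ratio"].to_numpy()

    def chrom_slices(self) -> dict[str, slice]:
        """Row slice per chromosome (rows are contiguous after sorting)."""
        out: dict[str, slice] = {}
        codes = self.probes["chrom"].to_numpy()
        for chrom in self.chroms:
            idx = np.flatnonzero(codes == chrom)
            out[chrom] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out


def _validate_probe_frame(df: pd.DataFrame) -> pd.DataFrame:
    required = ["probe_id", "chrom", "start", "end", "log2ratio"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"probe table missing columns: {missing_cols}")
    df = df[required].copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] > df["end"]).any():
        bad = df.index[df["start"] > df["end"]].tolist()[:5]
        raise ValueError(f"probes with start > end at rows {bad}")
    # duplicate (chrom, start) cannot be ordered deterministically
    dup = df.duplicated(subset=["chrom", "start"])
    if dup.any():
        pairs = df.loc[dup, ["chrom", "start"]].head(5).to_records(index=False)
        raise ValueError(f"duplicate probe positions: {list(pairs)}")
    key = [chrom_sort_key(c) for c in df["chrom"]]
    order = sorted(range(len(df)), key=lambda i: (key[i], df["start"].iat[i]))
    if order != list(range(len(df))):
        logger.warning("probe table not sorted; re-sorting %d rows", len(df))
        df = df.iloc[order]
    return df.reset_index(drop=True)


def read_probe_table(path, component_label=ComponentLabel.UNSPECIFIED,
                     sample_id: str | None = None) -> ProbeTrack:
    """Read a tab-separated probe table into a sorted, validated track.

    Missing log2 values (``NA``/``NaN``/empty/``.``) are flagged, not
    dropped; any other non-numeric log2 entry is a record-level error listing
    the offending line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    vals = df["log2ratio"].str.strip() if "log2ratio" in df.columns else None
    if vals is None:
        raise ValueError(f"{path}: probe table missing column 'log2ratio'")
    is_missing = vals.str.lower().isin(_MISSING_TOKENS)
    numeric = pd.to_numeric(vals.where(~is_missing), errors="coerce")
    bad = (~is_missing) & numeric.isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # header is line 1
        raise ValueError(f"{path}: non-numeric log2ratio on lines {lines}")
    if not np.isfinite(numeric.dropna()).all():
        raise ValueError(f"{path}: non-finite log2ratio values")
    df["log2ratio"] = numeric
    n_missing = int(is_missing.sum())
    if n_missing:
        logger.warning("%s: %d probes with missing log2 ratio (flagged)", path, n_missing)
    return ProbeTrack(
        sample_id=sample_id or path.stem,
        component_label=component_label,
        probes=df,
    )


def write_probe_table(track: ProbeTrack, path) -> None:
    df = track.probes.copy()
    df["log2ratio"] = df["log2ratio"].map(
        lambda v: "NA" if pd.isna(v) else f"{v:.6f}"
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_bed(path) -> list[GeneAnnotation]:
    """Read a BED4 (chrom, start, end, name) gene annotation, sorted and
    deduplicated."""
    genes: list[GeneAnnotation] = []
    seen: set[tuple] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = re.split(r"\s+", line)
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED fields")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            key = (name, chrom, start, end)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            genes.append(GeneAnnotation(gene=name, chrom=chrom, start=start, end=end))
    if n_dup:
        logger.warning("%s: %d duplicate gene rows dropped", path, n_dup)
    genes.sort(key=lambda g: (chrom_sort_key(g.chrom), g.start, g.end, g.gene))
    return genes


def write_gene_bed(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene}\n")


_SEG_COLUMNS = ["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def write_seg(profiles, path) -> None:
    """Export segment profiles as a SEG file.

    Accepts one :class:`~her2het.segmentation.SegmentProfile` or an iterable
    of them. Segments must be non-overlapping within sample x chromosome.
    """
    from .segmentation import SegmentProfile  # local import to avoid a cycle

    if isinstance(profiles, SegmentProfile):
        profiles = [profiles]
    rows = []
    for prof in profiles:
        by_chrom: dict[str, list] = {}
        for seg in prof.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.genomic_start)
            for a, b in zip(segs, segs[1:]):
                if b.genomic_start <= a.genomic_end:
                    raise ValueError(
                        f"overlapping segments in {prof.sample_id} {chrom}: "
                        f"[{a.genomic_start},{a.genomic_end}] and "
                        f"[{b.genomic_start},{b.genomic_end}]"
                    )
        for seg in prof.segments:
            rows.append(
                {
                    "sample": prof.sample_id,
                    "chrom": seg.chrom,
                    "loc.start": seg.genomic_start,
                    "loc.end": seg.genomic_end,
                    "num.mark": seg.n_probes,
                    "seg.mean": f"{seg.seg_mean:.6f}",
                }
            )
    pd.DataFrame(rows, columns=_SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file back as a DataFrame with typed columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: SEG file missing columns {missing}")
    df["loc.start"] = df["loc.start"].astype(np.int64)
    df["loc.end"] = df["loc.end"].astype(np.int64)
    df["num.mark"] = df["num.mark"].astype(np.int64)
    df["seg.mean"] = df["seg.mean"].astype(float)
    return df


_MUTATION_COLUMNS = [
    "case", "component", "gene", "chrom", "pos", "ref", "alt",
    "alt_reads", "total_reads", "purity", "local_cn",
]


def read_mutation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mutation table missing columns {missing}")
    for col in ("pos", "alt_reads", "total_reads", "local_cn"):
        df[col] = df[col].astype(np.int64)
    df["purity"] = df["purity"].astype(float)
    if ((df["alt_reads"] < 0) | (df["alt_reads"] > df["total_reads"])).any():
        raise ValueError(f"{path}: alt_reads outside [0, total_reads]")
    if ((df["purity"] <= 0) | (df["purity"] > 1)).any():
        raise ValueError(f"{path}: purity outside (0, 1]")
    return df[_MUTATION_COLUMNS + [c for c in df.columns if c not in _MUTATION_COLUMNS]]


def write_mutation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
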