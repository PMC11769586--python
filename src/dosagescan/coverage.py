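"""Per-base depth tracks and masked sliding-window mean depths.

Depth is counted per aligned base (CIGAR-aware: M/=/X consume coverage,
deletions and skips do not) from alignments that survive a mapping-quality
floor and optional PCR-duplicate removal.  Window means are taken over the
*unmasked* bases only; a window losing more than the exclusion fraction of
its span to the mask carries no usable mean and is flagged excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import pysam

from .refbuild import SubgenomeRegistry

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .maskfilters import AnalysisMask

__all__ = [
    "DepthTrack",
    "depth_from_alignments",
    "depth_from_table",
    "window_means",
    "write_window_table",
    "read_window_table",
]

WINDOW_COLUMNS = ["chrom", "start", "end", "masked_fraction", "D", "excluded", "score"]


@dataclass
class DepthTrack:
    """Per-base read depth for every chromosome of the reference."""

    data: dict[str, np.ndarray] = field(default_factory=dict)

    def get(self, chrom: str) -> np.ndarray:
        if chrom not in self.data:
            raise KeyError(chrom)
        return self.data[chrom]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def scaled(self, factor: int) -> "DepthTrack":
        return DepthTrack({c: a * factor for c, a in self.data.items()})

    # -- I/O -------------------------------------------------------------

    def to_table(self, path: str | Path, *, skip_zero: bool = True) -> None:
        """Write as 3-column text (chrom, 1-based pos, depth), the
        ``samtools depth`` convention; zero-depth bases are omitted by
        default and implied on reload."""
        with open(path, "w") as fh:
            for chrom, arr in self.data.items():
                idx = np.flatnonzero(arr) if skip_zero else np.arange(len(arr))
                pd.DataFrame(
                    {"chrom": chrom, "pos": idx + 1, "depth": arr[idx]}
                ).to_csv(fh, sep="\t", header=False, index=False)


def depth_from_table(path: str | Path, registry: SubgenomeRegistry) -> DepthTrack:
    """Load a 3-column per-base depth table (chrom, 1-based pos, depth).

    Positions absent from the table have depth 0; every registry
    chromosome gets a full-length track.
    """
    lengths = registry.lengths
    data = {c: np.zeros(n, dtype=np.int64) for c, n in lengths.items()}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "depth"],
        dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
    )
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in data:
            raise ValueError(f"depth table references unknown chromosome {chrom!r}")
        data[chrom][sub["pos"].to_numpy() - 1] = sub["depth"].to_numpy()
    return DepthTrack(data)


def depth_from_alignments(
    alignments: str | Path,
    registry: SubgenomeRegistry,
    *,
    min_mapq: int = 60,
    drop_duplicates: bool = True,
) -> DepthTrack:
    """Per-base depth from a coordinate-sorted BAM/SAM/CRAM file.

    Only primary, mapped reads with mapping quality ≥ ``min_mapq`` count;
    reads flagged as PCR/optical duplicates are skipped when
    ``drop_duplicates`` is set.  Coverage follows the aligned blocks of
    each read, so deletions and introns inside a read do not add depth.
    """
    lengths = registry.lengths
    path = str(alignments)
    mode = "r" if path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(path, mode) as af:
        ref_names = set(af.references or ())
        unknown = ref_names - set(lengths)
        if ref_names and not (ref_names & set(lengths)):
            raise ValueError(
                "alignment file references none of the registry chromosomes; "
                f"was it aligned to a different reference? ({sorted(unknown)[:3]}...)"
            )
        # difference-array accumulation, one cumsum per chromosome
        diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in lengths.items()}
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if drop_duplicates and read.is_duplicate:
                continue
            chrom = read.reference_name
            if chrom not in diffs:
                continue
            d = diffs[chrom]
            n = lengths[chrom]
            for s, e in read.get_blocks():
                s, e = max(0, s), min(n, e)
                if s < e:
                    d[s] += 1
                    d[e] -= 1
    return DepthTrack({c: np.cumsum(d[:-1]) for c, d in diffs.items()})


def window_means(
    track: DepthTrack,
    mask: "AnalysisMask | None" = None,
    *,
    window: int = 2_000_000,
    step: int = 500_000,
    exclusion_fraction: float = 0.95,
) -> pd.DataFrame:
    """Sliding-window mean depth over unmasked bases.

    Windows of ``window`` bases are laid at every ``step`` along each
    chromosome (the terminal windows truncate at the chromosome end).  For
    each window, ``masked_fraction`` is the masked share of its span and
    ``D`` the mean depth over its unmasked bases.  A window whose masked
    fraction strictly exceeds ``exclusion_fraction`` is flagged excluded
    and never receives a score; the default reads the "over 95 %" rule
    literally, so a window exactly 95 % masked is kept.

    Returns a table with columns chrom, start, end, masked_fraction, D,
    excluded, score (score is NaN until scoring).
    """
    if step <= 0 or window < step:
        raise ValueError(f"require window >= step > 0, got window={window}, step={step}")
    rows = []
    for chrom, depth in track.data.items():
        n = len(depth)
        masked = (
            mask.bool_array(chrom)
            if mask is not None and chrom in mask.chrom_lengths
            else np.zeros(n, dtype=bool)
        )
        cum_depth = np.concatenate(([0], np.cumsum(np.where(masked, 0, depth), dtype=np.int64)))
        cum_mask = np.concatenate(([0], np.cumsum(masked, dtype=np.int64)))
        for start in range(0, n, step):
            end = min(start + window, n)
            span = end - start
            n_masked = int(cum_mask[end] - cum_mask[start])
            frac = n_masked / span
            n_open = span - n_masked
            excl = frac > exclusion_fraction or n_open == 0
            d = (cum_depth[end] - cum_depth[start]) / n_open if n_open else np.nan
            rows.append((chrom, start, end, frac, d, excl, np.nan))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def write_window_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_window_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["excluded"] = df["excluded"].astype(bool)
    for col in ("start", "end"):
        df[col] = df[col].astype(np.int64)
    for col in ("masked_fraction", "D", "score"):
        df[col] = df[col].astype(np.float64)
    return df[WINDOW_COLUMNS]
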