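"""Filter cascade producing the per-chromosome exclusion mask.

Raw read-depth over an allopolyploid pseudo-reference is distorted by
repeats, by regions whose homoeologous relationship is absent or ambiguous,
and by regions where reads from one subgenome cross-map onto the other.
Three filters remove these before any dosage is computed:

* **repeat filter** — excludes annotated repeat intervals (RepeatMasker
  ``.out`` or BED input);
* **multi-/non-homoeologous filter** — from a synteny map between the two
  subgenomes, excludes positions covered by no block (no homoeologous
  counterpart) or by blocks whose partners lie at two or more distinct loci
  (ambiguous homoeology, typically centromeric/TE-driven);
* **ancestral diploid filter** — keeps a base only if it is covered
  (depth > 0) in *all* sequenced accessions of its own ancestral diploid
  and uncovered (depth = 0) in *all* accessions of the other ancestor.

Filters are evaluated at base resolution internally; masks are stored as
merged intervals tagged with the originating filter so a window's masked
fraction is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np

from ._intervals import bool_to_intervals, merge_intervals
from .refbuild import SubgenomeRegistry

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .coverage import DepthTrack

__all__ = [
    "AnalysisMask",
    "SyntenyBlock",
    "AncestralPanel",
    "repeat_filter",
    "homoeology_filter",
    "ancestral_filter",
    "merge_masks",
    "read_bed_intervals",
    "read_repeatmasker_out",
    "read_paf_blocks",
]

MASK_SOURCES = ("repeat", "multi_homoeolog", "non_homoeolog", "ancestral")


@dataclass
class AnalysisMask:
    """Excluded intervals per chromosome, tagged by originating filter.

    ``intervals[chrom]`` holds 0-based half-open ``(start, end, source)``
    records.  Records from different sources may overlap; :meth:`merged`
    gives the disjoint source-agnostic union actually applied downstream.
    """

    chrom_lengths: dict[str, int]
    intervals: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, source: str) -> None:
        if source not in MASK_SOURCES:
            raise ValueError(f"unknown mask source {source!r}")
        length = self.chrom_lengths[chrom]
        s, e = max(0, int(start)), min(length, int(end))
        if s >= e:
            return
        self.intervals.setdefault(chrom, []).append((s, e, source))
        self.intervals[chrom].sort()

    def merged(self, chrom: str) -> list[tuple[int, int]]:
        """Sorted disjoint union of all masked intervals on ``chrom``."""
        return merge_intervals([(s, e) for s, e, _ in self.intervals.get(chrom, [])])

    def bool_array(self, chrom: str) -> np.ndarray:
        """Per-base masked indicator for ``chrom``."""
        arr = np.zeros(self.chrom_lengths[chrom], dtype=bool)
        for s, e in self.merged(chrom):
            arr[s:e] = True
        return arr

    def masked_bases(self, chrom: str) -> int:
        return sum(e - s for s, e in self.merged(chrom))

    # -- I/O -------------------------------------------------------------

    def to_bed(self, path: str | Path) -> None:
        """BED with a 4th column naming the originating filter."""
        with open(path, "w") as fh:
            for chrom in self.chrom_lengths:
                for s, e, src in self.intervals.get(chrom, []):
                    fh.write(f"{chrom}\t{s}\t{e}\t{src}\n")

    @classmethod
    def from_bed(cls, path: str | Path, chrom_lengths: dict[str, int]) -> "AnalysisMask":
        mask = cls(dict(chrom_lengths))
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.split()
                chrom, s, e = parts[0], int(parts[1]), int(parts[2])
                src = parts[3] if len(parts) > 3 and parts[3] in MASK_SOURCES else "repeat"
                if chrom not in chrom_lengths:
                    warnings.warn(f"mask BED references unknown chromosome {chrom!r}; skipped")
                    continue
                mask.add(chrom, s, e, src)
        return mask


@dataclass(frozen=True)
class SyntenyBlock:
    """One syntenic block linking an A-subgenome tract to a C-subgenome tract."""

    a_chrom: str
    a_start: int
    a_end: int
    c_chrom: str
    c_start: int
    c_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.a_start >= self.a_end or self.c_start >= self.c_end:
            raise ValueError("degenerate synteny block")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def a_length(self) -> int:
        return self.a_end - self.a_start

    @property
    def c_length(self) -> int:
        return self.c_end - self.c_start

    def project_a_to_c(self, pos: int) -> int:
        """Map an A-side position inside the block to C-side coordinates."""
        frac = (pos - self.a_start) / self.a_length
        if self.strand == "+":
            return int(round(self.c_start + frac * self.c_length))
        return int(round(self.c_end - frac * self.c_length))

    def project_c_to_a(self, pos: int) -> int:
        frac = (pos - self.c_start) / self.c_length
        if self.strand == "+":
            return int(round(self.a_start + frac * self.a_length))
        return int(round(self.a_end - frac * self.a_length))


@dataclass
class AncestralPanel:
    """Depth tracks of resequenced accessions of the two ancestral diploids.

    Each accession is ``(id, subgenome_of_origin, depth_track)`` where the
    track covers the full concatenated reference.
    """

    accessions: list[tuple[str, str, "DepthTrack"]]

    def __post_init__(self) -> None:
        subs = {s for _, s, _ in self.accessions}
        for needed in ("A", "C"):
            if needed not in subs:
                raise ValueError(f"ancestral panel has no {needed}-origin accession")


# ---------------------------------------------------------------------------
# input parsers


def read_bed_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """BED file → per-chromosome interval lists (first three columns)."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return out


def read_repeatmasker_out(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """RepeatMasker ``.out`` annotation → per-chromosome repeat intervals.

    The format carries three header lines and 1-based inclusive query
    coordinates in columns 5–7.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 7 or not parts[0].isdigit():
                continue  # header / blank lines
            chrom, begin, end = parts[4], int(parts[5]), int(parts[6])
            out.setdefault(chrom, []).append((begin - 1, end))
    return out


def read_paf_blocks(
    path: str | Path,
    registry: SubgenomeRegistry,
    *,
    min_block_len: int = 5000,
    chain_gap: int = 10_000,
) -> list[SyntenyBlock]:
    """Read pairwise alignments (PAF) into filtered synteny blocks.

    Records aligning an A-subgenome chromosome to a C-subgenome chromosome
    are kept (either orientation of query/target); colinear records on the
    same chromosome pair and strand are chained when both coordinate gaps
    are at most ``chain_gap``; chains shorter than ``min_block_len`` on
    either side are dropped, mirroring a minimum-anchor-length synteny
    screen.
    """
    raw: list[SyntenyBlock] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            qname, qstart, qend = p[0], int(p[2]), int(p[3])
            strand, tname, tstart, tend = p[4], p[5], int(p[7]), int(p[8])
            try:
                q_sub = registry.subgenome_of(qname)
                t_sub = registry.subgenome_of(tname)
            except KeyError:
                continue
            if q_sub == t_sub:
                continue
            if q_sub == "A":
                raw.append(SyntenyBlock(qname, qstart, qend, tname, tstart, tend, strand))
            else:
                raw.append(SyntenyBlock(tname, tstart, tend, qname, qstart, qend, strand))

    # minimal chainer: merge colinear neighbours on the same pair/strand
    raw.sort(key=lambda b: (b.a_chrom, b.c_chrom, b.strand, b.a_start))
    chained: list[SyntenyBlock] = []
    for b in raw:
        if chained:
            last = chained[-1]
            same = (last.a_chrom, last.c_chrom, last.strand) == (b.a_chrom, b.c_chrom, b.strand)
            if (
                same
                and 0 <= b.a_start - last.a_end <= chain_gap
                and (
                    (b.strand == "+" and 0 <= b.c_start - last.c_end <= chain_gap)
                    or (b.strand == "-" and 0 <= last.c_start - b.c_end <= chain_gap)
                )
            ):
                chained[-1] = SyntenyBlock(
                    last.a_chrom,
                    last.a_start,
                    b.a_end,
                    last.c_chrom,
                    min(last.c_start, b.c_start),
                    max(last.c_end, b.c_end),
                    last.strand,
                )
                continue
        chained.append(b)
    return [b for b in chained if b.a_length >= min_block_len and b.c_length >= min_block_len]


# ---------------------------------------------------------------------------
# filters


def repeat_filter(
    annotations: dict[str, list[tuple[int, int]]] | str | Path,
    registry: SubgenomeRegistry,
) -> AnalysisMask:
    """Mask the union of annotated repeat intervals.

    ``annotations`` may be a per-chromosome interval dict, a BED path, or a
    RepeatMasker ``.out`` path.  Intervals on unknown chromosomes are
    skipped with a warning; intervals extending past a chromosome end are
    clipped with a warning.
    """
    if isinstance(annotations, (str, Path)):
        p = Path(annotations)
        annotations = (
            read_repeatmasker_out(p) if p.suffix == ".out" else read_bed_intervals(p)
        )
    lengths = registry.lengths
    mask = AnalysisMask(lengths)
    for chrom, ivs in annotations.items():
        if chrom not in lengths:
            warnings.warn(f"repeat annotation on unknown chromosome {chrom!r}; skipped")
            continue
        length = lengths[chrom]
        merged = []
        for s, e in ivs:
            if s < 0 or e > length:
                warnings.warn(
                    f"repeat interval {chrom}:{s}-{e} outside chromosome bounds; clipped"
                )
            s, e = max(0, s), min(length, e)
            if s < e:
                merged.append((s, e))
        for s, e in merge_intervals(merged):
            mask.add(chrom, s, e, "repeat")
    return mask


def _partner_loci_distinct(
    p1: tuple[str, int, int], p2: tuple[str, int, int]
) -> bool:
    """Two partner intervals count as distinct homoeologous loci when they
    sit on different chromosomes, or on the same chromosome neither overlap
    nor lie within one block length (the longer of the two) of each other."""
    c1, s1, e1 = p1
    c2, s2, e2 = p2
    if c1 != c2:
        return True
    if s1 < e2 and s2 < e1:  # overlap
        return False
    gap = max(s1, s2) - min(e1, e2)
    return gap > max(e1 - s1, e2 - s2)


def _count_partner_loci(partners: list[tuple[str, int, int]]) -> int:
    """Number of distinct partner-locus clusters (single-linkage)."""
    clusters: list[list[tuple[str, int, int]]] = []
    for p in partners:
        hit = None
        for cl in clusters:
            if any(not _partner_loci_distinct(p, q) for q in cl):
                hit = cl
                break
        if hit is None:
            clusters.append([p])
        else:
            hit.append(p)
    # merge clusters linked through a shared member
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(
                    not _partner_loci_distinct(p, q)
                    for p in clusters[i]
                    for q in clusters[j]
                ):
                    clusters[i].extend(clusters.pop(j))
                    changed = True
                    break
            if changed:
                break
    return len(clusters)


def homoeology_filter(
    blocks: Iterable[SyntenyBlock],
    registry: SubgenomeRegistry,
    *,
    min_block_len: int = 5000,
    max_partner_loci: int = 1,
) -> AnalysisMask:
    """Mask non-homoeologous and ambiguously homoeologous positions.

    A position is masked ``non_homoeolog`` when no synteny block covers it,
    and ``multi_homoeolog`` when the blocks covering it place its partner at
    more than ``max_partner_loci`` distinct loci of the other subgenome.
    Blocks shorter than ``min_block_len`` on either side are ignored.
    """
    blocks = [
        b for b in blocks if b.a_length >= min_block_len and b.c_length >= min_block_len
    ]
    for b in blocks:
        if registry.subgenome_of(b.a_chrom) == registry.subgenome_of(b.c_chrom):
            raise ValueError(
                f"synteny block joins two {registry.subgenome_of(b.a_chrom)}-subgenome "
                f"chromosomes: {b.a_chrom} / {b.c_chrom}"
            )

    mask = AnalysisMask(registry.lengths)
    for chrom in registry.names:
        sub = registry.subgenome_of(chrom)
        length = registry.lengths[chrom]
        own: list[tuple[int, int, tuple[str, int, int]]] = []
        for b in blocks:
            if sub == "A" and b.a_chrom == chrom:
                own.append((b.a_start, b.a_end, (b.c_chrom, b.c_start, b.c_end)))
            elif sub == "C" and b.c_chrom == chrom:
                own.append((b.c_start, b.c_end, (b.a_chrom, b.a_start, b.a_end)))
        # elementary segments between block boundaries share a covering set
        cuts = sorted({0, length} | {s for s, _, _ in own} | {e for _, e, _ in own})
        cuts = [c for c in cuts if 0 <= c <= length]
        non: list[tuple[int, int]] = []
        multi: list[tuple[int, int]] = []
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            covering = [p for s, e, p in own if s <= lo and hi <= e]
            if not covering:
                non.append((lo, hi))
            elif _count_partner_loci(covering) > max_partner_loci:
                multi.append((lo, hi))
        for s, e in merge_intervals(non):
            mask.add(chrom, s, e, "non_homoeolog")
        for s, e in merge_intervals(multi):
            mask.add(chrom, s, e, "multi_homoeolog")
    return mask


def ancestral_filter(
    panel: AncestralPanel,
    registry: SubgenomeRegistry,
    *,
    min_own_depth: int = 1,
    max_other_depth: int = 0,
) -> AnalysisMask:
    """Mask positions failing the ancestral-diploid coverage rule.

    A base on an A-subgenome chromosome is retained iff its depth is
    ≥ ``min_own_depth`` in every A-origin accession *and* ≤
    ``max_other_depth`` in every C-origin accession; symmetrically for
    C-subgenome bases.  The defaults implement the strict "> 0 in all own,
    = 0 in all other" rule; raise the thresholds for noisy panels.
    """
    mask = AnalysisMask(registry.lengths)
    for chrom in registry.names:
        sub = registry.subgenome_of(chrom)
        length = registry.lengths[chrom]
        retained = np.ones(length, dtype=bool)
        for acc_id, origin, track in panel.accessions:
            try:
                depth = track.get(chrom)
            except KeyError as exc:
                raise ValueError(
                    f"accession {acc_id!r} has no depth track for {chrom!r}"
                ) from exc
            if origin == sub:
                retained &= depth >= min_own_depth
            else:
                retained &= depth <= max_other_depth
        for s, e in bool_to_intervals(~retained):
            mask.add(chrom, s, e, "ancestral")
    return mask


def merge_masks(masks: list[AnalysisMask]) -> AnalysisMask:
    """Union of masks sharing one registry; source tags are preserved on
    the pre-merge records (the applied mask is their disjoint union)."""
    if not masks:
        raise ValueError("no masks to merge")
    lengths = masks[0].chrom_lengths
    for m in masks[1:]:
        if m.chrom_lengths != lengths:
            raise ValueError("masks built against different registries")
    out = AnalysisMask(dict(lengths))
    for m in masks:
        for chrom, ivs in m.intervals.items():
            for s, e, src in ivs:
                out.add(chrom, s, e, src)
    return out
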