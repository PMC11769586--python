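"""Calling homoeologous-exchange events from dosage-score profiles.

A homoeologous recombination (HR) between the A and C subgenomes shows up
as paired, syntenically matched shifts in the dosage score: e.g. in a
backcross individual an A-chromosome drop 2→1 opposite a C-chromosome rise
0→1.  This module

* segments each chromosome's score profile wherever the score shifts by
  more than a threshold (default 0.5, the value used for event counting),
* pairs A- and C-side segment boundaries through the subgenome synteny
  map,
* classifies events as ``unique`` (one backcross individual — arose at F1
  meiosis) or ``common`` (shared — candidate native exchange of the
  allotetraploid parent),
* types candidate native events from the parent's own dosage profile
  (reciprocal: both homoeologs ~2 throughout; nonreciprocal: ~0 on the
  lost tract, ~4 on its duplicated counterpart), and
* refines a coarse boundary to ~1 kb using fine windows and then a
  per-base two-fold depth-contrast scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coverage import DepthTrack
from .maskfilters import SyntenyBlock
from .refbuild import SubgenomeRegistry

__all__ = [
    "DosageSegment",
    "Site",
    "HREvent",
    "segment_scores",
    "pair_events",
    "classify_provenance",
    "classify_native_type",
    "refine_breakpoint",
    "write_events_tsv",
    "read_events_tsv",
    "write_events_json",
    "write_segments_tsv",
]


@dataclass(frozen=True)
class DosageSegment:
    """A maximal run of windows sharing one dosage level."""

    chrom: str
    start: int
    end: int
    state: int  # mean score rounded to the nearest integer
    mean_score: float
    n_windows: int = 0


@dataclass(frozen=True)
class Site:
    """Breakpoint neighbourhood on one chromosome (half-open interval)."""

    chrom: str
    start: int
    end: int

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class HREvent:
    """A (putative) homoeologous-exchange event.

    ``a_site``/``c_site`` bracket the breakpoints on the two homoeologs;
    one may be None when a score shift found no syntenic counterpart
    (``type`` stays ``unknown`` then).  ``a_delta``/``c_delta`` record the
    dosage-state change across each boundary (right minus left).
    """

    a_site: Site | None
    c_site: Site | None
    type: str = "unknown"  # reciprocal | nonreciprocal | unknown
    provenance: str | None = None  # unique | common | native
    individuals: list[str] = field(default_factory=list)
    a_delta: int | None = None
    c_delta: int | None = None


# ---------------------------------------------------------------------------
# segmentation


def segment_scores(
    table: pd.DataFrame, *, shift_threshold: float = 0.5, mode: str = "running_mean"
) -> list[DosageSegment]:
    """Group consecutive non-excluded windows into constant-dosage segments.

    A new segment opens at a window whose score departs from the current
    segment's running mean score (``mode='running_mean'``, robust to lone
    noisy windows) or from the previous window's score
    (``mode='adjacent'``) by more than ``shift_threshold``.  Interior
    segment boundaries are placed at the first window of the new segment,
    so segments tile the covered span contiguously.  Chromosomes whose
    windows are all excluded yield no segments, with a warning.
    """
    if mode not in ("running_mean", "adjacent"):
        raise ValueError(f"unknown segmentation mode {mode!r}")
    segments: list[DosageSegment] = []
    for chrom, sub in table.groupby("chrom", sort=False):
        sub = sub[~sub["excluded"] & sub["score"].notna()].sort_values("start")
        if sub.empty:
            warnings.warn(f"all windows excluded on {chrom}; no segmentation")
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        scores = sub["score"].to_numpy(dtype=float)
        runs: list[tuple[int, int]] = []  # index ranges [i, j)
        i = 0
        acc = scores[0]
        for j in range(1, len(scores)):
            ref = acc / (j - i) if mode == "running_mean" else scores[j - 1]
            if abs(scores[j] - ref) > shift_threshold:
                runs.append((i, j))
                i = j
                acc = scores[j]
            else:
                acc += scores[j]
        runs.append((i, len(scores)))
        for k, (i, j) in enumerate(runs):
            mean = float(scores[i:j].mean())
            seg_start = int(starts[i]) if k > 0 else int(starts[0])
            seg_end = int(starts[runs[k + 1][0]]) if k + 1 < len(runs) else int(ends[j - 1])
            segments.append(
                DosageSegment(chrom, seg_start, seg_end, int(round(mean)), mean, j - i)
            )
    return segments


def _boundaries(segments: list[DosageSegment]) -> dict[str, list[tuple[int, int]]]:
    """Per chromosome: (position, state delta) at each segment junction."""
    out: dict[str, list[tuple[int, int]]] = {}
    by_chrom: dict[str, list[DosageSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for left, right in zip(segs[:-1], segs[1:]):
            out.setdefault(chrom, []).append((right.start, right.state - left.state))
    return out


# ---------------------------------------------------------------------------
# event pairing


def _project(pos: int, chrom: str, blocks: list[SyntenyBlock], a_to_c: bool) -> int | None:
    """Map a position through the synteny block containing (or nearest to) it."""
    own = [
        b
        for b in blocks
        if (b.a_chrom if a_to_c else b.c_chrom) == chrom
    ]
    if not own:
        return None
    def dist(b: SyntenyBlock) -> int:
        s, e = (b.a_start, b.a_end) if a_to_c else (b.c_start, b.c_end)
        return 0 if s <= pos < e else min(abs(pos - s), abs(pos - e))
    best = min(own, key=dist)
    s, e = (best.a_start, best.a_end) if a_to_c else (best.c_start, best.c_end)
    clamped = min(max(pos, s), e - 1)
    return best.project_a_to_c(clamped) if a_to_c else best.project_c_to_a(clamped)


def pair_events(
    segments: list[DosageSegment],
    registry: SubgenomeRegistry,
    synteny: list[SyntenyBlock],
    *,
    neighborhood: int = 2_000_000,
    boundary_halfwidth: int = 500_000,
) -> list[HREvent]:
    """Pair A- and C-side segment boundaries into candidate HR events.

    An A-chromosome boundary is paired with a boundary on its homoeologous
    partner when the synteny map projects it within ``neighborhood`` bases
    of that boundary.  Each boundary is used at most once (nearest match
    first).  Unpaired boundaries become single-sided events of type
    ``unknown``.  Sites bracket each boundary by ``boundary_halfwidth`` on
    either side, clipped to the chromosome.
    """
    lengths = registry.lengths
    bnd = _boundaries(segments)

    def site(chrom: str, pos: int) -> Site:
        return Site(
            chrom,
            max(0, pos - boundary_halfwidth),
            min(lengths[chrom], pos + boundary_halfwidth),
        )

    events: list[HREvent] = []
    for a_chrom, c_chrom in registry.homoeolog_pairs:
        a_bnds = bnd.get(a_chrom, [])
        c_bnds = bnd.get(c_chrom, [])
        # nearest-first greedy matching on projected distance
        candidates = []
        for ai, (ap, _) in enumerate(a_bnds):
            proj = _project(ap, a_chrom, synteny, a_to_c=True)
            if proj is None:
                continue
            for ci, (cp, _) in enumerate(c_bnds):
                d = abs(cp - proj)
                if d <= neighborhood:
                    candidates.append((d, ai, ci))
        candidates.sort()
        matched_a: set[int] = set()
        matched_c: set[int] = set()
        for _, ai, ci in candidates:
            if ai in matched_a or ci in matched_c:
                continue
            matched_a.add(ai)
            matched_c.add(ci)
            ap, ad = a_bnds[ai]
            cp, cd = c_bnds[ci]
            events.append(
                HREvent(site(a_chrom, ap), site(c_chrom, cp), a_delta=ad, c_delta=cd)
            )
        for ai, (ap, ad) in enumerate(a_bnds):
            if ai not in matched_a:
                events.append(HREvent(site(a_chrom, ap), None, a_delta=ad))
        for ci, (cp, cd) in enumerate(c_bnds):
            if ci not in matched_c:
                events.append(HREvent(None, site(c_chrom, cp), c_delta=cd))
    # boundaries on chromosomes with no homoeologous partner
    paired_chroms = {c for pair in registry.homoeolog_pairs for c in pair}
    for chrom, blist in bnd.items():
        if chrom in paired_chroms:
            continue
        for pos, delta in blist:
            if registry.subgenome_of(chrom) == "A":
                events.append(HREvent(site(chrom, pos), None, a_delta=delta))
            else:
                events.append(HREvent(None, site(chrom, pos), c_delta=delta))
    return events


# ---------------------------------------------------------------------------
# provenance across individuals


def _event_key(ev: HREvent) -> tuple[str, str]:
    a = ev.a_site.chrom if ev.a_site else "."
    c = ev.c_site.chrom if ev.c_site else "."
    return (a, c)


def _co_localized(e1: HREvent, e2: HREvent, neighborhood: int) -> bool:
    if _event_key(e1) != _event_key(e2):
        return False
    for s1, s2 in ((e1.a_site, e2.a_site), (e1.c_site, e2.c_site)):
        if s1 is not None and s2 is not None and abs(s1.mid - s2.mid) > neighborhood:
            return False
    return True


def classify_provenance(
    events_by_individual: dict[str, list[HREvent]],
    *,
    min_shared: int = 2,
    neighborhood: int = 2_000_000,
) -> list[HREvent]:
    """Label events ``common`` or ``unique`` across backcross individuals.

    Events from different individuals are considered the same when they
    involve the same homoeolog pair and their boundary neighbourhoods lie
    within ``neighborhood`` (one coarse window by default).  An event seen
    in ≥ ``min_shared`` individuals is ``common`` (candidate native
    exchange of the parent); otherwise ``unique`` (arisen at F1 meiosis).

    Returns one representative event per cluster with ``individuals``
    listing its carriers.
    """
    clusters: list[tuple[HREvent, set[str]]] = []
    for indiv, events in events_by_individual.items():
        for ev in events:
            for rep, members in clusters:
                if _co_localized(rep, ev, neighborhood):
                    members.add(indiv)
                    break
            else:
                clusters.append((replace(ev), {indiv}))
    out = []
    for rep, members in clusters:
        rep.individuals = sorted(members)
        rep.provenance = "common" if len(members) >= min_shared else "unique"
        out.append(rep)
    return out


# ---------------------------------------------------------------------------
# native-event typing from the allotetraploid parent


def _flank_means(
    table: pd.DataFrame, chrom: str, pos: int, span: int
) -> tuple[float, float]:
    sub = table[(table["chrom"] == chrom) & ~table["excluded"] & table["score"].notna()]
    mids = (sub["start"] + sub["end"]) / 2
    left = sub[(mids >= pos - span) & (mids < pos)]["score"]
    right = sub[(mids >= pos) & (mids < pos + span)]["score"]
    return (
        float(left.mean()) if len(left) else np.nan,
        float(right.mean()) if len(right) else np.nan,
    )


def classify_native_type(
    parent_table: pd.DataFrame,
    event: HREvent,
    *,
    tol: float = 0.5,
    span: int = 2_000_000,
) -> str:
    """Type an event from the allotetraploid parent's dosage profile.

    ``reciprocal``: both homoeologs score within ``tol`` of 2 on both
    sides of the event (a balanced exchange leaves the parent's dosage
    flat).  ``nonreciprocal``: one chromosome's flank scores ~0 while a
    flank of its homoeologous counterpart scores ~4 (substitution that
    duplicated one tract and lost the other).  Any other pattern — e.g. a
    trisomic ~3 carry-over — returns ``unknown`` with a warning.

    The parent table must be scored in allotetraploid mode.
    """
    if event.a_site is None or event.c_site is None:
        warnings.warn("single-sided event cannot be typed from the parent profile")
        return "unknown"
    aL, aR = _flank_means(parent_table, event.a_site.chrom, event.a_site.mid, span)
    cL, cR = _flank_means(parent_table, event.c_site.chrom, event.c_site.mid, span)
    vals = [aL, aR, cL, cR]
    if any(np.isnan(v) for v in vals):
        warnings.warn("parent profile lacks scored windows around the event; cannot type")
        return "unknown"
    if all(abs(v - 2) <= tol for v in vals):
        return "reciprocal"
    for dup, lost in ((aL, (cL, cR)), (aR, (cL, cR)), (cL, (aL, aR)), (cR, (aL, aR))):
        if abs(dup - 4) <= tol and any(abs(v) <= tol for v in lost):
            return "nonreciprocal"
    warnings.warn(
        f"parent dosage pattern (A {aL:.2f}/{aR:.2f}, C {cL:.2f}/{cR:.2f}) matches "
        "neither the reciprocal 2/2 nor the nonreciprocal 0/4 signature"
    )
    return "unknown"


# ---------------------------------------------------------------------------
# breakpoint refinement


def _moving_flanks(depth: np.ndarray, lo: int, hi: int, flank: int):
    """Left/right flank means at every position p in [lo, hi]."""
    n = len(depth)
    lo = max(lo, flank)
    hi = min(hi, n - flank)
    if lo > hi:
        return None
    cum = np.concatenate(([0], np.cumsum(depth, dtype=np.float64)))
    pos = np.arange(lo, hi + 1)
    left = (cum[pos] - cum[pos - flank]) / flank
    right = (cum[pos + flank] - cum[pos]) / flank
    return pos, left, right


def _scan_boundary(
    depth: np.ndarray, lo: int, hi: int, *, flank: int, min_contrast: float = 1.5
) -> int | None:
    """Position in [lo, hi] where the left/right flank-depth contrast is
    largest — the two-fold change point — with ties broken to the lower
    coordinate; or, for absence boundaries, where depth dies out to ~0.
    Returns None when the depth is effectively flat (largest contrast
    below ``min_contrast``, chosen well under the two-fold signal a true
    copy-number step produces)."""
    res = _moving_flanks(depth, lo, hi, flank)
    if res is None:
        return None
    pos, left, right = res
    hi_side = max(left[0], right[-1])
    lo_side = min(left[0], right[-1])
    zero_tol = max(1.0, 0.05 * hi_side)
    dropping = left[0] >= right[-1]
    if lo_side < zero_tol:
        # absence boundary: first position where the low-side flank dies out
        low = right if dropping else left[::-1]
        idx = np.flatnonzero(low < zero_tol)
        if idx.size == 0:
            return None
        p = int(pos[idx[0]]) if dropping else int(pos[::-1][idx[0]])
        # snap to the start (resp. end) of the zero run itself
        if dropping:
            window = depth[max(0, p - flank): p + 1]
            rel = np.flatnonzero(window > 0)
            off = (rel[-1] + 1) if rel.size else 0
            return max(0, p - flank) + int(off)
        window = depth[p: p + flank]
        rel = np.flatnonzero(window > 0)
        return p + int(rel[0]) if rel.size else p
    r = left / np.maximum(right, 1e-9)
    contrast = r if dropping else 1.0 / np.maximum(r, 1e-12)
    best = int(np.argmax(contrast))  # first maximum = lowest coordinate
    if contrast[best] < min_contrast:
        return None
    return int(pos[best])


def refine_breakpoint(
    fine_tables: dict[str, pd.DataFrame],
    tracks: dict[str, DepthTrack],
    expected_scores: dict[str, float],
    candidate_region: tuple[str, int, int],
    *,
    flank: int = 500,
    resolution: int = 1000,
    shift_threshold: float = 0.5,
) -> tuple[str, int, int]:
    """Refine a coarse breakpoint to ~``resolution`` bases.

    Stage 1 intersects, across individuals, the fine windows (10 kb / 5 kb
    scale) inside ``candidate_region`` whose score deviates from the
    expected dosage of that chromosome (``expected_scores[chrom]``, e.g. 2
    for A, 0 or 1 for C) by more than ``shift_threshold``.  Stage 2 scans
    per-base depth inside the intersection for the earliest position whose
    ``flank``-sized left/right mean-depth ratio crosses two-fold (or where
    depth dies to ~0 for absence boundaries) and brackets the consensus
    position at ``resolution``.

    Falls back to the unchanged candidate region, with a warning, when no
    notable fine window or no depth contrast exists; when individuals
    disagree by more than ``flank`` the widest consistent interval is
    returned with a warning.
    """
    chrom, lo, hi = candidate_region
    expected = expected_scores[chrom]

    offset = lo
    width = hi - lo
    inter = np.ones(width, dtype=bool)
    any_notable = False
    for indiv, table in fine_tables.items():
        sub = table[
            (table["chrom"] == chrom)
            & ~table["excluded"]
            & table["score"].notna()
            & (table["end"] > lo)
            & (table["start"] < hi)
        ]
        notable = sub[(sub["score"] - expected).abs() > shift_threshold]
        cover = np.zeros(width, dtype=bool)
        for s, e in zip(notable["start"], notable["end"]):
            cover[max(0, s - offset): min(width, e - offset)] = True
        if cover.any():
            any_notable = True
        inter &= cover
    if not any_notable or not inter.any():
        warnings.warn(
            f"no shared notable fine window in {chrom}:{lo}-{hi}; candidate region kept"
        )
        return candidate_region
    idx = np.flatnonzero(inter)
    scan_lo, scan_hi = offset + int(idx[0]), offset + int(idx[-1]) + 1

    boundaries = []
    for indiv, track in tracks.items():
        depth = track.get(chrom)
        b = _scan_boundary(depth, scan_lo, scan_hi, flank=flank)
        if b is not None:
            boundaries.append(b)
    if not boundaries:
        warnings.warn(
            f"no two-fold depth contrast found in {chrom}:{scan_lo}-{scan_hi}; "
            "candidate region kept"
        )
        return candidate_region
    spread = max(boundaries) - min(boundaries)
    if spread > flank:
        warnings.warn(
            f"individuals disagree on the boundary by {spread} bases (> flank); "
            "returning the widest consistent interval"
        )
        return (chrom, min(boundaries), max(boundaries) + 1)
    center = int(round(float(np.mean(boundaries))))
    left = (center // resolution) * resolution
    return (chrom, left, left + resolution)


# ---------------------------------------------------------------------------
# event and segment I/O

_EVENT_COLS = [
    "a_chrom", "a_start", "a_end", "c_chrom", "c_start", "c_end",
    "type", "provenance", "individuals", "a_delta", "c_delta",
]


def _events_frame(events: list[HREvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        a = ev.a_site or Site(".", -1, -1)
        c = ev.c_site or Site(".", -1, -1)
        rows.append(
            (
                a.chrom, a.start, a.end, c.chrom, c.start, c.end,
                ev.type, ev.provenance or ".", ",".join(ev.individuals) or ".",
                ev.a_delta if ev.a_delta is not None else ".",
                ev.c_delta if ev.c_delta is not None else ".",
            )
        )
    return pd.DataFrame(rows, columns=_EVENT_COLS)


def write_events_tsv(events: list[HREvent], path) -> None:
    _events_frame(events).to_csv(path, sep="\t", index=False)


def write_events_json(events: list[HREvent], path) -> None:
    import json

    _events_frame(events).to_json(path, orient="records", indent=1)
    # normalise to plain JSON text ending with newline
    with open(path, "a") as fh:
        fh.write("\n")


def read_events_tsv(path) -> list[HREvent]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: list[HREvent] = []
    for _, r in df.iterrows():
        a = None if r["a_chrom"] == "." else Site(r["a_chrom"], int(r["a_start"]), int(r["a_end"]))
        c = None if r["c_chrom"] == "." else Site(r["c_chrom"], int(r["c_start"]), int(r["c_end"]))
        out.append(
            HREvent(
                a, c,
                type=r["type"],
                provenance=None if r["provenance"] == "." else r["provenance"],
                individuals=[] if r["individuals"] == "." else r["individuals"].split(","),
                a_delta=None if r["a_delta"] == "." else int(float(r["a_delta"])),
                c_delta=None if r["c_delta"] == "." else int(float(r["c_delta"])),
            )
        )
    return out


def write_segments_tsv(segments: list[DosageSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstate\tmean_score\tn_windows\n")
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.state}\t{s.mean_score:.4f}\t{s.n_windows}\n"
            )
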