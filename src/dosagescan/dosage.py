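"""Dosage scoring: normalized window depth estimating regional copy number.

For a window with mean filtered depth *D* and a normalization median *M*,

    score = (D / M) × 2

so that disomic regions score ~2, monosomic ~1, absent ~0 and tetrasomic
~4.  *M* is the median of *D* over windows of chromosomes assumed disomic:

* **backcross mode** (F1, BC1F1, BC2F1 samples, genome AA(+C parts)): the
  A subgenome is disomic, so M is the median over non-excluded A-subgenome
  windows and is applied genome-wide — introgressed C material then reads
  out at 1 (monosomic) or 0 (absent);
* **allotetraploid mode** (AACC cultivars): each subgenome is normalized
  by its own median, so both read ~2 when disomic and nonreciprocal
  exchanges stand out as 0/4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .refbuild import SubgenomeRegistry

__all__ = ["ScoringContext", "compute_M", "score"]

MODES = ("allotetraploid", "backcross")


@dataclass
class ScoringContext:
    """Normalization constants for dosage scoring.

    ``m`` maps subgenome → median reference depth M.  In backcross mode
    both entries hold the single A-genome median; in allotetraploid mode
    each subgenome carries its own.
    """

    mode: str
    m: dict[str, float]
    registry: SubgenomeRegistry

    def m_for(self, chrom: str) -> float:
        return self.m[self.registry.subgenome_of(chrom)]


def _median_D(table: pd.DataFrame, chroms: list[str], what: str) -> float:
    sel = table[~table["excluded"] & table["chrom"].isin(chroms)]
    if sel.empty:
        raise ValueError(f"no non-excluded windows on {what} chromosomes; cannot compute M")
    m = float(np.median(sel["D"]))
    if m <= 0:
        raise ValueError(f"median depth M on {what} chromosomes is {m}; degenerate library")
    return m


def compute_M(
    table: pd.DataFrame, registry: SubgenomeRegistry, mode: str
) -> ScoringContext:
    """Normalization median(s) from a window table.

    ``mode='backcross'``: M = median D over non-excluded A-subgenome
    windows, applied to every chromosome.  ``mode='allotetraploid'``:
    per-subgenome medians, each applied to its own subgenome.  The median
    of an even number of windows is the mean of the two central values.
    """
    if mode not in MODES:
        raise ValueError(f"unknown scoring mode {mode!r}")
    a_chroms = registry.chromosomes_of("A")
    c_chroms = registry.chromosomes_of("C")
    if mode == "backcross":
        m_a = _median_D(table, a_chroms, "A-subgenome")
        return ScoringContext(mode, {"A": m_a, "C": m_a}, registry)
    m_a = _median_D(table, a_chroms, "A-subgenome")
    m_c = _median_D(table, c_chroms, "C-subgenome")
    return ScoringContext(mode, {"A": m_a, "C": m_c}, registry)


def score(table: pd.DataFrame, ctx: ScoringContext) -> pd.DataFrame:
    """Attach dosage scores: (D / M) × 2 for every non-excluded window.

    Excluded windows keep score NaN (missing, never zero).  Returns a new
    table; the input is not modified.
    """
    out = table.copy()
    m_by_chrom = {c: ctx.m_for(c) for c in out["chrom"].unique()}
    m_vec = out["chrom"].map(m_by_chrom)
    out["score"] = np.where(out["excluded"], np.nan, (out["D"] / m_vec) * 2.0)
    return out
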