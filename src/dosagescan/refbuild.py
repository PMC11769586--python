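"""Concatenated two-subgenome pseudo-reference and the subgenome registry.

An allopolyploid such as *Brassica napus* (AACC) is analysed against a
pseudo-reference built by concatenating the genome assemblies of its two
diploid ancestors (A and C subgenomes).  The :class:`SubgenomeRegistry`
records, for every chromosome of that concatenated reference, which
subgenome it belongs to and which chromosome of the other subgenome is its
homoeologous partner.  Every downstream stage (masking, windowing, scoring,
event calling) consults this registry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Chromosome", "SubgenomeRegistry", "concat_reference", "load_registry"]

SUBGENOMES = ("A", "C")

#: Default pattern recognising unanchored contig/scaffold records.
DEFAULT_CONTIG_PATTERN = r"(?i)^(ctg|contig|scaffold|scf|tig|utg)"


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    subgenome: str  # "A" or "C"


@dataclass
class SubgenomeRegistry:
    """Chromosome → subgenome map with homoeolog pairing.

    Parameters
    ----------
    chromosomes
        Ordered records of the concatenated reference.
    homoeolog_pairs
        ``(a_chrom, c_chrom)`` name pairs linking homoeologous chromosomes.
    """

    chromosomes: list[Chromosome]
    homoeolog_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate chromosome names: {sorted(dup)}")
        for c in self.chromosomes:
            if c.subgenome not in SUBGENOMES:
                raise ValueError(
                    f"unknown subgenome {c.subgenome!r} for {c.name}"
                )
            if c.length <= 0:
                raise ValueError(f"non-positive length for {c.name}")
        by_name = {c.name: c for c in self.chromosomes}
        for a, c in self.homoeolog_pairs:
            if a not in by_name or c not in by_name:
                missing = a if a not in by_name else c
                raise ValueError(f"homoeolog pair references unknown chromosome {missing!r}")
            if by_name[a].subgenome == by_name[c].subgenome:
                raise ValueError(
                    f"homoeolog pair ({a}, {c}) joins chromosomes of the same subgenome"
                )

    # -- lookups ---------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    def subgenome_of(self, name: str) -> str:
        for c in self.chromosomes:
            if c.name == name:
                return c.subgenome
        raise KeyError(name)

    def chromosomes_of(self, subgenome: str) -> list[str]:
        return [c.name for c in self.chromosomes if c.subgenome == subgenome]

    def partner_of(self, name: str) -> str | None:
        """Homoeologous partner chromosome, or None if unpaired."""
        for a, c in self.homoeolog_pairs:
            if a == name:
                return c
            if c == name:
                return a
        return None

    # -- serialisation ---------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: name, length, subgenome, homoeolog ('.' if none)."""
        with open(path, "w") as fh:
            fh.write("name\tlength\tsubgenome\thomoeolog\n")
            for c in self.chromosomes:
                partner = self.partner_of(c.name) or "."
                fh.write(f"{c.name}\t{c.length}\t{c.subgenome}\t{partner}\n")


def load_registry(path: str | Path) -> SubgenomeRegistry:
    """Load a registry manifest written by :meth:`SubgenomeRegistry.to_tsv`.

    Rows give name, length, subgenome and an optional homoeolog partner
    ('.' or empty for none).  Raises ``ValueError`` on unknown subgenome
    labels, duplicate names, or pairs referencing missing/same-subgenome
    chromosomes.
    """
    chroms: list[Chromosome] = []
    raw_pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for col in ("name", "length", "subgenome"):
            if col not in idx:
                raise ValueError(f"registry manifest missing column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[idx["name"]]
            length = int(parts[idx["length"]])
            sub = parts[idx["subgenome"]]
            chroms.append(Chromosome(name, length, sub))
            if "homoeolog" in idx and len(parts) > idx["homoeolog"]:
                partner = parts[idx["homoeolog"]]
                if partner and partner != ".":
                    raw_pairs.append((name, partner))
    # normalise pairs so the A-side chromosome comes first, dropping mirrors
    by_name = {c.name: c for c in chroms}
    pairs: list[tuple[str, str]] = []
    for x, y in raw_pairs:
        if y not in by_name:
            raise ValueError(f"homoeolog pair references unknown chromosome {y!r}")
        if by_name[x].subgenome == by_name[y].subgenome:
            raise ValueError(f"homoeolog pair ({x}, {y}) joins chromosomes of the same subgenome")
        pair = (x, y) if by_name[x].subgenome == "A" else (y, x)
        if pair not in pairs:
            pairs.append(pair)
    return SubgenomeRegistry(chroms, pairs)


def concat_reference(
    fasta_a: str | Path,
    fasta_c: str | Path,
    out_fasta: str | Path,
    *,
    drop_unanchored: bool = True,
    anchored_name_rule: str | None = None,
    pair_by_index: bool = True,
) -> SubgenomeRegistry:
    """Concatenate two ancestor assemblies into one pseudo-reference.

    A-genome records are emitted first, then C-genome records.  When
    ``drop_unanchored`` is set, C-genome records whose names look like
    unanchored contigs (``anchored_name_rule`` gives the *contig-like*
    pattern; default matches ctg/contig/scaffold/tig prefixes) are omitted,
    mirroring the removal of unplaced contigs from the C ancestor assembly
    before concatenation.  A-genome records are treated the same way.

    C-genome record names are kept as-is unless they collide with an
    A-genome name, in which case they gain a ``C_`` prefix so coordinates
    stay citable.  A collision that persists after prefixing is fatal.

    When ``pair_by_index`` is true, the i-th retained A record is paired
    with the i-th retained C record (up to the shorter list) — appropriate
    for ancestor assemblies ordered by homoeology; pass False to leave
    pairing to an explicit manifest.

    Returns the registry describing the emitted reference.
    """
    contig_re = re.compile(anchored_name_rule or DEFAULT_CONTIG_PATTERN)

    def read_records(path: str | Path, label: str) -> list[SeqRecord]:
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise ValueError(f"empty {label}-genome FASTA: {path}")
        return recs

    recs_a = read_records(fasta_a, "A")
    recs_c = read_records(fasta_c, "C")
    if drop_unanchored:
        recs_a = [r for r in recs_a if not contig_re.search(r.id)]
        recs_c = [r for r in recs_c if not contig_re.search(r.id)]
        if not recs_a or not recs_c:
            raise ValueError("all records of one subgenome were dropped as unanchored")

    a_names = {r.id for r in recs_a}
    out_records: list[SeqRecord] = []
    chroms: list[Chromosome] = []
    seen: set[str] = set()
    for r in recs_a:
        if r.id in seen:
            raise ValueError(f"duplicate record name in A-genome input: {r.id!r}")
        seen.add(r.id)
        out_records.append(SeqRecord(Seq(str(r.seq)), id=r.id, description=""))
        chroms.append(Chromosome(r.id, len(r.seq), "A"))
    for r in recs_c:
        name = r.id if r.id not in a_names else f"C_{r.id}"
        if name in seen:
            raise ValueError(f"duplicate record name after prefixing: {name!r}")
        seen.add(name)
        out_records.append(SeqRecord(Seq(str(r.seq)), id=name, description=""))
        chroms.append(Chromosome(name, len(r.seq), "C"))

    pairs: list[tuple[str, str]] = []
    if pair_by_index:
        a_list = [c.name for c in chroms if c.subgenome == "A"]
        c_list = [c.name for c in chroms if c.subgenome == "C"]
        pairs = list(zip(a_list, c_list))

    SeqIO.write(out_records, str(out_fasta), "fasta")
    return SubgenomeRegistry(chroms, pairs)
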