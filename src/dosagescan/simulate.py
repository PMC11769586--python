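"""Synthetic allopolyploid pedigrees with planted homoeologous exchanges.

Everything the real pipeline consumes can be generated here with known
ground truth: a pair of homoeologous subgenomes with synteny blocks and
repeat/shared tracts, ancestral-diploid depth panels, and the crossing
scheme diploid (AA) × allotetraploid (AACC) → triploid F1 (AAC) →
backcross (BC1F1) progeny.

Genomes are represented as haplotypes — lists of reference-coordinate
segments — so a planted exchange manipulates chromosomes the way meiosis
does and copy numbers are simple coverage counts over haplotypes.  In
particular the conservation property of reciprocal exchanges (summed copy
number of the homoeolog pair unchanged) holds by construction.

Sequencing is emulated by drawing per-base depth as Poisson with mean
``lambda × copy_number / 2``, where ``lambda`` is the depth of a disomic
region; read-level artefacts (GC bias, error) are deliberately absent —
the point is to exercise the dosage arithmetic, the filter semantics and
the event-calling contracts, not the aligner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .coverage import DepthTrack
from .maskfilters import AncestralPanel, SyntenyBlock
from .refbuild import Chromosome, SubgenomeRegistry

__all__ = [
    "EventSpec",
    "SimConfig",
    "SimReference",
    "TruthTable",
    "PedigreeSim",
    "simulate_reference",
    "simulate_pedigree",
    "simulate_depth",
    "simulate_ancestral_panel",
    "write_reference_fasta",
]

# haplotype segment: (source chromosome, start, end) in reference coordinates
Segment = tuple[str, int, int]
Haplotype = list[Segment]
CopyNumberMap = dict[str, list[tuple[int, int, int]]]  # chrom -> (start, end, cn)


@dataclass(frozen=True)
class EventSpec:
    """One planted homoeologous exchange.

    ``pair`` indexes the homoeolog pair; breakpoints are reference
    positions on the A and C member.  ``generation='native'`` fixes the
    event homozygously in the allotetraploid parent;  ``'F1'`` plants it
    in the gamete transmitted to BC1F1 individual ``sample``.
    """

    pair: int
    a_breakpoint: int
    c_breakpoint: int
    type: str = "reciprocal"  # reciprocal | nonreciprocal
    generation: str = "native"  # native | F1
    sample: int = 0

    def __post_init__(self) -> None:
        if self.type not in ("reciprocal", "nonreciprocal"):
            raise ValueError(f"unknown event type {self.type!r}")
        if self.generation not in ("native", "F1"):
            raise ValueError(f"unknown event generation {self.generation!r}")


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults mirror a desk-scale version of the real design: a handful of
    10 Mb homoeolog pairs, disomic depth around 30× (the Poisson mean of a
    copy-number-2 region; the real study worked at ~6×, and any positive
    depth scales through unchanged), ~10 % annotated repeats, 80 % of each
    subgenome divergent enough to map uniquely, and seven backcross
    individuals as in the sequenced population.
    """

    n_pairs: int = 2
    chrom_len: int = 10_000_000
    events: list[EventSpec] = field(default_factory=list)
    lam: float = 30.0            # mean depth of a disomic (copy-number 2) region
    repeat_fraction: float = 0.1
    specific_fraction: float = 0.8  # subgenome-specific share of each chromosome
    n_bc1: int = 7
    n_synteny_blocks: int = 4    # 1:1 blocks per homoeolog pair
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        for frac in (self.repeat_fraction, self.specific_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for ev in self.events:
            if not (0 < ev.a_breakpoint < self.chrom_len) or not (
                0 < ev.c_breakpoint < self.chrom_len
            ):
                raise ValueError(f"event breakpoints outside chromosome bounds: {ev}")
            if not 0 <= ev.pair < self.n_pairs:
                raise ValueError(f"event references pair {ev.pair} of {self.n_pairs}")

    def a_name(self, i: int) -> str:
        return f"A{i + 1:02d}"

    def c_name(self, i: int) -> str:
        return f"C{i + 1}"


@dataclass
class SimReference:
    """Simulated two-subgenome reference and its annotations."""

    config: SimConfig
    registry: SubgenomeRegistry
    synteny: list[SyntenyBlock]
    repeats: dict[str, list[tuple[int, int]]]
    shared: dict[str, list[tuple[int, int]]]  # cross-mapping (non-specific) tracts


@dataclass
class TruthTable:
    """Planted events plus exact per-sample copy numbers."""

    events: list[EventSpec]
    copy_numbers: dict[str, CopyNumberMap]  # sample id -> chrom -> intervals

    def copy_number_at(self, sample: str, chrom: str, pos: int) -> int:
        for s, e, cn in self.copy_numbers[sample][chrom]:
            if s <= pos < e:
                return cn
        raise ValueError(f"position {pos} outside {chrom}")


@dataclass
class PedigreeSim:
    reference: SimReference
    samples: dict[str, CopyNumberMap]  # role/sample id -> copy-number map
    truth: TruthTable


# ---------------------------------------------------------------------------
# reference


def _place_disjoint(
    rng: np.random.Generator, length: int, fraction: float, element: int
) -> list[tuple[int, int]]:
    """Disjoint fixed-size intervals totalling ~fraction of [0, length)."""
    if fraction <= 0:
        return []
    slots = length // element
    k = min(slots, int(round(fraction * length / element)))
    if k == 0:
        return []
    picks = np.sort(rng.choice(slots, size=k, replace=False))
    return [(int(p) * element, (int(p) + 1) * element) for p in picks]


def simulate_reference(config: SimConfig) -> SimReference:
    """Homoeologous chromosome pairs with synteny, repeats and shared tracts.

    Each pair is fully syntenic 1:1 (split into ``n_synteny_blocks``
    blocks).  Repeat intervals are placed independently per chromosome to
    ``repeat_fraction``; shared (cross-mapping) tracts occupy
    ``1 − specific_fraction`` of each pair at matching coordinates on both
    members, emulating sequence too conserved to map uniquely.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chrom_len
    chroms: list[Chromosome] = []
    pairs: list[tuple[str, str]] = []
    for i in range(config.n_pairs):
        chroms.append(Chromosome(config.a_name(i), L, "A"))
    for i in range(config.n_pairs):
        chroms.append(Chromosome(config.c_name(i), L, "C"))
        pairs.append((config.a_name(i), config.c_name(i)))
    registry = SubgenomeRegistry(chroms, pairs)

    synteny: list[SyntenyBlock] = []
    edges = np.linspace(0, L, config.n_synteny_blocks + 1).astype(int)
    for i in range(config.n_pairs):
        for s, e in zip(edges[:-1], edges[1:]):
            synteny.append(
                SyntenyBlock(config.a_name(i), int(s), int(e), config.c_name(i), int(s), int(e))
            )

    repeats = {
        c.name: _place_disjoint(rng, L, config.repeat_fraction, element=5000)
        for c in chroms
    }
    shared: dict[str, list[tuple[int, int]]] = {}
    for i in range(config.n_pairs):
        tracts = _place_disjoint(rng, L, 1 - config.specific_fraction, element=10_000)
        shared[config.a_name(i)] = list(tracts)
        shared[config.c_name(i)] = list(tracts)
    return SimReference(config, registry, synteny, repeats, shared)


BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def write_reference_fasta(
    config: SimConfig, path_a: str | Path, path_c: str | Path, *, line_width: int = 70
) -> None:
    """Random ancestor FASTAs for the concatenation path.

    C-subgenome chromosomes are divergent copies of their A partners
    (substitutions at the non-specific rate complement), so aligners see
    genuine homoeology.  Deterministic for a given config.
    """
    rng = np.random.default_rng((config.seed, 0xFA57A))
    sub_rate = 0.05

    def write(fh, name: str, seq_codes: np.ndarray) -> None:
        fh.write(f">{name}\n")
        s = seq_codes.tobytes().decode()
        for i in range(0, len(s), line_width):
            fh.write(s[i:i + line_width] + "\n")

    with open(path_a, "w") as fa, open(path_c, "w") as fc:
        for i in range(config.n_pairs):
            a_seq = BASES[rng.integers(0, 4, size=config.chrom_len)]
            c_seq = a_seq.copy()
            mut = rng.random(config.chrom_len) < sub_rate
            c_seq[mut] = BASES[(rng.integers(1, 4, size=int(mut.sum())) +
                                np.searchsorted(BASES, c_seq[mut])) % 4]
            write(fa, config.a_name(i), a_seq)
            write(fc, config.c_name(i), c_seq)


# ---------------------------------------------------------------------------
# pedigree


def _split_hap(hap: Haplotype, src_chrom: str, pos: int) -> tuple[Haplotype, Haplotype]:
    """Split a haplotype at reference position ``pos`` of ``src_chrom``."""
    head: Haplotype = []
    tail: Haplotype = []
    cutting = False
    for chrom, s, e in hap:
        if cutting:
            tail.append((chrom, s, e))
        elif chrom == src_chrom and s <= pos <= e:
            if pos > s:
                head.append((chrom, s, pos))
            if pos < e:
                tail.append((chrom, pos, e))
            cutting = True
        else:
            head.append((chrom, s, e))
    if not cutting:
        raise ValueError(f"haplotype does not traverse {src_chrom}:{pos}")
    return head, tail


def _cn_map(haplotypes: list[Haplotype], lengths: dict[str, int]) -> CopyNumberMap:
    points: dict[str, dict[int, int]] = {c: {0: 0, n: 0} for c, n in lengths.items()}
    for hap in haplotypes:
        for chrom, s, e in hap:
            d = points[chrom]
            d[s] = d.get(s, 0) + 1
            d[e] = d.get(e, 0) - 1
    out: CopyNumberMap = {}
    for chrom, d in points.items():
        cuts = sorted(d)
        cn = 0
        ivs: list[tuple[int, int, int]] = []
        for s, e in zip(cuts[:-1], cuts[1:]):
            cn += d[s]
            if ivs and ivs[-1][2] == cn:
                ivs[-1] = (ivs[-1][0], e, cn)
            else:
                ivs.append((s, e, cn))
        out[chrom] = ivs
    return out


def simulate_pedigree(
    config: SimConfig, reference: SimReference | None = None
) -> PedigreeSim:
    """Copy-number maps for the whole crossing scheme.

    * ``P_dip`` — the diploid parent: copy 2 on every A chromosome, 0 on C.
    * ``P_tet`` — the allotetraploid parent: copy 2 on both subgenomes,
      with native events applied homozygously (reciprocal: recombinant on
      both homoeologs, dosage flat at 2; nonreciprocal: both C homologues
      carry the A tract, so copy 4 over the duplicated A tract and 0 over
      the lost C tract).
    * ``F1`` — one A set from each parent plus one C set from the
      allotetraploid: A at 2, C at 1.
    * ``BC1F1_xx`` — an F1 gamete (each C chromosome transmitted as a
      univalent with probability 1/2; planted F1 events recombine the
      transmitted copies) plus a full A set from the diploid parent.

    All randomness derives from ``config.seed``.
    """
    ref = reference or simulate_reference(config)
    cfg = ref.config
    lengths = ref.registry.lengths
    L = cfg.chrom_len
    rng = np.random.default_rng((cfg.seed, 0x9ED16))

    a_names = [cfg.a_name(i) for i in range(cfg.n_pairs)]
    c_names = [cfg.c_name(i) for i in range(cfg.n_pairs)]

    def full(chrom: str) -> Haplotype:
        return [(chrom, 0, L)]

    native = [e for e in cfg.events if e.generation == "native"]
    f1_events = [e for e in cfg.events if e.generation == "F1"]

    # allotetraploid parent haplotypes, native events applied to both copies
    tet_a: dict[int, Haplotype] = {i: full(a_names[i]) for i in range(cfg.n_pairs)}
    tet_c: dict[int, Haplotype] = {i: full(c_names[i]) for i in range(cfg.n_pairs)}
    for ev in native:
        a_head, a_tail = _split_hap(tet_a[ev.pair], a_names[ev.pair], ev.a_breakpoint)
        c_head, c_tail = _split_hap(tet_c[ev.pair], c_names[ev.pair], ev.c_breakpoint)
        if ev.type == "reciprocal":
            tet_a[ev.pair] = a_head + c_tail
            tet_c[ev.pair] = c_head + a_tail
        else:  # nonreciprocal: the C homologue substitutes its tract by the A tract
            tet_c[ev.pair] = c_head + a_tail

    samples: dict[str, CopyNumberMap] = {}
    samples["P_dip"] = _cn_map([full(a) for a in a_names] * 2, lengths)
    tet_haps = [h for i in range(cfg.n_pairs) for h in (tet_a[i], tet_a[i], tet_c[i], tet_c[i])]
    samples["P_tet"] = _cn_map(tet_haps, lengths)

    f1_a_dip = {i: full(a_names[i]) for i in range(cfg.n_pairs)}
    f1_haps = (
        [f1_a_dip[i] for i in range(cfg.n_pairs)]
        + [tet_a[i] for i in range(cfg.n_pairs)]
        + [tet_c[i] for i in range(cfg.n_pairs)]
    )
    samples["F1"] = _cn_map(f1_haps, lengths)

    for j in range(cfg.n_bc1):
        sample_id = f"BC1F1_{j + 1:02d}"
        gamete: list[Haplotype] = []
        my_events = [e for e in f1_events if e.sample == j]
        for i in range(cfg.n_pairs):
            # which F1 A homologue is transmitted
            a_hap = f1_a_dip[i] if rng.random() < 0.5 else tet_a[i]
            c_hap = tet_c[i]
            ev = next((e for e in my_events if e.pair == i), None)
            if ev is None:
                gamete.append(a_hap)
                if rng.random() < 0.5:  # univalent transmission
                    gamete.append(c_hap)
                continue
            a_head, a_tail = _split_hap(a_hap, a_names[i], ev.a_breakpoint)
            c_head, c_tail = _split_hap(c_hap, c_names[i], ev.c_breakpoint)
            if ev.type == "reciprocal":
                # one recombinant product enters the gamete in place of the
                # A copy; the reciprocal product and the C univalent do not
                gamete.append(a_head + c_tail)
            else:
                # the C univalent comes along carrying the A tract in place
                # of its own tail: A tract gains a third copy, C tail lost
                gamete.append(a_hap)
                gamete.append(c_head + a_tail)
        bc_haps = gamete + [full(a) for a in a_names]
        samples[sample_id] = _cn_map(bc_haps, lengths)

    truth = TruthTable(list(cfg.events), {s: m for s, m in samples.items()})
    _assert_reciprocal_conservation(cfg, ref.registry, truth)
    return PedigreeSim(ref, samples, truth)


def _assert_reciprocal_conservation(
    cfg: SimConfig, registry: SubgenomeRegistry, truth: TruthTable
) -> None:
    """Post-hoc check: native reciprocal events leave the allotetraploid's
    summed pair copy number at 4 everywhere."""
    for ev in truth.events:
        if ev.type != "reciprocal" or ev.generation != "native":
            continue
        a, c = cfg.a_name(ev.pair), cfg.c_name(ev.pair)
        for pos in (0, ev.a_breakpoint, cfg.chrom_len - 1):
            total = truth.copy_number_at("P_tet", a, pos) + truth.copy_number_at(
                "P_tet", c, min(pos, cfg.chrom_len - 1)
            )
            if total != 4:
                raise AssertionError(
                    f"reciprocal conservation violated at {a}/{c} pos {pos}: {total}"
                )


# ---------------------------------------------------------------------------
# depth


def simulate_depth(
    cn_map: CopyNumberMap,
    lam: float,
    seed: int | tuple,
    chrom_lengths: dict[str, int],
    attenuation: dict[str, list[tuple[int, int, float]]] | None = None,
) -> DepthTrack:
    """Per-base Poisson depth from a copy-number map.

    Mean depth at a base of copy number ``cn`` is ``lam × cn / 2`` (so a
    disomic region averages ``lam``); ``attenuation`` optionally scales
    the mean over given intervals (mappability loss inside repeat or
    shared tracts), exercising what the filter cascade is meant to catch.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        arr = np.zeros(length, dtype=np.int64)
        # piecewise-constant mean: split copy-number intervals at
        # attenuation boundaries, then draw with a scalar rate per piece
        att = (attenuation or {}).get(chrom, [])
        cuts = sorted(
            {0, length}
            | {x for s, e, _ in cn_map.get(chrom, []) for x in (s, e)}
            | {x for s, e, _ in att for x in (s, e)}
        )
        cn_at = np.zeros(len(cuts) - 1)
        for s, e, cn in cn_map.get(chrom, []):
            for k, (lo, hi) in enumerate(zip(cuts[:-1], cuts[1:])):
                if s <= lo and hi <= e:
                    cn_at[k] = cn
        for k, (lo, hi) in enumerate(zip(cuts[:-1], cuts[1:])):
            mean = lam * cn_at[k] / 2.0
            for s, e, factor in att:
                if s <= lo and hi <= e:
                    mean *= factor
            if mean > 0:
                arr[lo:hi] = rng.poisson(mean, size=hi - lo)
        data[chrom] = arr
    return DepthTrack(data)


def simulate_ancestral_panel(
    reference: SimReference,
    *,
    n_per_subgenome: int = 4,
    lam: float = 20.0,
    contamination: float = 0.0,
    seed: int | tuple | None = None,
) -> AncestralPanel:
    """Depth tracks of ancestral-diploid accessions against the reference.

    Each accession covers its own subgenome everywhere (depth ≥ 1) and
    cross-maps onto the *shared* tracts of the other subgenome — exactly
    the regions the ancestral filter exists to remove.  ``contamination``
    adds stray per-base coverage on the other subgenome outside shared
    tracts, for probing the filter's all-accessions strictness.
    """
    cfg = reference.config
    rng = np.random.default_rng(seed if seed is not None else (cfg.seed, 0xA2CE5))
    lengths = reference.registry.lengths
    accessions = []
    for origin in ("A", "C"):
        for k in range(n_per_subgenome):
            data: dict[str, np.ndarray] = {}
            for chrom, length in lengths.items():
                if reference.registry.subgenome_of(chrom) == origin:
                    data[chrom] = 1 + rng.poisson(lam, size=length)
                else:
                    arr = np.zeros(length, dtype=np.int64)
                    for s, e in reference.shared.get(chrom, []):
                        arr[s:e] = 1 + rng.poisson(lam, size=e - s)
                    if contamination > 0:
                        stray = rng.random(length) < contamination
                        arr[stray] += 1
                    data[chrom] = arr
            accessions.append((f"{origin}_acc{k + 1}", origin, DepthTrack(data)))
    return AncestralPanel(accessions)


# ---------------------------------------------------------------------------
# fixture export (the formats the real pipeline consumes)


def write_truth_json(truth: TruthTable, path: str | Path) -> None:
    payload = {
        "events": [asdict(e) for e in truth.events],
        "copy_numbers": {
            s: {c: [list(iv) for iv in ivs] for c, ivs in m.items()}
            for s, m in truth.copy_numbers.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_synteny_tsv(blocks: list[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("a_chrom\ta_start\ta_end\tc_chrom\tc_start\tc_end\tstrand\n")
        for b in blocks:
            fh.write(
                f"{b.a_chrom}\t{b.a_start}\t{b.a_end}\t{b.c_chrom}\t{b.c_start}\t"
                f"{b.c_end}\t{b.strand}\n"
            )


def read_synteny_tsv(path: str | Path) -> list[SyntenyBlock]:
    blocks = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            a, as_, ae, c, cs, ce, strand = line.split("\t")
            blocks.append(
                SyntenyBlock(a, int(as_), int(ae), c, int(cs), int(ce), strand.strip())
            )
    return blocks
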