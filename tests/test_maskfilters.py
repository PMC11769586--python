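"""Filter cascade: repeat, homoeology and ancestral masks."""

import numpy as np
import pytest

from dosagescan.coverage import DepthTrack
from dosagescan.maskfilters import (
    AnalysisMask,
    AncestralPanel,
    SyntenyBlock,
    ancestral_filter,
    homoeology_filter,
    merge_masks,
    read_paf_blocks,
    read_repeatmasker_out,
    repeat_filter,
)
from dosagescan.refbuild import Chromosome, SubgenomeRegistry


@pytest.fixture
def registry_10k():
    return SubgenomeRegistry(
        [Chromosome("A01", 10_000, "A"), Chromosome("C1", 10_000, "C"),
         Chromosome("C4", 10_000, "C")],
        [("A01", "C1")],
    )


class TestRepeatFilter:
    def test_overlapping_repeats_merge(self, registry_100k):
        mask = repeat_filter({"A01": [(100, 200), (150, 300)]}, registry_100k)
        assert mask.merged("A01") == [(100, 300)]

    def test_empty_annotation_gives_empty_mask(self, registry_100k):
        mask = repeat_filter({}, registry_100k)
        assert all(mask.masked_bases(c) == 0 for c in registry_100k.names)

    def test_masked_bases_equal_annotated_total(self, registry_100k):
        ivs = [(0, 1000), (2000, 2500), (5000, 6000), (7000, 8000), (9000, 9500)]
        mask = repeat_filter({"A01": ivs}, registry_100k)
        assert mask.masked_bases("A01") == 4000

    def test_out_of_bounds_clipped_with_warning(self, registry_100k):
        with pytest.warns(UserWarning, match="clipped"):
            mask = repeat_filter({"A01": [(99_000, 101_000)]}, registry_100k)
        assert mask.merged("A01") == [(99_000, 100_000)]

    def test_unknown_chromosome_skipped_with_warning(self, registry_100k):
        with pytest.warns(UserWarning, match="unknown chromosome"):
            mask = repeat_filter({"chrX": [(0, 10)]}, registry_100k)
        assert "chrX" not in mask.intervals

    def test_repeatmasker_out_parser(self, tmp_path):
        text = (
            "   SW  perc perc perc  query      position in query\n"
            "score  div. del. ins.  sequence    begin     end\n"
            "\n"
            "  463   1.3  0.6  1.7  A01        101       200 (0) + R1 LTR 1 100 (0) 1\n"
            "  239  29.4 10.0  1.2  C1          51        60 (0) C R2 DNA (0) 100 1 2\n"
        )
        (tmp_path / "rm.out").write_text(text)
        ivs = read_repeatmasker_out(tmp_path / "rm.out")
        assert ivs == {"A01": [(100, 200)], "C1": [(50, 60)]}


class TestHomoeologyFilter:
    def test_uncovered_flanks_masked_non_homoeolog(self, registry_10k):
        blocks = [SyntenyBlock("A01", 2000, 8000, "C1", 2000, 8000)]
        mask = homoeology_filter(blocks, registry_10k, min_block_len=1000)
        non = [(s, e) for s, e, src in mask.intervals["A01"] if src == "non_homoeolog"]
        assert non == [(0, 2000), (8000, 10_000)]

    def test_two_partner_chromosomes_masked_multi(self, registry_10k):
        blocks = [
            SyntenyBlock("A01", 0, 6000, "C1", 0, 6000),
            SyntenyBlock("A01", 0, 6000, "C4", 0, 6000),
        ]
        mask = homoeology_filter(blocks, registry_10k, min_block_len=1000)
        multi = [(s, e) for s, e, src in mask.intervals["A01"] if src == "multi_homoeolog"]
        assert multi == [(0, 6000)]

    def test_full_unique_tiling_leaves_chromosome_unmasked(self, registry_10k):
        blocks = [
            SyntenyBlock("A01", 0, 5000, "C1", 0, 5000),
            SyntenyBlock("A01", 5000, 10_000, "C1", 5000, 10_000),
        ]
        mask = homoeology_filter(blocks, registry_10k, min_block_len=1000)
        assert mask.masked_bases("A01") == 0
        assert mask.masked_bases("C1") == 0

    def test_same_subgenome_block_fatal(self, registry_10k):
        blocks = [SyntenyBlock("C1", 0, 6000, "C4", 0, 6000)]
        with pytest.raises(ValueError, match="subgenome"):
            homoeology_filter(blocks, registry_10k, min_block_len=1000)

    def test_matches_per_base_brute_force(self, rng):
        """On a small chromosome the interval mask must equal a literal
        per-base evaluation of the coverage/multiplicity rule."""
        registry = SubgenomeRegistry(
            [Chromosome("A01", 2000, "A"), Chromosome("C1", 2000, "C"),
             Chromosome("C2", 2000, "C")],
            [("A01", "C1")],
        )
        for _ in range(10):
            blocks = []
            for _ in range(rng.integers(1, 6)):
                s = int(rng.integers(0, 1800))
                e = int(rng.integers(s + 100, 2000))
                cs = int(rng.integers(0, 1800))
                ce = min(2000, cs + (e - s))
                c_chrom = "C1" if rng.random() < 0.7 else "C2"
                blocks.append(SyntenyBlock("A01", s, e, c_chrom, cs, ce))
            mask = homoeology_filter(blocks, registry, min_block_len=50)
            got = mask.bool_array("A01")

            # independent per-base oracle with the same distinctness metric
            expected = np.zeros(2000, dtype=bool)
            for p in range(2000):
                covering = [b for b in blocks if b.a_start <= p < b.a_end]
                if not covering:
                    expected[p] = True
                    continue
                loci = []
                for b in covering:
                    for grp in loci:
                        rep = grp[0]
                        same_chrom = rep.c_chrom == b.c_chrom
                        overlap = same_chrom and rep.c_start < b.c_end and b.c_start < rep.c_end
                        gap = max(rep.c_start, b.c_start) - min(rep.c_end, b.c_end)
                        near = same_chrom and gap <= max(rep.c_length, b.c_length)
                        if overlap or near:
                            grp.append(b)
                            break
                    else:
                        loci.append([b])
                # transitive closure for the oracle: merge linked groups
                merged = True
                while merged:
                    merged = False
                    for i in range(len(loci)):
                        for j in range(i + 1, len(loci)):
                            link = False
                            for x in loci[i]:
                                for y in loci[j]:
                                    same = x.c_chrom == y.c_chrom
                                    ov = same and x.c_start < y.c_end and y.c_start < x.c_end
                                    gp = max(x.c_start, y.c_start) - min(x.c_end, y.c_end)
                                    if ov or (same and gp <= max(x.c_length, y.c_length)):
                                        link = True
                            if link:
                                loci[i] += loci.pop(j)
                                merged = True
                                break
                        if merged:
                            break
                expected[p] = len(loci) > 1
            np.testing.assert_array_equal(got, expected)


class TestAncestralFilter:
    @staticmethod
    def panel_for(depths_a, depths_c, length=10):
        """One-base logic probe expanded to a tiny chromosome."""
        accs = []
        for i, d in enumerate(depths_a):
            track = DepthTrack({"A01": np.full(length, d), "C1": np.zeros(length, int)})
            accs.append((f"rapa{i}", "A", track))
        for i, d in enumerate(depths_c):
            track = DepthTrack({"A01": np.full(length, d), "C1": np.full(length, 5)})
            accs.append((f"oleracea{i}", "C", track))
        return AncestralPanel(accs)

    @pytest.fixture
    def registry_tiny(self):
        return SubgenomeRegistry(
            [Chromosome("A01", 10, "A"), Chromosome("C1", 10, "C")], [("A01", "C1")]
        )

    @pytest.mark.parametrize(
        "rapa, oleracea, retained",
        [
            ((3, 5, 2, 4), (0, 0, 0, 0), True),   # covered in all own, zero in all other
            ((3, 5, 2, 4), (1, 0, 0, 0), False),  # one other-ancestor accession covers it
            ((3, 0, 2, 4), (0, 0, 0, 0), False),  # one own accession misses it
        ],
    )
    def test_retention_rule(self, registry_tiny, rapa, oleracea, retained):
        # own-accession depth on A01 per `rapa`; other-accession depth per `oleracea`
        accs = []
        for i, d in enumerate(rapa):
            accs.append(
                (f"rapa{i}", "A",
                 DepthTrack({"A01": np.full(10, d), "C1": np.zeros(10, int)}))
            )
        for i, d in enumerate(oleracea):
            accs.append(
                (f"ole{i}", "C",
                 DepthTrack({"A01": np.full(10, d), "C1": np.full(10, 5)}))
            )
        mask = ancestral_filter(AncestralPanel(accs), registry_tiny)
        assert (mask.masked_bases("A01") == 0) == retained

    def test_missing_track_fatal(self, registry_tiny):
        accs = [
            ("rapa0", "A", DepthTrack({"A01": np.full(10, 3)})),  # no C1 track
            ("ole0", "C", DepthTrack({"A01": np.zeros(10, int), "C1": np.full(10, 5)})),
        ]
        with pytest.raises(ValueError, match="no depth track"):
            ancestral_filter(AncestralPanel(accs), registry_tiny)

    def test_panel_requires_both_subgenomes(self):
        with pytest.raises(ValueError, match="no C-origin"):
            AncestralPanel([("rapa0", "A", DepthTrack({}))])

    def test_matches_per_base_brute_force(self, registry_tiny, rng):
        accs = []
        for i in range(3):
            accs.append(
                (f"a{i}", "A",
                 DepthTrack({"A01": rng.poisson(1.0, 10), "C1": rng.poisson(0.3, 10)}))
            )
            accs.append(
                (f"c{i}", "C",
                 DepthTrack({"A01": rng.poisson(0.3, 10), "C1": rng.poisson(1.0, 10)}))
            )
        panel = AncestralPanel(accs)
        mask = ancestral_filter(panel, registry_tiny)
        for chrom in ("A01", "C1"):
            own_sub = registry_tiny.subgenome_of(chrom)
            expected = np.zeros(10, dtype=bool)
            for p in range(10):
                ok = all(
                    t.get(chrom)[p] > 0 if sub == own_sub else t.get(chrom)[p] == 0
                    for _, sub, t in accs
                )
                expected[p] = not ok
            np.testing.assert_array_equal(mask.bool_array(chrom), expected)


class TestMergeMasks:
    def test_union(self, registry_100k):
        m1 = AnalysisMask(registry_100k.lengths)
        m1.add("A01", 0, 100, "repeat")
        m2 = AnalysisMask(registry_100k.lengths)
        m2.add("A01", 50, 150, "ancestral")
        merged = merge_masks([m1, m2])
        assert merged.merged("A01") == [(0, 150)]
        assert {src for _, _, src in merged.intervals["A01"]} == {"repeat", "ancestral"}

    def test_empty_plus_nonempty_is_identity(self, registry_100k):
        m1 = AnalysisMask(registry_100k.lengths)
        m2 = AnalysisMask(registry_100k.lengths)
        m2.add("C1", 10, 40, "repeat")
        merged = merge_masks([m1, m2])
        assert merged.merged("C1") == [(10, 40)]

    def test_idempotent(self, registry_100k, rng):
        m = AnalysisMask(registry_100k.lengths)
        for _ in range(20):
            s = int(rng.integers(0, 90_000))
            m.add("A01", s, s + int(rng.integers(1, 5000)), "repeat")
        once = merge_masks([m])
        twice = merge_masks([once])
        assert once.merged("A01") == twice.merged("A01")

    def test_union_matches_per_base_inclusion_exclusion(self, registry_100k, rng):
        masks, arrays = [], []
        for frac in (0.3, 0.2, 0.1):
            m = AnalysisMask(registry_100k.lengths)
            arr = np.zeros(100_000, dtype=bool)
            target = int(frac * 100_000)
            while arr.sum() < target:
                s = int(rng.integers(0, 99_000))
                e = min(100_000, s + 1000)
                m.add("A01", s, e, "repeat")
                arr[s:e] = True
            masks.append(m)
            arrays.append(arr)
        merged = merge_masks(masks)
        brute = arrays[0] | arrays[1] | arrays[2]
        assert merged.masked_bases("A01") == int(brute.sum())

    def test_registry_mismatch_fatal(self, registry_100k):
        m1 = AnalysisMask(registry_100k.lengths)
        m2 = AnalysisMask({"A01": 5})
        with pytest.raises(ValueError, match="different registries"):
            merge_masks([m1, m2])


class TestPafReader:
    def paf_line(self, q, qs, qe, strand, t, ts, te, qlen=100_000, tlen=100_000):
        return (
            f"{q}\t{qlen}\t{qs}\t{qe}\t{strand}\t{t}\t{tlen}\t{ts}\t{te}"
            f"\t{qe-qs}\t{qe-qs}\t60\n"
        )

    def test_reads_filters_and_orients(self, tmp_path, registry_100k):
        path = tmp_path / "aln.paf"
        path.write_text(
            self.paf_line("A01", 0, 20_000, "+", "C1", 0, 20_000)
            + self.paf_line("C2", 0, 30_000, "+", "A02", 0, 30_000)  # C as query
            + self.paf_line("A01", 50_000, 52_000, "+", "C1", 50_000, 52_000)  # short
            + self.paf_line("A01", 0, 9000, "+", "A02", 0, 9000)  # same subgenome
        )
        blocks = read_paf_blocks(path, registry_100k, min_block_len=5000)
        assert len(blocks) == 2
        assert all(b.a_chrom.startswith("A") and b.c_chrom.startswith("C") for b in blocks)

    def test_chains_colinear_records(self, tmp_path, registry_100k):
        path = tmp_path / "aln.paf"
        path.write_text(
            self.paf_line("A01", 0, 4000, "+", "C1", 0, 4000)
            + self.paf_line("A01", 4500, 9000, "+", "C1", 4500, 9000)
        )
        blocks = read_paf_blocks(path, registry_100k, min_block_len=5000, chain_gap=1000)
        assert len(blocks) == 1
        assert (blocks[0].a_start, blocks[0].a_end) == (0, 9000)
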