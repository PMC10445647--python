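"""Unit tests for nearest-gene, splice-window, concordance and OCR annotation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_cs
from finecoloc.annotate import (
    direction_concordance,
    nearest_gene,
    nearest_genes,
    ocr_overlap,
    splice_concordance,
    splice_window_hits,
)


def gene_df(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "gene_name", "chrom", "start", "end", "strand", "biotype"],
    )


GENES = gene_df([
    ("G1", "G1", "chr1", 100, 200, "+", "protein_coding"),
    ("G2", "G2", "chr1", 400, 500, "+", "protein_coding"),
    ("L1", "L1", "chr1", 240, 260, "+", "lncRNA"),
])


class TestNearestGene:
    def test_containment_gives_zero_distance(self):
        gene, d = nearest_gene(("chr1", 150), GENES)
        assert gene["gene_id"] == "G1" and d == 0

    def test_signed_gap_negative_for_upstream_gene(self):
        genes = gene_df([
            ("G1", "G1", "chr1", 100, 200, "+", "protein_coding"),
            ("G2", "G2", "chr1", 400, 500, "+", "protein_coding"),
        ])
        gene, d = nearest_gene(("chr1", 250), genes)
        assert gene["gene_id"] == "G1" and d == -50

    def test_coding_only_skips_noncoding_nearest(self):
        # L1 is nearest at pos 250 but non-coding; next coding gene wins
        gene, d = nearest_gene(("chr1", 250), GENES)
        assert gene["gene_id"] == "L1" and d == 0
        gene, d = nearest_gene(("chr1", 250), GENES, coding_only=True)
        assert gene["gene_id"] == "G1" and d == -50

    def test_tie_broken_by_start_then_id(self):
        genes = gene_df([
            ("B", "B", "chr1", 300, 350, "+", "protein_coding"),
            ("A", "A", "chr1", 300, 350, "+", "protein_coding"),
            ("C", "C", "chr1", 150, 200, "+", "protein_coding"),
        ])
        # pos 250: C ends at 200 (gap 50), A/B start at 300 (gap 50) -> C (smaller start)
        gene, d = nearest_gene(("chr1", 250), genes)
        assert gene["gene_id"] == "C" and d == -50
        # pos 325 inside A and B -> lexical id
        gene, d = nearest_gene(("chr1", 325), genes)
        assert gene["gene_id"] == "A" and d == 0

    def test_absent_chromosome_is_named_in_error(self):
        with pytest.raises(ValueError, match="chrX"):
            nearest_gene(("chrX", 100), GENES)

    def test_agrees_with_exhaustive_scan_on_random_fixture(self, rng):
        genes = gene_df([
            (f"g{i:03d}", f"g{i:03d}", "chr1",
             int(s), int(s + rng.integers(10, 300)), "+", "protein_coding")
            for i, s in enumerate(rng.integers(0, 20_000, 60))
        ])
        for pos in rng.integers(0, 21_000, 200):
            pos = int(pos)
            gene, d = nearest_gene(("chr1", pos), genes)
            # oracle: full scan with explicit tie-break ordering
            best = None
            for row in genes.itertuples(index=False):
                dd = 0 if row.start <= pos <= row.end else (
                    -(pos - row.end) if row.end < pos else row.start - pos
                )
                key = (abs(dd), row.start, row.gene_id)
                if best is None or key < best[0]:
                    best = (key, row.gene_id, dd)
            assert (gene["gene_id"], d) == (best[1], best[2])

    def test_bulk_wrapper_matches_scalar(self):
        table = nearest_genes([("chr1", 150), ("chr1", 250)], GENES)
        assert list(table["gene_id"]) == ["G1", "L1"]


def vid(pos, chrom="chr1"):
    return f"{chrom}_{pos}_A_G_b38"


class TestSpliceWindows:
    INTRONS = pd.DataFrame(
        {"chrom": ["chr1"], "start": [1000], "end": [2000], "strand": ["+"]}
    )

    def test_variant_on_donor_boundary_is_canonical(self):
        cs = make_cs("l:1", [vid(1000)], [0.5])
        hits = splice_window_hits(cs, self.INTRONS)
        assert len(hits) == 1
        h = hits.iloc[0]
        assert h["side"] == "donor" and h["offset"] == 0
        assert h["canonical_dinucleotide"]

    def test_second_intronic_base_is_canonical(self):
        hits = splice_window_hits(make_cs("l:1", [vid(1001)], [0.5]), self.INTRONS)
        assert hits.iloc[0]["canonical_dinucleotide"]
        hits = splice_window_hits(make_cs("l:1", [vid(1002)], [0.5]), self.INTRONS)
        assert not hits.iloc[0]["canonical_dinucleotide"]

    def test_window_threshold_is_exact(self):
        assert len(splice_window_hits(make_cs("l:1", [vid(1025)], [0.5]),
                                      self.INTRONS)) == 1
        assert splice_window_hits(make_cs("l:1", [vid(1026)], [0.5]),
                                  self.INTRONS).empty

    def test_minus_strand_swaps_sides(self):
        introns = self.INTRONS.assign(strand="-")
        hits = splice_window_hits(make_cs("l:1", [vid(1000)], [0.5]), introns)
        assert hits.iloc[0]["side"] == "acceptor"
        hits = splice_window_hits(make_cs("l:1", [vid(2000)], [0.5]), introns)
        assert hits.iloc[0]["side"] == "donor"

    def test_seven_variant_fixture_counts(self):
        # six introns, seven variants each within 25 bp of one boundary
        introns = pd.DataFrame(
            {
                "chrom": ["chr1"] * 6,
                "start": [1000, 3000, 5000, 7000, 9000, 11000],
                "end": [1500, 3500, 5500, 7500, 9500, 11500],
                "strand": ["+"] * 6,
            }
        )
        positions = [1000, 1510, 2990, 5025, 7499, 9000, 11475]
        cs = make_cs("l:1", [vid(p) for p in positions], [0.1] * 7)
        hits = splice_window_hits(cs, introns)
        assert len(hits) == 7
        # brute-force double-loop oracle over every (variant, boundary)
        expected = 0
        for p in positions:
            for intron in introns.itertuples(index=False):
                expected += int(abs(p - intron.start) <= 25)
                expected += int(abs(p - intron.end) <= 25)
        assert expected == 7

    def test_translation_invariance(self):
        cs = make_cs("l:1", [vid(1010), vid(1990)], [0.5, 0.3])
        base = splice_window_hits(cs, self.INTRONS)
        shift = 12345
        cs2 = make_cs("l:1", [vid(1010 + shift), vid(1990 + shift)], [0.5, 0.3])
        introns2 = self.INTRONS.assign(start=self.INTRONS["start"] + shift,
                                       end=self.INTRONS["end"] + shift)
        moved = splice_window_hits(cs2, introns2)
        assert list(moved["offset"]) == list(base["offset"])
        assert list(moved["side"]) == list(base["side"])

    def test_malformed_intron_rejected(self):
        bad = pd.DataFrame({"chrom": ["chr1"], "start": [2000], "end": [1000]})
        with pytest.raises(ValueError, match="malformed"):
            splice_window_hits(make_cs("l:1", [vid(1000)], [0.5]), bad)


class TestSpliceConcordance:
    def test_negative_score_with_negative_observed_is_concordant(self):
        hits = pd.DataFrame()
        scores = pd.DataFrame(
            {"variant_id": [vid(100)], "event": ["chr1:100-500"], "score": [-4.751]}
        )
        obs = pd.DataFrame(
            {"variant_id": [vid(100)], "event": ["chr1:100-500"], "observed_sign": [-1]}
        )
        out = splice_concordance(hits, scores, obs)
        assert out.iloc[0]["verdict"] == "concordant"

    def test_zero_score_is_indeterminate(self):
        scores = pd.DataFrame(
            {"variant_id": [vid(1)], "event": ["e"], "score": [0.0]}
        )
        obs = pd.DataFrame({"variant_id": [vid(1)], "event": ["e"], "observed_sign": [1]})
        assert splice_concordance(pd.DataFrame(), scores, obs).iloc[0]["verdict"] \
            == "indeterminate"

    def test_discordant_and_unscored(self):
        scores = pd.DataFrame(
            {"variant_id": [vid(1)], "event": ["e"], "score": [0.787]}
        )
        obs = pd.DataFrame(
            {"variant_id": [vid(1), vid(2)], "event": ["e", "e"],
             "observed_sign": [-1, 1]}
        )
        out = splice_concordance(pd.DataFrame(), scores, obs)
        assert list(out["verdict"]) == ["discordant", "unscored"]


class TestDirectionConcordance:
    def test_single_tissue_is_consistent(self):
        df = pd.DataFrame({"feature": ["G1"], "tissue": ["t1"], "effect_sign": [1]})
        out = direction_concordance(df)
        assert out.iloc[0]["consistent"] and out.iloc[0]["n_tissues"] == 1

    def test_majority_fraction_counting(self):
        df = pd.DataFrame(
            {
                "feature": ["A"] * 3 + ["B"] * 3,
                "tissue": ["t1", "t2", "t3"] * 2,
                "effect_sign": [1, 1, 1, 1, 1, -1],
            }
        )
        out = direction_concordance(df).set_index("feature")
        assert out.loc["A", "consistent"]
        assert not out.loc["B", "consistent"]
        assert out.loc["B", "majority_fraction"] == pytest.approx(2 / 3)

    def test_simulated_shared_direction_is_mostly_consistent(self, rng):
        # strong common effect across tissues, small per-tissue noise on beta
        n_consistent = 0
        for rep in range(100):
            signs = np.sign(1.0 + rng.normal(0, 0.3, size=4))
            df = pd.DataFrame(
                {"feature": "G", "tissue": [f"t{i}" for i in range(4)],
                 "effect_sign": signs}
            )
            n_consistent += int(direction_concordance(df).iloc[0]["consistent"])
        assert n_consistent >= 95


class TestOcrOverlap:
    INTERVALS = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [100, 900], "end": [200, 1000]}
    )

    def test_half_open_boundaries(self):
        at_start = make_cs("s:1", [vid(100)], [0.9])
        at_end = make_cs("s:2", [vid(200)], [0.9])
        out = ocr_overlap([at_start, at_end], self.INTERVALS)
        assert out.set_index("cs_id")["in_ocr"].to_dict() == {"s:1": True, "s:2": False}

    def test_empty_intervals_give_all_false(self):
        cs = make_cs("s:1", [vid(150)], [0.9])
        out = ocr_overlap([cs], pd.DataFrame(columns=["chrom", "start", "end"]))
        assert not out["in_ocr"].any()

    def test_matches_double_loop_oracle(self, rng):
        intervals = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": (s := rng.integers(0, 5000, 5)),
                "end": s + rng.integers(1, 400, 5),
            }
        )
        sets = []
        for i in range(10):
            poss = rng.integers(0, 5500, 3)
            sets.append(make_cs(f"s:{i}", [vid(int(p)) for p in poss], [0.3] * 3))
        out = ocr_overlap(sets, intervals).set_index("cs_id")["in_ocr"]
        for cs in sets:
            expected = any(
                iv.start <= int(m.split("_")[1]) < iv.end
                for m in cs.member_ids
                for iv in intervals.itertuples(index=False)
            )
            assert out[cs.cs_id] == expected

    def test_record_order_independence(self, rng):
        intervals = self.INTERVALS.iloc[::-1].reset_index(drop=True)
        cs = make_cs("s:1", [vid(950), vid(50)], [0.5, 0.4])
        a = ocr_overlap([cs], self.INTERVALS)
        b = ocr_overlap([cs], intervals)
        assert a["in_ocr"].tolist() == b["in_ocr"].tolist()

    def test_per_gene_rollup(self):
        s1 = make_cs("s:1", [vid(150)], [0.9])
        s2 = make_cs("s:2", [vid(5000)], [0.9])
        per_set, per_gene = ocr_overlap(
            [s1, s2], self.INTERVALS, gene_map={"s:1": "G1", "s:2": "G1"}
        )
        assert per_gene.set_index("gene")["any_set_in_ocr"]["G1"]
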