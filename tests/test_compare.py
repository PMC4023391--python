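import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from mistseq import compare as cmp
from mistseq.model import GeneModel, ValidationError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def naive_hits(motif, seq):
    """All-positions matcher written from the IUPAC table directly."""
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        if all(seq[i + j] in IUPAC[m] for j, m in enumerate(motif)):
            hits.append(i)
    return hits


class TestCategoryAnova:
    def frame(self, groups):
        rows = []
        for cat, ks in groups.items():
            rows += [(cat, k) for k in ks]
        return pd.DataFrame(rows, columns=["category", "k"])

    def test_identical_groups_give_f_zero_p_one(self):
        vals = list(np.linspace(0.01, 0.1, 25))
        stats = cmp.category_anova(
            self.frame({"coding_1orf": vals, "sut": vals}), min_n=20
        )
        assert stats.anova_f == pytest.approx(0.0, abs=1e-12)
        assert stats.pairwise.iloc[0]["p"] == pytest.approx(1.0)

    def test_textbook_two_group_f_statistic(self):
        """{1,2,3} vs {11,12,13}: between SS = 150, within MS = 1 -> F = 150."""
        a = [1.0, 2.0, 3.0]
        b = [11.0, 12.0, 13.0]
        stats = cmp.category_anova(self.frame({"x": a, "y": b}), min_n=3)
        assert stats.anova_f == pytest.approx(150.0)
        assert stats.df_between == 1 and stats.df_within == 4

    def test_planted_category_shift_detected(self):
        rng = np.random.default_rng(4)
        coding = rng.lognormal(np.log(0.03), 0.5, 400)
        noncoding = rng.lognormal(np.log(0.03 * 1.3), 0.5, 400)
        stats = cmp.category_anova(
            self.frame({"coding_1orf": coding, "sut": noncoding})
        )
        med = stats.medians.set_index("category")["median_k"]
        assert med["coding_1orf"] < med["sut"]
        assert stats.anova_p < 0.01

    def test_fewer_than_two_eligible_categories_refused(self):
        with pytest.raises(ValidationError):
            cmp.category_anova(self.frame({"coding_1orf": [0.1] * 30, "sut": [0.1] * 5}))


class TestUtrLengthRelation:
    def coding_frame(self, utr, k, genes=None):
        n = len(utr)
        return pd.DataFrame(
            {
                "site": [f"s{i}" for i in range(n)],
                "gene_id": genes if genes is not None else [f"g{i}" for i in range(n)],
                "utr3_length": utr,
                "k": k,
            }
        )

    def test_independent_lengths_uncorrelated(self):
        rng = np.random.default_rng(5)
        df = self.coding_frame(rng.integers(20, 300, 1000), rng.lognormal(-3, 1, 1000))
        out = cmp.utr_length_relation(df)
        assert abs(out["spearman"]) < 0.1

    def test_monotone_relation_gives_rho_one(self):
        utr = np.arange(10, 60)
        df = self.coding_frame(utr, 0.001 * utr)
        assert cmp.utr_length_relation(df)["spearman"] == pytest.approx(1.0)

    def test_distal_more_stable_pair_has_negative_delta(self):
        df = self.coding_frame(
            [50, 200], [np.log(2) / 10, np.log(2) / 40], genes=["g", "g"]
        )
        df = pd.concat([df, self.coding_frame(np.arange(20, 30), [0.02] * 10)])
        out = cmp.utr_length_relation(df)
        pair = out["pairs"].set_index("gene_id").loc["g"]
        assert pair["delta_length"] == 150 and pair["delta_k"] < 0


class TestPairDistanceProfile:
    def pairs(self, rows):
        df = pd.DataFrame(rows, columns=["distance_nt", "p", "significant"])
        df["site_a"] = "a"
        df["site_b"] = "b"
        return df

    def test_adjacent_significant_pair_in_first_bin(self):
        out = cmp.pair_distance_profile(self.pairs([(1, 1e-5, True), (50, 0.5, False)]))
        assert out["significant_by_distance"]["1"] == 1
        assert out["n_significant"] == 1

    def test_distance_zero_pairs_excluded(self):
        out = cmp.pair_distance_profile(self.pairs([(0, 1e-5, True)]))
        assert len(out["table"]) == 0

    def test_bins_partition_significant_pairs(self):
        rows = [(d, 1e-4, True) for d in (1, 3, 8, 60, 400)]
        out = cmp.pair_distance_profile(self.pairs(rows))
        assert sum(out["significant_by_distance"].values()) == 5


class TestMotifScanning:
    def test_simple_hit_contained(self):
        assert cmp.brute_force_iupac_hits("TGTAAATA", "CCTGTAAATACC") == [2]

    def test_degenerate_iupac_semantics(self):
        # TGTAHMNTA: H={ACT}, M={AC}, N any
        assert cmp.brute_force_iupac_hits("TGTAHMNTA", "GTGTACAGTAG") == [1]
        assert cmp.brute_force_iupac_hits("TGTAHMNTA", "GTGTAGAGTAG") == []

    def test_invalid_iupac_letter_rejected(self):
        with pytest.raises(ValidationError, match="IUPAC"):
            cmp.iupac_regex("TGX!")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        seq=hst.text(alphabet="ACGT", min_size=20, max_size=120),
        motif=hst.text(alphabet="ACGTRYSWKMBDHVN", min_size=2, max_size=8),
    )
    def test_regex_scan_agrees_with_naive_matcher(self, seq, motif):
        pat = cmp.iupac_regex(motif)
        got = list(cmp._finditer_overlapping(pat, seq))
        assert got == naive_hits(motif, seq)

    def test_scan_positions_and_containment(self):
        # gene on plus strand: CDS [10, 40), sites at 59 and 79
        genome = {"c": "G" * 40 + "AC" + "TGTAAATA" + "G" * 30 + "C" * 20}
        annotations = pd.DataFrame(
            {
                "site": ["c:59:+", "c:79:+"],
                "gene_id": ["g", "g"],
                "chrom": ["c", "c"],
                "pos": [59, 79],
                "strand": ["+", "+"],
                "coding": [True, True],
                "utr3_length": [20, 40],
            }
        )
        motifs = pd.DataFrame({"motif_id": ["PUF3"], "iupac": ["TGTAAATA"]})
        hits = cmp.scan_motifs(genome, motifs, annotations)
        by_site = hits.set_index("site")
        assert bool(by_site.loc["c:59:+", "contained"]) is True
        assert by_site.loc["c:59:+", "distance_to_3prime"] == 10
        assert by_site.loc["c:79:+", "distance_to_3prime"] == 30
        assert (hits["hit_pos"] == 42).all()

    def test_hit_downstream_of_site_not_contained(self):
        genome = {"c": "G" * 40 + "C" * 25 + "TGTAAATA" + "G" * 30}
        annotations = pd.DataFrame(
            {
                "site": ["c:59:+"],
                "gene_id": ["g"],
                "chrom": ["c"],
                "pos": [59],
                "strand": ["+"],
                "coding": [True],
                "utr3_length": [20],
            }
        )
        motifs = pd.DataFrame({"motif_id": ["PUF3"], "iupac": ["TGTAAATA"]})
        hits = cmp.scan_motifs(genome, motifs, annotations, max_downstream=20)
        assert len(hits) == 1 and not bool(hits.iloc[0]["contained"])
        assert hits.iloc[0]["distance_to_3prime"] < 0

    def test_minus_strand_hits_found_on_sense(self, world):
        """Every planted motif is recovered, on either strand."""
        truth = world.truth[world.truth.coding.astype(bool)]
        annotations = truth.rename(columns={})[
            ["site", "gene_id", "chrom", "pos", "strand", "coding", "utr3_length"]
        ]
        hits = cmp.scan_motifs(world.genome, world.motifs, annotations)
        contained = set(hits[(hits.motif_id == "PUF3") & hits.contained]["site"])
        planted = set(truth.loc[truth.motif_present, "site"])
        assert planted <= contained
        minus_planted = truth[truth.motif_present & (truth.strand == "-")]
        assert len(minus_planted) > 0


class TestMotifStabilitySplit:
    def test_all_contained_gives_no_test(self):
        fits = pd.DataFrame(
            {
                "site": ["a", "b"],
                "gene_id": ["g", "g"],
                "coding": [True, True],
                "k": [0.1, 0.2],
            }
        )
        hits = pd.DataFrame(
            {"motif_id": ["m", "m"], "site": ["a", "b"], "gene_id": ["g", "g"],
             "contained": [True, True], "distance_to_3prime": [5, 5]}
        )
        out = cmp.motif_stability_split(fits, hits, "m")
        assert out["n_without"] == 0 and np.isnan(out["p"])


class TestDivergentPairs:
    def genes(self, gap):
        return [
            GeneModel("m1", "c", 1000, 2000, "-"),
            GeneModel("p1", "c", 2000 + gap, 3000 + gap, "+"),
        ]

    def test_head_to_head_within_gap_found(self):
        gk = pd.Series({"m1": 0.1, "p1": 0.1})
        out = cmp.divergent_pair_correlation(self.genes(150), gk)
        assert out["n"] == 1

    def test_convergent_pairs_excluded(self):
        genes = [
            GeneModel("p1", "c", 1000, 2000, "+"),
            GeneModel("m1", "c", 2100, 3000, "-"),
        ]
        gk = pd.Series({"m1": 0.1, "p1": 0.1})
        assert cmp.divergent_pair_correlation(genes, gk)["n"] == 0

    def test_gap_beyond_limit_excluded(self):
        gk = pd.Series({"m1": 0.1, "p1": 0.1})
        assert cmp.divergent_pair_correlation(self.genes(300), gk)["n"] == 0

    def test_identical_rates_give_rho_one(self):
        genes, gk = [], {}
        for i in range(8):
            off = i * 5000
            genes += [
                GeneModel(f"m{i}", "c", 1000 + off, 2000 + off, "-"),
                GeneModel(f"p{i}", "c", 2100 + off, 3000 + off, "+"),
            ]
            gk[f"m{i}"] = gk[f"p{i}"] = 0.01 * (i + 1)
        out = cmp.divergent_pair_correlation(genes, pd.Series(gk))
        assert out["spearman"] == pytest.approx(1.0)

    def test_independent_rates_weakly_correlated(self):
        rng = np.random.default_rng(6)
        genes, gk = [], {}
        for i in range(200):
            off = i * 5000
            genes += [
                GeneModel(f"m{i}", "c", 1000 + off, 2000 + off, "-"),
                GeneModel(f"p{i}", "c", 2100 + off, 3000 + off, "+"),
            ]
            gk[f"m{i}"] = rng.lognormal(-3, 1)
            gk[f"p{i}"] = rng.lognormal(-3, 1)
        out = cmp.divergent_pair_correlation(genes, pd.Series(gk))
        assert out["n"] == 200 and abs(out["spearman"]) < 0.15
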