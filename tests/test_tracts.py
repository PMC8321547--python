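import numpy as np
import pandas as pd
import pytest

from bovadapt.tracts import (GenomeMask, assign_genes, filter_tracts,
                             genome_fraction, merge_intervals,
                             overlap_permutation_test, snp_tract_overlap,
                             overlap_summary_from_counts)
from bovadapt.panel_io import GeneAnnotation
from tests.conftest import make_table


def tracts_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label",
                                       "carrier_frac"])


class TestGenomeFraction:
    mask = GenomeMask({"1": 1000})

    def test_half_genome_full_carrier(self):
        tr = tracts_df([("1", 0, 500, "ind", 1.0)])
        assert genome_fraction(tr, self.mask, "ind") == 0.5

    def test_empty_tract_set(self):
        assert genome_fraction(tracts_df([]), self.mask, "ind") == 0.0

    def test_carrier_fraction_weighting(self):
        tr = tracts_df([("1", 0, 100, "ind", 0.5), ("1", 200, 300, "ind", 1.0)])
        assert genome_fraction(tr, self.mask, "ind") == pytest.approx(0.15)

    def test_unknown_label_rejected(self):
        tr = tracts_df([("1", 0, 100, "ind", 1.0)])
        with pytest.raises(KeyError):
            genome_fraction(tr, self.mask, "taur")

    def test_fractions_additive_and_bounded(self):
        tr = tracts_df([("1", 0, 600, "ind", 1.0), ("1", 600, 1000, "taur", 1.0)])
        fi = genome_fraction(tr, self.mask, "ind")
        ft = genome_fraction(tr, self.mask, "taur")
        assert fi + ft == pytest.approx(1.0)

    def test_excluded_regions_shrink_denominator(self):
        mask = GenomeMask({"1": 1000}, excluded=(("1", 500, 1000),))
        tr = tracts_df([("1", 0, 250, "ind", 1.0)])
        assert genome_fraction(tr, mask, "ind") == 0.5


class TestSnpTractOverlap:
    def test_half_open_conventions(self):
        # site pos (1-based) 101 -> pos0 100 == tract start -> inside;
        # pos0 200 == tract end -> outside
        t = make_table({"a": [0.5, 0.5]}, two_n=10)
        t.sites["pos"] = [101, 201]
        tr = tracts_df([("1", 100, 200, "ind", 1.0)])
        flag, summary = snp_tract_overlap(t, tr, "ind")
        assert flag.tolist() == [True, False]
        assert summary["pct_overlapping"] == 50.0

    def test_summary_arithmetic_from_counts(self):
        s = overlap_summary_from_counts(9809, 13257)
        assert s["pct_overlapping"] == 73.99


class TestFilterTracts:
    tr = tracts_df([("1", 0, 100, "ind", 1.0),
                    ("1", 200, 300, "ind", 1.0),
                    ("1", 400, 500, "ind", 1.0)])

    def sites(self, positions):
        return pd.DataFrame({"chrom": "1", "pos0": positions})

    def test_four_case_truth_table(self):
        allele_sets = {
            "shared_bovinae": self.sites([50]),        # tract 1: shared only
            "indicine_specific": self.sites([250]),    # tract 2: shared+rescue
            "shared_hanwoo": self.sites([260]),
        }
        kept, ledger = filter_tracts(self.tr, allele_sets)
        # tract 1 removed (shared, no rescue); tract 2 rescued; tract 3
        # untouched by any allele -> retained
        assert kept["start"].tolist() == [200, 400]
        assert ledger["removed"] == 1 and ledger["rescued"] == 1
        assert ledger["removed"] + ledger["retained"] == ledger["input"]

    def test_no_shared_sets_keeps_everything(self):
        kept, ledger = filter_tracts(
            self.tr, {"indicine_specific": self.sites([])})
        assert len(kept) == 3 and ledger["removed"] == 0


class TestAssignGenes:
    tr = tracts_df([("1", 0, 600, "anc", 1.0), ("1", 700, 1000, "eu", 1.0)])

    def test_inclusive_boundary(self):
        g = GeneAnnotation("g", "1", 0, 1000, "+")
        assert assign_genes([g], self.tr, 0.6) == {"g": ["anc"]}

    def test_below_boundary_unassigned(self):
        g = GeneAnnotation("g", "1", 1, 1000, "+")  # overlap 599 of 999
        assert assign_genes([g], self.tr, 0.6) == {}

    def test_overlaps_sum_across_tracts(self):
        tr = tracts_df([("1", 0, 300, "anc", 1.0), ("1", 500, 800, "anc", 1.0)])
        g = GeneAnnotation("g", "1", 0, 1000, "+")
        assert assign_genes([g], tr, 0.6) == {"g": ["anc"]}

    def test_agrees_with_per_base_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n_tracts = rng.integers(1, 6)
            rows = []
            for _ in range(n_tracts):
                s = int(rng.integers(0, 900))
                e = s + int(rng.integers(10, 200))
                rows.append(("1", s, min(e, 1000),
                             rng.choice(["anc", "eu"]), 1.0))
            tr = tracts_df(rows)
            gs = int(rng.integers(0, 900))
            gene = GeneAnnotation("g", "1", gs, gs + int(rng.integers(50, 100)),
                                  "+")
            got = assign_genes([gene], tr, 0.6).get("g", [])
            # brute force: count covered bases per label
            expect = []
            for label in ("anc", "eu"):
                cov = np.zeros(1000, dtype=bool)
                for c, s, e in merge_intervals(
                        tr[tr.label == label][["chrom", "start", "end"]]
                        .itertuples(index=False)):
                    cov[s:e] = True
                if cov[gene.start:gene.end].sum() >= 0.6 * gene.length:
                    expect.append(label)
            assert got == expect


class TestPermutationTest:
    def test_annotation_covering_whole_mask(self):
        mask = GenomeMask({"1": 1000})
        res = overlap_permutation_test([("1", 100, 200)], [("1", 0, 1000)],
                                       mask, n_perm=200, seed=0)
        assert res["fold"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_null_p_centred(self):
        # query placed like the null -> p should be moderate, not extreme
        mask = GenomeMask({"1": 10_000})
        ann = [("1", i * 200, i * 200 + 100) for i in range(50)]  # 50% cover
        # a 100 bp query half inside one annotation block overlaps exactly
        # the null-mean 50 bp, so p should sit near 0.5
        res = overlap_permutation_test([("1", 4050, 4150)], ann, mask,
                                       n_perm=2000, seed=1)
        assert 0.3 < res["p"] < 0.7

    def test_query_longer_than_chromosome_rejected(self):
        with pytest.raises(ValueError):
            overlap_permutation_test([("1", 0, 2000)], [("1", 0, 10)],
                                     GenomeMask({"1": 1000}), n_perm=10)
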