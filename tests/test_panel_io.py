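import numpy as np
import pandas as pd
import pytest

from bovadapt import panel_io
from bovadapt.panel_io import (GeneAnnotation, PanelConfig, PanelError,
                               hard_filter, presence_filter, read_vcf,
                               write_vcf)
from bovadapt.synthetic import SimTreeSpec, default_panel, simulate_sites

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=QD,Number=1,Type=Float,Description="QD">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
)


def write_lines(path, body):
    path.write_text(VCF_HEADER + body)
    return str(path)


@pytest.fixture
def two_sample_panel():
    return PanelConfig({"s1": "popA", "s2": "popA"},
                       {"popA": frozenset({"target"})})


class TestReadVcf:
    def test_het_counts(self, tmp_path, two_sample_panel):
        path = write_lines(tmp_path / "a.vcf",
                           "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\n")
        t = read_vcf(path, two_sample_panel)
        assert t.alt_counts[0, 0] == 1
        assert t.called[0, 0] == 4
        assert t.freq("popA")[0] == 0.25

    def test_all_missing_population_undefined(self, tmp_path, two_sample_panel):
        path = write_lines(tmp_path / "a.vcf",
                           "1\t100\t.\tA\tG\t.\t.\t.\tGT\t./.\t./.\n")
        t = read_vcf(path, two_sample_panel)
        assert np.isnan(t.freq("popA")[0])

    def test_indel_and_multiallelic_dropped(self, tmp_path, two_sample_panel):
        body = ("1\t100\t.\tAT\tA\t.\t.\t.\tGT\t0/1\t0/0\n"
                "1\t200\t.\tA\tG,T\t.\t.\t.\tGT\t0/1\t0/0\n"
                "1\t300\t.\tA\tG\t.\t.\t.\tGT\t1/1\t0/0\n")
        t = read_vcf(write_lines(tmp_path / "a.vcf", body), two_sample_panel)
        assert t.n_sites == 1
        assert t.meta["dropped_non_snp"] == 2

    def test_no_panel_overlap_errors(self, tmp_path):
        path = write_lines(tmp_path / "a.vcf",
                           "1\t100\t.\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\n")
        other = PanelConfig({"x": "p"}, {"p": frozenset({"target"})})
        with pytest.raises(PanelError):
            read_vcf(path, other)

    def test_round_trip(self, tmp_path):
        spec = SimTreeSpec.star(["a", "b"], F=0.1, n=5, seed=4)
        table = simulate_sites(spec, 50)
        panel = default_panel(spec)
        write_vcf(table, tmp_path / "rt.vcf")
        back = read_vcf(tmp_path / "rt.vcf", panel)
        assert np.array_equal(back.genotypes, table.genotypes)
        assert back.sites["pos"].tolist() == table.sites["pos"].tolist()
        assert np.array_equal(back.alt_counts, table.alt_counts)


class TestHardFilter:
    def make(self, **ann):
        t = simulate_sites(SimTreeSpec.star(["a"], F=0.1, n=4, seed=0), 1)
        for k, v in ann.items():
            t.sites[k] = v
        return t

    @pytest.mark.parametrize("ann,rule", [
        (dict(QD=1.5, MQ=50.0, FS=10.0, MQRankSum=0.0, ReadPosRankSum=0.0), "QD"),
        (dict(QD=2.5, MQ=50.0, FS=61.0, MQRankSum=0.0, ReadPosRankSum=0.0), "FS"),
        (dict(QD=2.5, MQ=39.0, FS=10.0, MQRankSum=0.0, ReadPosRankSum=0.0), "MQ"),
        (dict(QD=2.5, MQ=50.0, FS=10.0, MQRankSum=-13.0, ReadPosRankSum=0.0),
         "MQRankSum"),
    ], ids=["qd", "strand_bias", "mq", "mqranksum"])
    def test_failing_site_removed(self, ann, rule):
        out, counts = hard_filter(self.make(**ann))
        assert out.n_sites == 0
        assert counts[rule] == 1

    def test_passing_site_retained(self):
        t = self.make(QD=2.5, MQ=50.0, FS=10.0, MQRankSum=0.0,
                      ReadPosRankSum=0.0)
        out, counts = hard_filter(t)
        assert out.n_sites == 1
        assert counts["total_removed"] == 0

    def test_missing_annotation_passes(self):
        t = self.make(QD=np.nan)
        out, _ = hard_filter(t)
        assert out.n_sites == 1

    def test_idempotent_and_multirule_accounting(self):
        t = self.make(QD=1.0, MQ=10.0, FS=100.0, MQRankSum=0.0,
                      ReadPosRankSum=0.0)
        out, counts = hard_filter(t)
        assert counts["total_removed"] == 1
        assert counts["QD"] + counts["MQ"] + counts["FS"] == 3
        again, counts2 = hard_filter(out)
        assert again.n_sites == out.n_sites
        assert counts2["total_removed"] == 0


class TestPresenceFilter:
    def make(self, n_called, n_samples=80):
        spec = SimTreeSpec.star(["a"], F=0.1, n=n_samples, seed=1)
        t = simulate_sites(spec, 1)
        t.genotypes[0, n_called:] = -1
        panel_io.recount_from_genotypes(t)
        return t

    def test_inclusive_boundary(self):
        assert presence_filter(self.make(20), 0.25).n_sites == 1

    def test_below_boundary_removed(self):
        assert presence_filter(self.make(19), 0.25).n_sites == 0

    def test_full_presence_requires_no_missing(self):
        assert presence_filter(self.make(79), 1.0).n_sites == 0
        assert presence_filter(self.make(80), 1.0).n_sites == 1

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            presence_filter(self.make(20), 0.0)


class TestPanelConfig:
    def test_tsv_round_trip(self, tmp_path, six_group_panel):
        six_group_panel.to_tsv(tmp_path / "panel.tsv")
        back = PanelConfig.from_tsv(tmp_path / "panel.tsv")
        assert back == six_group_panel

    def test_unknown_tag_rejected(self):
        with pytest.raises(PanelError):
            PanelConfig({"s": "p"}, {"p": frozenset({"martian"})})

    def test_target_required(self):
        with pytest.raises(PanelError):
            PanelConfig({"s": "p"}, {"p": frozenset({"other"})})


class TestGeneAnnotation:
    def test_bed12_round_trip(self, tmp_path):
        genes = [GeneAnnotation("g1", "1", 100, 400, "+",
                                ((100, 160, 0), (200, 260, 0), (300, 345, 0)))]
        panel_io.write_genes_bed12(genes, tmp_path / "g.bed")
        back = panel_io.read_genes_bed12(tmp_path / "g.bed")
        assert back == genes

    def test_overlapping_cds_rejected(self):
        with pytest.raises(ValueError):
            GeneAnnotation("g", "1", 0, 100, "+", ((0, 50, 0), (40, 90, 0)))


def test_autosome_filter():
    spec = SimTreeSpec.star(["a"], F=0.1, n=4, seed=0)
    t = simulate_sites(spec, 10)
    t.sites.loc[t.sites.index[:3], "chrom"] = "X"
    kept = panel_io.autosome_filter(t, ["1"])
    assert kept.n_sites == 7
    assert set(kept.sites["chrom"]) == {"1"}
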