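"""Reading, writing and round-tripping the pipeline's file formats."""

import numpy as np
import pytest

from ylineage.io import (
    read_call_table,
    read_haplotype_matrix,
    read_network,
    write_haplotype_matrix,
    write_network,
)
from ylineage.matrix import Call
from ylineage.network import construct_mj_network
from ylineage.simulate import SplitModelParams, simulate_split_haplotypes


class TestPackagedPanel:
    def test_dimensions(self, table1):
        assert table1.n_samples == 19
        assert table1.n_sites == 31
        assert sum(s.assayed for s in table1.sites) == 13

    def test_sample_provenance(self, table1):
        sequenced = [s for s in table1.samples if s.sequenced]
        assert len(sequenced) == 17
        genotyped = [s for s in table1.samples if s.genotyped]
        assert len(genotyped) == 10

    def test_genotyped_only_sample_missing_at_unassayed_sites(self, table1):
        row = table1.row("S12-1163")
        assert int((row != Call.MISSING).sum()) == 13
        assert int((row == Call.MISSING).sum()) == 18
        # all non-missing calls sit at assayed loci
        for j, site in enumerate(table1.sites):
            assert (row[j] != Call.MISSING) == site.assayed

    def test_site_alleles_match_locus_name_suffixes(self, table1):
        # locus ids end with the (unordered) allele pair, e.g. G_343GC
        for site in table1.sites:
            if site.locus_id == "R_805G":  # truncated name in the source
                continue
            suffix = site.locus_id.rsplit("_", 1)[-1]
            pair = set(suffix[-2:])
            assert pair == {site.ancestral_allele, site.derived_allele}

    def test_excluded_locus_discrepancy_recorded(self, table1):
        assert set(table1.metadata["excluded_locus_aliases"]) == {
            "20_357AT", "20_349AT",
        }


class TestMatrixTsv:
    def test_roundtrip(self, tmp_path, table1):
        paths = [tmp_path / n for n in ("m.tsv", "sites.tsv", "samples.tsv")]
        write_haplotype_matrix(table1, *paths)
        back = read_haplotype_matrix(paths[0], sites_path=paths[1],
                                     samples_path=paths[2])
        assert back == table1

    def test_roundtrip_simulated(self, tmp_path):
        m, _ = simulate_split_haplotypes(SplitModelParams(seed=11))
        paths = [tmp_path / n for n in ("m.tsv", "s.tsv", "p.tsv")]
        write_haplotype_matrix(m, *paths)
        back = read_haplotype_matrix(paths[0], sites_path=paths[1],
                                     samples_path=paths[2])
        assert back == m

    def test_all_ancestral_sample(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "sample\tpopulation\tL1\tL2\n"
            "Ancestral\t\tA\tC\n"
            "s1\tpop\t-\t-\n"
        )
        m = read_haplotype_matrix(p)
        assert m.n_samples == 1
        assert (m.calls == Call.ANCESTRAL).all()

    def test_malformed_row_length_names_row(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "sample\tpopulation\tL1\tL2\n"
            "Ancestral\t\tA\tC\n"
            "s1\tpop\t-\n"
        )
        with pytest.raises(ValueError, match="s1"):
            read_haplotype_matrix(p)

    def test_unknown_allele_names_sample_and_locus(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "sample\tpopulation\tL1\tL2\n"
            "Ancestral\t\tA\tC\n"
            "s1\tpop\tG\t-\n"
            "s2\tpop\tT\t-\n"
        )
        sites = tmp_path / "sites.tsv"
        sites.write_text(
            "locus_id\tancestral_allele\tderived_allele\n"
            "L1\tA\tG\nL2\tC\tT\n"
        )
        with pytest.raises(ValueError, match="s2.*L1"):
            read_haplotype_matrix(p, sites_path=sites)

    def test_two_derived_alleles_without_metadata_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "sample\tpopulation\tL1\n"
            "Ancestral\t\tA\n"
            "s1\tpop\tG\n"
            "s2\tpop\tT\n"
        )
        with pytest.raises(ValueError, match="bi-allelic"):
            read_haplotype_matrix(p)


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=frag1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


class TestVcf:
    def test_depths_read_through(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(
            VCF_HEADER
            + "frag1\t10\t.\tA\tG\t50\tPASS\t.\tGT:DP\t0:12\t1:8\n"
            + "frag1\t20\t.\tC\tT\t50\tPASS\t.\tGT:DP\t0:30\t0:20\n"
            + "frag1\t30\t.\tG\tA\t50\tPASS\t.\tGT:DP\t1:200\t1:100\n"
        )
        table = read_call_table(p, format="vcf")
        assert [pr.pooled_depth for pr in table.profiles] == [20, 50, 300]
        assert not any(pr.het_flag for pr in table.profiles)

    def test_heterozygote_sets_paralogy_flag_not_allele(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(
            VCF_HEADER
            + "frag1\t10\t.\tA\tG\t50\tPASS\t.\tGT:DP\t0/1:40\t0:10\n"
        )
        table = read_call_table(p, format="vcf")
        assert table.profiles[0].het_flag
        het_call = table.calls.query("sample == 'S1'").iloc[0]["call"]
        assert het_call == "MISSING"  # never decoded into the matrix

    def test_multiallelic_routed_to_filtering(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(
            VCF_HEADER
            + "frag1\t10\t.\tA\tG,T\t50\tPASS\t.\tGT:DP\t0:10\t0:10\n"
        )
        table = read_call_table(p, format="vcf")
        assert table.multiallelic_sites == [0]

    def test_missing_depth_field_names_dp(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=frag1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "frag1\t10\t.\tA\tG\t50\tPASS\t.\tGT\t0\t1\n"
        )
        with pytest.raises(ValueError, match="DP"):
            read_call_table(p, format="vcf")


class TestNetworkFiles:
    @pytest.mark.parametrize("fmt", ["graphml", "dot"])
    def test_roundtrip(self, tmp_path, tiny_matrix, fmt):
        net = construct_mj_network(tiny_matrix)
        p = tmp_path / f"net.{fmt}"
        write_network(net, p, format=fmt)
        back = read_network(p, format=fmt)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert set(map(frozenset, back.graph.edges)) == set(
            map(frozenset, net.graph.edges)
        )
        for n in net.graph.nodes:
            a, b = net.graph.nodes[n], back.graph.nodes[n]
            assert np.array_equal(a["state"], b["state"])
            for key in ("multiplicity", "labels", "is_median", "is_root"):
                assert a[key] == b[key], (n, key)
        for e in net.graph.edges:
            assert net.graph.edges[e]["weight"] == back.graph.edges[e]["weight"]
            assert net.graph.edges[e]["loci"] == back.graph.edges[e]["loci"]

    def test_root_attribute_on_table1_network(self, tmp_path, table1_sequenced):
        net = construct_mj_network(table1_sequenced)
        p = tmp_path / "net.graphml"
        write_network(net, p)
        back = read_network(p)
        roots = [n for n, a in back.graph.nodes(data=True) if a["is_root"]]
        assert roots == [net.root]
        # the root carries the all-ancestral haplotype
        assert not back.graph.nodes[roots[0]]["state"].any()
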