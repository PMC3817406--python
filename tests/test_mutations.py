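from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from colsen.mutations import (
    DEFAULT_GENE_UNIVERSE,
    MutationRecord,
    MutationTableError,
    chemogenomic_overlap_test,
    convergence_stats,
    geneset_enrichment,
    read_mutation_table,
    simulate_resequencing_panel,
    synthetic_chemogenomic_hits,
    write_mutation_table,
)


def rec(clone, gene, pos, alt="T", mtype="SNP", coding=True, syn=False):
    return MutationRecord(clone, gene, pos, "C", alt, mtype, coding, syn if coding else None)


class TestRecords:
    def test_position_must_be_positive(self):
        with pytest.raises(MutationTableError):
            rec("c1", "trkH", 0)

    def test_synonymous_only_when_coding(self):
        with pytest.raises(MutationTableError):
            MutationRecord("c1", "x", 5, "C", "T", "SNP", False, True)

    def test_unknown_type_rejected(self):
        with pytest.raises(MutationTableError):
            MutationRecord("c1", "x", 5, "C", "T", "SV", True, False)


class TestIo:
    def test_tsv_roundtrip(self, tmp_path):
        records = [rec("c1", "trkH", 10), rec("c2", "cyoB", 20, mtype="deletion", alt=""), rec("c1", "x", 5, coding=False)]
        path = tmp_path / "muts.tsv"
        write_mutation_table(records, path)
        back = read_mutation_table(path)
        assert back == records

    def test_empty_table(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("clone_id\tgene\tposition\tref\talt\tmtype\tcoding\tsynonymous\n")
        assert read_mutation_table(path) == []

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "clone_id\tgene\tposition\tref\talt\tmtype\tcoding\tsynonymous\n"
            "c1\ttrkH\t0\tC\tT\tSNP\ttrue\tfalse\n"
        )
        with pytest.raises(MutationTableError, match="line 2"):
            read_mutation_table(path)

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("clone_id\tgene\n")
        with pytest.raises(MutationTableError, match="missing columns"):
            read_mutation_table(path)

    def test_vcf_reading(self, tmp_path):
        vcf = tmp_path / "muts.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
            '##INFO=<ID=CODING,Number=0,Type=Flag,Description="coding">\n'
            '##INFO=<ID=SYN,Number=0,Type=Flag,Description="synonymous">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">\n'
            "##contig=<ID=chr1,length=4641652>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tcloneA\tcloneB\n"
            "chr1\t100\t.\tC\tT\t.\tPASS\tGENE=trkH;CODING\tGT\t1\t0\n"
            "chr1\t200\t.\tG\tGAA\t.\tPASS\tGENE=cyoB;CODING\tGT\t1\t1\n"
        )
        records = read_mutation_table(vcf, format="vcf")
        assert len(records) == 3
        first = [r for r in records if r.position == 100]
        assert first == [MutationRecord("cloneA", "trkH", 100, "C", "T", "SNP", True, False)]
        assert {r.clone_id for r in records if r.gene == "cyoB"} == {"cloneA", "cloneB"}
        assert all(r.mtype == "insertion" for r in records if r.gene == "cyoB")


class TestConvergence:
    def test_study_condition_panel_bookkeeping(self):
        """14 clones: 12 escalation clones x8 + 2 fixed x2 = 100 mutations."""
        records, roster = simulate_resequencing_panel(seed=0)
        s = convergence_stats(records, roster)
        assert s.total_mutations == 100
        assert s.group_means["gradient"] == pytest.approx(8.0)
        assert s.group_means["fixed"] == pytest.approx(2.0)
        assert s.fraction_coding_nonsynonymous == pytest.approx(0.89)
        assert s.n_genes == 44
        assert s.n_repeated_genes == 13
        assert s.repeated_gene_fraction == pytest.approx(13 / 44)
        assert s.n_shared_sites == 3
        assert s.shared_mutation_fraction == pytest.approx(0.07)

    def test_single_clone_no_sharing(self):
        records = [rec("c1", "trkH", 10), rec("c1", "trkH", 20)]
        roster = pd.DataFrame({"clone_id": ["c1"], "group": ["g"]})
        s = convergence_stats(records, roster)
        assert s.n_shared_sites == 0
        assert s.shared_site_fraction == 0.0
        assert s.n_repeated_genes == 0

    def test_three_clone_table_matches_bruteforce(self):
        records = [
            rec("c1", "trkH", 10),
            rec("c2", "trkH", 10),  # shared site
            rec("c3", "trkH", 99),  # same gene, new site
            rec("c1", "cyoB", 50),
            rec("c2", "fusA", 60),
            rec("c3", "fusA", 61),
            rec("c3", "rpsL", 70, alt="G"),
            rec("c1", "rpsL", 70, alt="A"),  # same position, different allele
        ]
        roster = pd.DataFrame({"clone_id": ["c1", "c2", "c3"], "group": ["g"] * 3})
        s = convergence_stats(records, roster)
        # brute force over distinct sites
        sites = {}
        for r in records:
            sites.setdefault((r.gene, r.position, r.alt), set()).add(r.clone_id)
        shared = [k for k, v in sites.items() if len(v) >= 2]
        assert s.n_sites == len(sites) == 7
        assert s.n_shared_sites == len(shared) == 1
        assert s.shared_site_fraction == pytest.approx(1 / 7)
        pos_sites = {}
        for r in records:
            pos_sites.setdefault((r.gene, r.position), set()).add(r.clone_id)
        assert s.n_shared_sites_position_only == sum(len(v) >= 2 for v in pos_sites.values()) == 2
        genes = {}
        for r in records:
            genes.setdefault(r.gene, set()).add(r.clone_id)
        assert s.n_repeated_genes == sum(len(v) >= 2 for v in genes.values()) == 3
        assert s.total_mutations == 8

    def test_unknown_clone_rejected(self):
        roster = pd.DataFrame({"clone_id": ["c1"], "group": ["g"]})
        with pytest.raises(MutationTableError):
            convergence_stats([rec("c9", "trkH", 10)], roster)

    def test_totals_conserved_under_grouping(self):
        records, roster = simulate_resequencing_panel(seed=3)
        s = convergence_stats(records, roster)
        assert s.per_clone.sum() == s.total_mutations == len(records)


class TestOverlapTest:
    def test_subset_overlap_one(self):
        res = chemogenomic_overlap_test({"a", "b"}, {"a", "b", "c"}, 100)
        assert res.overlap_fraction == 1.0

    def test_disjoint_sets_match_hypergeometric_oracle(self):
        mutated = {f"m{i}" for i in range(10)}
        hits = {f"h{i}" for i in range(100)}
        res = chemogenomic_overlap_test(mutated, hits, 4000)
        # two-sided Fisher by direct hypergeometric summation
        p_obs = hypergeom.pmf(0, 4000, 100, 10)
        oracle = sum(
            hypergeom.pmf(k, 4000, 100, 10)
            for k in range(0, 11)
            if hypergeom.pmf(k, 4000, 100, 10) <= p_obs * (1 + 1e-9)
        )
        assert res.pvalue == pytest.approx(oracle, rel=1e-9)

    def test_symmetry(self):
        a = {f"m{i}" for i in range(20)}
        b = {f"m{i}" for i in range(15, 60)}
        r1 = chemogenomic_overlap_test(a, b, 500)
        r2 = chemogenomic_overlap_test(b, a, 500)
        assert r1.pvalue == pytest.approx(r2.pvalue, rel=1e-12)

    def test_universe_boundary(self):
        a, b = {"x", "y"}, {"x", "y"}
        res = chemogenomic_overlap_test(a, b, 3)
        assert 0 < res.pvalue <= 1

    def test_synthetic_hits_config(self):
        records, _ = simulate_resequencing_panel(seed=0)
        mutated = {r.gene for r in records}
        hits = synthetic_chemogenomic_hits(mutated, seed=1)
        res = chemogenomic_overlap_test(mutated, hits, DEFAULT_GENE_UNIVERSE)
        assert res.overlap_fraction == pytest.approx(16 / 44)
        assert res.pvalue < 0.05


class TestEnrichment:
    def test_identical_set_most_enriched(self):
        mutated = {"a", "b", "c"}
        coll = {"self": mutated, "noise": {"x", "y", "z", "w"}}
        out = geneset_enrichment(mutated, coll, 50)
        out = out.set_index("set")
        assert out.loc["self", "pvalue"] == out["pvalue"].min()

    def test_disjoint_set_p_one(self):
        out = geneset_enrichment({"a"}, {"s": {"x", "y"}}, 100).set_index("set")
        assert out.loc["s", "pvalue"] == pytest.approx(1.0)

    def test_bh_matches_hand_calculation(self):
        """q-values reproduce the manual step-up ordering on a 5-set toy."""
        mutated = {f"g{i}" for i in range(10)}
        coll = {
            "s1": set(list(mutated)[:8]) | {"x1"},
            "s2": set(list(mutated)[:4]) | {f"x{i}" for i in range(6)},
            "s3": {f"x{i}" for i in range(10)},
            "s4": set(list(mutated)[:2]) | {f"y{i}" for i in range(8)},
            "s5": set(list(mutated)[:6]) | {f"z{i}" for i in range(4)},
        }
        out = geneset_enrichment(mutated, coll, 200)
        p = out["pvalue"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        hand = np.empty(m)
        prev = 1.0
        for rank_from_last, idx in enumerate(order[::-1]):
            rank = m - rank_from_last
            prev = min(prev, p[idx] * m / rank)
            hand[idx] = prev
        assert np.allclose(out["qvalue"], hand, atol=1e-12)

    def test_empty_collection_rejected(self):
        with pytest.raises(MutationTableError):
            geneset_enrichment({"a"}, {}, 10)
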