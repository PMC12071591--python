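import numpy as np
import pandas as pd
import pytest

from prsvalidate import formats_io as fio
from prsvalidate.formats_io import (
    FormatError,
    KinshipPair,
    ScoringVariant,
    read_bed,
    read_genotypes,
    read_scoring_file,
    read_tables,
    write_scoring_file,
    write_vcf,
)

SCORING_HEADER = "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n"


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestScoringFile:
    def test_well_formed_file_parses_all_rows(self, tmp_path):
        p = _write(tmp_path, "s.tsv", SCORING_HEADER
                   + "rs1\t1\t100\tA\tG\t0.12\n"
                   + "rs2\t1\t200\tC\tT\t-0.05\n"
                   + "rs3\t2\t300\tG\tA\t0.0\n")
        sf = read_scoring_file(p)
        assert len(sf) == 3
        # zero beta is parsed here; filtering is downstream policy
        assert sf.variants[2].beta == 0.0

    def test_non_acgt_allele_rejected_with_diagnostic(self, tmp_path):
        p = _write(tmp_path, "s.tsv", SCORING_HEADER
                   + "rs1\t1\t100\tA\tG\t0.12\n"
                   + "rs2\t1\t200\tN\tT\t0.05\n")
        with pytest.warns(UserWarning, match="rejected 1"):
            sf = read_scoring_file(p)
        assert len(sf) == 1
        assert len(sf.rejects) == 1
        assert sf.rejects[0][0] == 3  # 1-based line number of the bad row

    def test_missing_column_is_format_error(self, tmp_path):
        p = _write(tmp_path, "s.tsv",
                   "rsID\tchr_name\teffect_allele\tother_allele\teffect_weight\n"
                   "rs1\t1\tA\tG\t0.12\n")
        with pytest.raises(FormatError, match="chr_position"):
            read_scoring_file(p)

    def test_round_trip_is_field_identical(self, tmp_path):
        sf = read_scoring_file(_write(tmp_path, "s.tsv", SCORING_HEADER
                                      + "rs1\t1\t100\tA\tG\t0.123456789\n"
                                      + "rs2\tX\t200\tC\tT\t-1e-4\n"))
        out = tmp_path / "round.tsv"
        write_scoring_file(sf, out)
        back = read_scoring_file(out)
        assert back.variants == sf.variants

    def test_duplicate_variant_key_rejected(self):
        v = ScoringVariant("rs1", "1", 5, "A", "G", 0.1)
        with pytest.raises(FormatError, match="duplicate"):
            fio.ScoringFile(prs_name="d", variants=[v, v])

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ScoringVariant("rs1", "1", 5, "A", "A", 0.1)
        with pytest.raises(ValueError):
            ScoringVariant("rs1", "1", 0, "A", "G", 0.1)
        with pytest.raises(ValueError):
            ScoringVariant("rs1", "1", 5, "A", "G", float("nan"))


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
    '##FORMAT=<ID=DS,Number=A,Type=Float,Description="d">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
)


class TestReadGenotypes:
    def _scoring(self, rows):
        return fio.ScoringFile(prs_name="t", variants=[
            ScoringVariant(f"rs{i}", c, p, e, o, b)
            for i, (c, p, e, o, b) in enumerate(rows)])

    def test_gt_het_alt_effect_gives_dosage_one(self, tmp_path):
        vcf = _write(tmp_path, "a.vcf", VCF_HEADER
                     + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n")
        sc = self._scoring([("1", 100, "G", "A", 0.2)])
        gm = read_genotypes(vcf, sc)
        assert gm.dosages.tolist() == [[1.0], [2.0]]

    def test_ds_preferred_when_requested(self, tmp_path):
        vcf = _write(tmp_path, "a.vcf", VCF_HEADER
                     + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT:DS\t0/1:1.37\t0/0:0.02\n")
        sc = self._scoring([("1", 100, "G", "A", 0.2)])
        gm = read_genotypes(vcf, sc, prefer_dosage=True)
        assert gm.dosages[0, 0] == pytest.approx(1.37, abs=1e-6)
        gm_gt = read_genotypes(vcf, sc, prefer_dosage=False)
        assert gm_gt.dosages[0, 0] == 1.0

    def test_absent_scoring_variant_listed_not_found(self, tmp_path):
        vcf = _write(tmp_path, "a.vcf", VCF_HEADER
                     + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n")
        sc = self._scoring([("1", 100, "G", "A", 0.2), ("2", 500, "C", "T", 0.1)])
        gm = read_genotypes(vcf, sc)
        assert gm.n_sites == 1
        assert gm.not_found == [sc.variants[1].key]

    def test_multiallelic_split_matches_single_alternate(self, tmp_path):
        vcf = _write(tmp_path, "a.vcf", VCF_HEADER
                     + "1\t100\t.\tA\tG,C\t.\tPASS\t.\tGT\t0/2\t1/2\n")
        sc = self._scoring([("1", 100, "C", "A", 0.2)])
        gm = read_genotypes(vcf, sc)
        # counts of the C alternate only
        assert gm.dosages.tolist() == [[1.0], [1.0]]
        assert gm.sites[0].alt == "C"

    def test_missing_gt_stored_as_nan(self, tmp_path):
        vcf = _write(tmp_path, "a.vcf", VCF_HEADER
                     + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\n")
        sc = self._scoring([("1", 100, "G", "A", 0.2)])
        gm = read_genotypes(vcf, sc)
        assert np.isnan(gm.dosages[0, 0]) and gm.dosages[1, 0] == 1.0

    def test_vcf_round_trip_recovers_simulated_matrix(self, tmp_path, small_cohort):
        gm = small_cohort.genotypes
        sub = fio.GenotypeMatrix(samples=gm.samples[:30], sites=gm.sites[:40],
                                 dosages=gm.dosages[:30, :40])
        path = tmp_path / "cohort.vcf"
        write_vcf(path, sub.samples, sub.sites, sub.dosages)
        back = read_genotypes(path, small_cohort.scoring)
        cols = {(s.chrom, s.pos): j for j, s in enumerate(back.sites)}
        order = [cols[(s.chrom, s.pos)] for s in sub.sites]
        np.testing.assert_array_equal(back.dosages[:, order], sub.dosages)


META = ("sample_id\tstatus\tsex\tage\tBRCA1\tATM\n"
        "s1\tcase\tfemale\t50\t0\t1\n"
        "s2\tcontrol\tmale\t41\t1\t0\n"
        "s3\tcontrol\tfemale\t39\t0\t0\n"
        "s4\tcase\tfemale\t61\t0\t0\n"
        "s5\tcontrol\tmale\t45\t0\t0\n")


class TestReadTables:
    def test_join_and_counts(self, tmp_path):
        meta = _write(tmp_path, "m.tsv", META)
        kin = _write(tmp_path, "k.tsv", "sample_a\tsample_b\tdegree\ns1\ts2\t1\n")
        anc = _write(tmp_path, "a.tsv", "sample_id\tEUR\tAFR\tEAS\tAMR\n"
                     "s1\t0.8\t0.1\t0.05\t0.05\n")
        records, pairs = read_tables(meta, kin, anc)
        assert len(records) == 5 and len(pairs) == 1
        assert records[0].carrier_flags == {"BRCA1": False, "ATM": True}
        assert records[1].ancestry_props == {}  # no ancestry row -> empty

    def test_ancestry_near_one_renormalized(self, tmp_path):
        meta = _write(tmp_path, "m.tsv", META)
        anc = _write(tmp_path, "a.tsv", "sample_id\tEUR\tAFR\tEAS\tAMR\n"
                     "s1\t0.78\t0.1\t0.05\t0.05\n")  # sums to 0.98
        records, _ = read_tables(meta, ancestry_path=anc)
        assert sum(records[0].ancestry_props.values()) == pytest.approx(1.0)

    def test_ancestry_far_from_one_rejected(self, tmp_path):
        meta = _write(tmp_path, "m.tsv", META)
        anc = _write(tmp_path, "a.tsv", "sample_id\tEUR\tAFR\tEAS\tAMR\n"
                     "s1\t0.5\t0.1\t0.05\t0.05\n")
        with pytest.warns(UserWarning, match="rejected 1"):
            records, _ = read_tables(meta, ancestry_path=anc)
        assert records[0].ancestry_props == {}

    def test_self_pair_and_unknown_sample_dropped(self, tmp_path):
        meta = _write(tmp_path, "m.tsv", META)
        kin = _write(tmp_path, "k.tsv", "sample_a\tsample_b\tdegree\n"
                     "s1\ts1\t1\nnope\ts2\t1\ns3\ts4\t1\n")
        with pytest.warns(UserWarning, match="dropped 2"):
            _, pairs = read_tables(meta, kin)
        assert len(pairs) == 1

    def test_duplicate_sample_id_is_error(self, tmp_path):
        meta = _write(tmp_path, "m.tsv",
                      "sample_id\tstatus\ns1\tcase\ns1\tcontrol\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_tables(meta)

    def test_kinship_pair_invariants(self):
        with pytest.raises(ValueError):
            KinshipPair("a", "a", degree=1)
        with pytest.raises(ValueError):
            KinshipPair("a", "b", coefficient=0.7)
        assert KinshipPair("a", "b", coefficient=0.25).coefficient == 0.25


def test_read_bed_merges_overlaps(tmp_path):
    p = _write(tmp_path, "t.bed", "1\t100\t200\n1\t150\t300\n1\t400\t500\n2\t0\t10\n")
    bed = read_bed(p)
    assert bed["1"].tolist() == [[100, 300], [400, 500]]
    assert bed["2"].tolist() == [[0, 10]]
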