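import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prsvalidate.formats_io import ScoringFile, ScoringVariant, VariantSite
from prsvalidate.score_engine import (
    Orientation,
    ScoringError,
    compute_scores,
    filter_scoring_variants,
    match_alleles,
    normalization_bounds,
)

from conftest import make_genotypes, make_scoring


def _variant(i, beta, chrom="1", pos=None, eff="G", oth="A", vid=None):
    return ScoringVariant(vid or f"rs{i}", chrom, pos or (1000 + i), eff, oth, beta)


class TestFilter:
    def test_null_beta_dropped(self):
        sf = ScoringFile("t", [_variant(0, 0.0), _variant(1, 0.3)])
        kept, drops = filter_scoring_variants(sf)
        assert drops["null-beta"] == 1 and len(kept) == 1

    def test_distance_rule_keeps_near_and_drops_far(self):
        # target covers 0-based [2000, 2100); positions are 1-based
        targets = {"1": np.array([[2000, 2100]])}
        near = _variant(0, 0.1, pos=2111)   # 10 bp past the last target base
        far = _variant(1, 0.1, pos=2500)    # 400 bp past
        inside = _variant(2, 0.1, pos=2050)
        sf = ScoringFile("t", [near, far, inside])
        kept, drops = filter_scoring_variants(sf, targets=targets, max_distance_bp=200)
        assert {v.variant_id for v in kept.variants} == {"rs0", "rs2"}
        assert drops["off-target"] == 1

    def test_chromosome_without_targets_is_off_target(self):
        sf = ScoringFile("t", [_variant(0, 0.1, chrom="2"), _variant(1, 0.1)])
        kept, drops = filter_scoring_variants(sf, targets={"1": np.array([[0, 10**9]])})
        assert drops["off-target"] == 1 and len(kept) == 1

    def test_exclusion_list_and_maf(self):
        sf = ScoringFile("t", [_variant(0, 0.1), _variant(1, 0.1), _variant(2, 0.1)])
        kept, drops = filter_scoring_variants(
            sf, maf={"rs1": 0.0002}, maf_min=0.001, exclusion_ids={"rs2"})
        assert drops["maf-filtered"] == 1 and drops["exclusion-list"] == 1
        assert [v.variant_id for v in kept.variants] == ["rs0"]

    def test_everything_dropped_is_error(self):
        sf = ScoringFile("t", [_variant(0, 0.0)])
        with pytest.raises(ScoringError, match="no scorable"):
            filter_scoring_variants(sf)


class TestMatchAlleles:
    def _geno(self, sites):
        import numpy as np
        return make_genotypes(np.zeros((1, len(sites))), sites)

    def test_orientations(self):
        sites = [VariantSite("1", 1000, "A", "G")]
        geno = self._geno(sites)
        alt = ScoringFile("t", [ScoringVariant("r", "1", 1000, "G", "A", 0.1)])
        ref = ScoringFile("t", [ScoringVariant("r", "1", 1000, "A", "G", 0.1)])
        assert match_alleles(alt, geno)[0].orientation is Orientation.EFFECT_IS_ALT
        assert match_alleles(ref, geno)[0].orientation is Orientation.EFFECT_IS_REF

    def test_ambiguous_strand_excluded_by_default(self):
        sites = [VariantSite("1", 1000, "A", "T")]
        sf = ScoringFile("t", [ScoringVariant("r", "1", 1000, "A", "T", 0.1)])
        m = match_alleles(sf, self._geno(sites))[0]
        assert m.orientation is Orientation.EXCLUDED and m.reason == "ambiguous-strand"
        m2 = match_alleles(sf, self._geno(sites), allow_ambiguous=True)[0]
        assert m2.orientation is Orientation.EFFECT_IS_REF

    def test_not_found(self):
        sf = ScoringFile("t", [ScoringVariant("r", "9", 77, "G", "A", 0.1)])
        m = match_alleles(sf, self._geno([VariantSite("1", 1000, "A", "G")]))[0]
        assert m.reason == "not-found"


class TestComputeScores:
    def test_hand_evaluated_example(self):
        # betas {0.2, -0.1}, dosages {1, 2}: raw 0, normalized 1/3
        sf, sites = make_scoring([0.2, -0.1])
        geno = make_genotypes([[1.0, 2.0], [2.0, 0.0]], sites)
        matched = match_alleles(sf, geno)
        scores = compute_scores(matched, sf, geno, controls={"S0", "S1"})
        assert scores.raw[0] == pytest.approx(0.0)
        assert scores.normalized[0] == pytest.approx(1.0 / 3.0)

    def test_boundary_configurations_hit_zero_and_one(self):
        sf, sites = make_scoring([0.5, -0.25, 0.1])
        lo_d = [0.0, 2.0, 0.0]   # minimizing config
        hi_d = [2.0, 0.0, 2.0]   # maximizing config
        geno = make_genotypes([lo_d, hi_d], sites)
        scores = compute_scores(match_alleles(sf, geno), sf, geno, {"S0", "S1"})
        assert scores.normalized[0] == pytest.approx(0.0, abs=1e-12)
        assert scores.normalized[1] == pytest.approx(1.0, abs=1e-12)

    def test_effect_is_ref_flips_dosage(self):
        sf, sites = make_scoring([1.0], effect_is_alt=[False])
        geno = make_genotypes([[2.0], [0.0]], sites)  # ALT dosages
        scores = compute_scores(match_alleles(sf, geno), sf, geno, {"S0", "S1"})
        assert scores.raw.tolist() == [0.0, 2.0]  # effect dosage = 2 - alt

    def test_missing_dosage_mean_imputed_with_2eaf(self):
        sf, sites = make_scoring([1.0])
        d = np.array([[0.0], [2.0], [np.nan], [1.0]], dtype=np.float32)
        geno = make_genotypes(d, sites)
        scores = compute_scores(match_alleles(sf, geno), sf, geno,
                                {"S0", "S1", "S2", "S3"})
        assert scores.raw[2] == pytest.approx(1.0)  # 2 * EAF of (0,2,1)/2 = 1.0

    def test_standardized_controls_mean0_sd1(self, small_cohort):
        sf = small_cohort.scoring
        geno = small_cohort.genotypes
        controls = set(small_cohort.metadata.loc[
            small_cohort.metadata.status == "control", "sample_id"])
        scores = compute_scores(match_alleles(sf, geno), sf, geno, controls)
        mask = np.array([s in controls for s in scores.sample_ids])
        assert scores.standardized[mask].mean() == pytest.approx(0.0, abs=1e-8)
        assert scores.standardized[mask].std() == pytest.approx(1.0, abs=1e-8)
        assert np.all((scores.normalized >= 0) & (scores.normalized <= 1))

    def test_zero_sd_controls_is_error(self):
        sf, sites = make_scoring([1.0])
        geno = make_genotypes([[1.0], [1.0]], sites)
        with pytest.raises(ScoringError, match="SD is zero"):
            compute_scores(match_alleles(sf, geno), sf, geno, {"S0", "S1"})

    def test_allele_flip_with_beta_negation_invariance(self):
        rng = np.random.default_rng(5)
        betas = rng.normal(0, 0.3, 20)
        sf, sites = make_scoring(betas)
        d = rng.integers(0, 3, size=(30, 20)).astype(float)
        geno = make_genotypes(d, sites)
        controls = {f"S{i}" for i in range(15)}
        base = compute_scores(match_alleles(sf, geno), sf, geno, controls)

        flip = rng.random(20) < 0.5
        flipped_variants = []
        for v, f in zip(sf.variants, flip):
            if f:
                flipped_variants.append(ScoringVariant(
                    v.variant_id, v.chrom, v.pos, v.other_allele,
                    v.effect_allele, -v.beta))
            else:
                flipped_variants.append(v)
        sf2 = ScoringFile("flipped", flipped_variants)
        other = compute_scores(match_alleles(sf2, geno), sf2, geno, controls)
        np.testing.assert_allclose(other.normalized, base.normalized, atol=1e-12)
        np.testing.assert_allclose(other.standardized, base.standardized, atol=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_normalized_score_always_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, 15))
    betas = rng.normal(0, 1, m)
    betas[betas == 0] = 0.1
    sf, sites = make_scoring(betas)
    d = rng.uniform(0, 2, size=(8, m))
    geno = make_genotypes(d, sites)
    scores = compute_scores(match_alleles(sf, geno), sf, geno,
                            {f"S{i}" for i in range(8)})
    assert np.all(scores.normalized >= -1e-12)
    assert np.all(scores.normalized <= 1 + 1e-12)
    lo, hi = normalization_bounds(np.asarray(betas))
    assert lo <= scores.raw.min() and scores.raw.max() <= hi
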