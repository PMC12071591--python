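import numpy as np
import pytest

from prsvalidate.formats_io import GenotypeMatrix, ScoringFile, ScoringVariant, VariantSite
from prsvalidate.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured simulated cohort shared across tests."""
    cfg = SimulationConfig(n_cases=400, n_controls=600, n_variants=250,
                           n_families=12)
    return simulate_cohort(cfg, seed=11)


def make_scoring(betas, effect_is_alt=None, chrom="1", start_pos=1000):
    """ScoringFile + matching VariantSite list for hand-built genotype tests.

    Allele pairs are non-ambiguous (A/G).  ``effect_is_alt[i]`` False makes
    variant i's effect allele the REF.
    """
    betas = np.asarray(betas, dtype=float)
    if effect_is_alt is None:
        effect_is_alt = [True] * len(betas)
    variants, sites = [], []
    for i, (b, is_alt) in enumerate(zip(betas, effect_is_alt)):
        pos = start_pos + i
        ref, alt = "A", "G"
        eff, oth = (alt, ref) if is_alt else (ref, alt)
        variants.append(ScoringVariant(variant_id=f"rs{i}", chrom=chrom, pos=pos,
                                       effect_allele=eff, other_allele=oth,
                                       beta=float(b)))
        sites.append(VariantSite(chrom, pos, ref, alt))
    return ScoringFile(prs_name="test", variants=variants), sites


def make_genotypes(dosages, sites, sample_prefix="S"):
    dosages = np.asarray(dosages, dtype=np.float32)
    samples = [f"{sample_prefix}{i}" for i in range(dosages.shape[0])]
    return GenotypeMatrix(samples=samples, sites=sites, dosages=dosages)
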