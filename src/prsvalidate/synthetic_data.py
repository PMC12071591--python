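"""Admixed case-control cohort generator with known ground truth.

The generator emulates the statistical structure of a large Brazilian
breast-cancer PRS validation cohort so that every analysis stage can be
verified against known truth:

* per-sample admixture proportions ``q`` over EUR/AFR/EAS/AMR drawn from a
  EUR-skewed Dirichlet (median q_EUR ~ 0.84) plus a small EAS-concentrated
  component emulating the East-Asian-majority subgroup;
* per-ancestry allele frequencies from a Balding-Nichols model around a
  shared ancestral frequency, so PCs and admixture are recoverable;
* genotypes Binomial(2, q . p_k) — Hardy-Weinberg within the individual
  mixture, variants independent given ancestry (no LD: every downstream
  statistic in scope is LD-agnostic given dosages);
* disease status from a logistic liability model
  P(case) = expit(alpha + gamma * z + sum_g carrier_g * ln OR_g)
  with ``z`` the population-standardized true PRS, ``gamma`` the log-OR
  per SD, carrier flags for monogenic risk genes acting additively on the
  logit, and ``alpha`` solved for the target prevalence; cases/controls
  are then sampled down to the requested sizes (outcome-dependent
  sampling, under which the logistic per-SD OR remains consistent);
* first-degree family clusters (parent-offspring pairs and trios) for the
  relatedness-pruning stage, with Mendelian transmission;
* an imputation-noise channel that redraws a fraction of genotypes from
  their individual allele frequencies, with the fraction optionally
  calibrated by bisection to hit a target Spearman correlation between
  clean and noisy scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .concordance import compare_scores
from .formats_io import (
    ANCESTRIES,
    GenotypeMatrix,
    ScoringFile,
    ScoringVariant,
    VariantSite,
)
from . import score_engine

#: default carrier model: gene -> (population carrier frequency, true OR).
#: ORs follow the monogenic effect sizes reported for breast cancer
#: (high-penetrance BRCA1/BRCA2/TP53/PALB2/PTEN; moderate ATM/CHEK2; the
#: Brazilian TP53 R337H founder variant); frequencies are plausible
#: clinical-cohort carrier rates.
DEFAULT_CARRIER_SPEC = {
    "BRCA1": (0.010, 13.4),
    "BRCA2": (0.012, 8.8),
    "TP53": (0.0012, 14.0),
    "PALB2": (0.004, 5.0),
    "PTEN": (0.0008, 6.0),
    "ATM": (0.008, 2.5),
    "CHEK2": (0.010, 2.1),
    "TP53_R337H": (0.0025, 4.0),
}

#: non-strand-ambiguous (ref, alt) pairs
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the validation-cohort design: ~5.6k cases / ~8.8k
    controls, a 2575-variant score, per-SD effect gamma = ln 1.43,
    EUR-majority admixture with a ~1.5% EAS-concentrated component,
    monogenic carriers with ORs 2-14, first-degree family clusters, and
    imputation noise calibrated to Spearman rho 0.74.
    """

    n_cases: int = 5598
    n_controls: int = 8767
    n_variants: int = 2575
    dirichlet_alpha: tuple = (5.0, 0.55, 0.1, 0.55)   # EUR, AFR, EAS, AMR
    eas_fraction: float = 0.015
    eas_dirichlet_alpha: tuple = (0.3, 0.1, 8.0, 0.2)
    fst: tuple = (0.10, 0.15, 0.15, 0.12)
    ancestral_af_range: tuple = (0.05, 0.95)
    beta_sd: float = 0.05
    gamma: float = float(np.log(1.43))   # log-OR per SD of the true score
    prevalence: float = 0.10
    carrier_spec: dict = field(default_factory=lambda: dict(DEFAULT_CARRIER_SPEC))
    n_families: int = 100
    family_offspring: int = 1
    noise_epsilon: float | None = None
    target_rho: float | None = 0.74
    prs_name: str = "PRS_synth"
    chunk_size: int = 20000

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0,1)")
        if not np.isfinite(self.gamma):
            raise ValueError("gamma must be finite")
        if not 0 <= self.eas_fraction < 1:
            raise ValueError("eas_fraction must be in [0,1)")
        lo, hi = self.ancestral_af_range
        if not (0 < lo < hi < 1):
            raise ValueError("ancestral_af_range must satisfy 0 < lo < hi < 1")
        for gene, (freq, or_) in self.carrier_spec.items():
            if not 0 < freq < 1:
                raise ValueError(f"{gene}: carrier frequency must be in (0,1)")
            if or_ <= 0:
                raise ValueError(f"{gene}: OR must be positive")


@dataclass
class TruthSet:
    """Ground truth for every simulated sample."""

    sample_ids: list[str]
    q: np.ndarray              # n x 4 admixture proportions
    z_true: np.ndarray         # population-standardized true score
    liability: np.ndarray      # alpha + gamma*z + carrier term (logit scale)
    status: np.ndarray         # 1 = case
    carrier_flags: pd.DataFrame
    pedigree_edges: list[tuple[str, str]]
    ancestral_afs: np.ndarray  # 4 x m ALT allele frequencies
    alpha: float
    raw_mu: float
    raw_sd: float
    gamma: float

    def site_afs(self) -> np.ndarray:
        """Per-sample, per-variant individual ALT allele frequencies."""
        return self.q @ self.ancestral_afs


@dataclass
class SimulatedCohort:
    """Everything the pipeline consumes, plus the truth behind it."""

    config: SimulationConfig
    scoring: ScoringFile
    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    kinship: pd.DataFrame
    ancestry: pd.DataFrame
    truth: TruthSet

    def write(self, out_dir, with_ds: bool = False) -> dict:
        """Emit VCF + scoring/metadata/kinship/ancestry TSVs + truth JSON."""
        import json
        from pathlib import Path

        from .formats_io import write_scoring_file, write_vcf

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "scoring": out / "scoring.tsv",
            "metadata": out / "metadata.tsv",
            "kinship": out / "kinship.tsv",
            "ancestry": out / "ancestry.tsv",
            "truth": out / "truth.json",
        }
        write_vcf(paths["vcf"], self.genotypes.samples, self.genotypes.sites,
                  self.genotypes.dosages, with_ds=with_ds)
        write_scoring_file(self.scoring, paths["scoring"])
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        self.kinship.to_csv(paths["kinship"], sep="\t", index=False)
        self.ancestry.to_csv(paths["ancestry"], sep="\t", index=False)
        truth = {
            "alpha": self.truth.alpha,
            "gamma": self.truth.gamma,
            "raw_mu": self.truth.raw_mu,
            "raw_sd": self.truth.raw_sd,
            "sample_ids": self.truth.sample_ids,
            "z_true": self.truth.z_true.tolist(),
            "status": self.truth.status.tolist(),
            "pedigree_edges": self.truth.pedigree_edges,
        }
        paths["truth"].write_text(json.dumps(truth))
        return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# variant model
# ---------------------------------------------------------------------------

@dataclass
class _VariantModel:
    scoring: ScoringFile
    sites: list[VariantSite]
    P: np.ndarray            # 4 x m per-ancestry ALT allele frequencies
    signed_beta: np.ndarray  # beta on the ALT-dosage scale
    const: np.ndarray        # additive constant from effect-is-ref variants
    raw_mu: float
    raw_sd: float


def _draw_variant_model(cfg: SimulationConfig, rng: np.random.Generator) -> _VariantModel:
    m = cfg.n_variants
    lo, hi = cfg.ancestral_af_range
    p_anc = rng.uniform(lo, hi, size=m)
    P = np.empty((4, m))
    for k, f in enumerate(cfg.fst):
        if f <= 0:
            P[k] = p_anc
        else:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            P[k] = rng.beta(a, b)
    P = np.clip(P, 0.01, 0.99)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    effect_is_alt = rng.random(m) < 0.5
    betas = rng.normal(0.0, cfg.beta_sd, size=m)
    betas[betas == 0.0] = cfg.beta_sd  # exact zeros would be null-beta drops

    chroms = [str(1 + i % 22) for i in range(m)]
    pos = [100_000 + 1_500 * (i // 22) for i in range(m)]
    sites, variants = [], []
    for i in range(m):
        ref, alt = _ALLELE_PAIRS[pair_idx[i]]
        sites.append(VariantSite(chroms[i], pos[i], ref, alt))
        eff, oth = (alt, ref) if effect_is_alt[i] else (ref, alt)
        variants.append(ScoringVariant(
            variant_id=f"rs{900000 + i}", chrom=chroms[i], pos=pos[i],
            effect_allele=eff, other_allele=oth, beta=float(betas[i]),
        ))
    scoring = ScoringFile(prs_name=cfg.prs_name, variants=variants,
                          provenance="synthetic")

    sign = np.where(effect_is_alt, 1.0, -1.0)
    c = betas * sign
    const = 2.0 * betas[~effect_is_alt].sum()

    mu_q, cov_q = _admixture_moments(cfg)
    ep = mu_q @ P                                  # E[p_i]
    var_p = np.einsum("ki,kl,li->i", P, cov_q, P)  # Var(p_i)
    ep1p = ep - (var_p + ep**2)                    # E[p(1-p)]
    mu_raw = 2.0 * c @ ep + const
    pc = P @ c
    var_raw = 2.0 * (c**2) @ ep1p + 4.0 * pc @ cov_q @ pc
    return _VariantModel(scoring=scoring, sites=sites, P=P, signed_beta=c,
                         const=const, raw_mu=float(mu_raw),
                         raw_sd=float(np.sqrt(var_raw)))


def _admixture_moments(cfg: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean and covariance of q under the two-component Dirichlet mixture."""
    comps = [(1.0 - cfg.eas_fraction, np.asarray(cfg.dirichlet_alpha, float))]
    if cfg.eas_fraction > 0:
        comps.append((cfg.eas_fraction, np.asarray(cfg.eas_dirichlet_alpha, float)))
    mu = np.zeros(4)
    second = np.zeros((4, 4))
    for w, a in comps:
        a0 = a.sum()
        m = a / a0
        cov = (np.diag(m) - np.outer(m, m)) / (a0 + 1.0)
        mu += w * m
        second += w * (cov + np.outer(m, m))
    return mu, second - np.outer(mu, mu)


def _draw_admixture(cfg: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    q = rng.dirichlet(cfg.dirichlet_alpha, size=n)
    if cfg.eas_fraction > 0:
        mask = rng.random(n) < cfg.eas_fraction
        n_eas = int(mask.sum())
        if n_eas:
            q[mask] = rng.dirichlet(cfg.eas_dirichlet_alpha, size=n_eas)
    return q


def _carrier_logit(flags: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    log_ors = np.log([or_ for _, or_ in cfg.carrier_spec.values()])
    return flags @ log_ors


def _solve_alpha(cfg: SimulationConfig, model: _VariantModel,
                 rng: np.random.Generator, n_pilot: int = 8000) -> float:
    """Bisection for the liability intercept hitting the target prevalence."""
    q = _draw_admixture(cfg, rng, n_pilot)
    G = rng.binomial(2, q @ model.P).astype(np.int8)
    z = (G @ model.signed_beta + model.const - model.raw_mu) / model.raw_sd
    flags = rng.random((n_pilot, len(cfg.carrier_spec))) < np.array(
        [f for f, _ in cfg.carrier_spec.values()])
    lp = cfg.gamma * z + _carrier_logit(flags, cfg)

    def objective(alpha: float) -> float:
        return float(expit(alpha + lp).mean() - cfg.prevalence)

    try:
        return brentq(objective, -30.0, 10.0, xtol=1e-6)
    except ValueError as exc:
        raise SimulationError(
            f"target prevalence {cfg.prevalence} unattainable: {exc}") from exc


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimulationConfig, seed: int) -> SimulatedCohort:
    """Generate a full admixed case-control cohort with ground truth.

    Unrelated individuals are drawn from the liability model and sampled
    down to ``n_cases`` cases and ``n_controls`` controls (simulated in
    chunks, so arbitrarily low prevalences only cost time, not memory).
    Family clusters are appended afterwards, so the cohort QC stage has
    first-degree structure to prune; family members' statuses follow the
    same disease model.
    """
    rng = np.random.default_rng(seed)
    model = _draw_variant_model(cfg, rng)
    gene_freqs = np.array([f for f, _ in cfg.carrier_spec.values()])
    alpha = _solve_alpha(cfg, model, rng)

    need = {1: cfg.n_cases, 0: cfg.n_controls}
    kept: dict[str, list] = {"G": [], "q": [], "z": [], "flags": [], "status": [],
                             "lp": []}
    max_draws = max(500_000, int(40 * (cfg.n_cases / cfg.prevalence
                                       + cfg.n_controls / (1 - cfg.prevalence))))
    drawn = 0
    while (need[1] > 0 or need[0] > 0) and drawn < max_draws:
        n = min(cfg.chunk_size, max_draws - drawn)
        drawn += n
        q = _draw_admixture(cfg, rng, n)
        G = rng.binomial(2, q @ model.P).astype(np.int8)
        z = (G @ model.signed_beta + model.const - model.raw_mu) / model.raw_sd
        flags = rng.random((n, len(gene_freqs))) < gene_freqs
        lp = alpha + cfg.gamma * z + _carrier_logit(flags, cfg)
        status = (rng.random(n) < expit(lp)).astype(np.int8)
        for s in (1, 0):
            if need[s] <= 0:
                continue
            idx = np.flatnonzero(status == s)[: need[s]]
            need[s] -= len(idx)
            kept["G"].append(G[idx])
            kept["q"].append(q[idx])
            kept["z"].append(z[idx])
            kept["flags"].append(flags[idx])
            kept["lp"].append(lp[idx])
            kept["status"].append(status[idx])
    if need[1] > 0 or need[0] > 0:
        raise SimulationError(
            f"could not collect requested cases/controls within {max_draws} draws "
            f"(prevalence {cfg.prevalence} too extreme for the liability model)")

    G = np.concatenate(kept["G"])
    q = np.concatenate(kept["q"])
    z = np.concatenate(kept["z"])
    flags = np.concatenate(kept["flags"])
    lp = np.concatenate(kept["lp"])
    status = np.concatenate(kept["status"])
    ids = [f"S{i:06d}" for i in range(len(status))]
    pedigree: list[tuple[str, str]] = []

    if cfg.n_families > 0:
        fam = simulate_families(cfg, model, alpha, rng)
        G = np.concatenate([G, fam["G"]])
        q = np.concatenate([q, fam["q"]])
        z = np.concatenate([z, fam["z"]])
        flags = np.concatenate([flags, fam["flags"]])
        lp = np.concatenate([lp, fam["lp"]])
        status = np.concatenate([status, fam["status"]])
        ids.extend(fam["ids"])
        pedigree = fam["edges"]

    n_total = len(ids)
    # demographics: cases are all women; controls are a mixed clinical pool
    is_case = status == 1
    sex = np.where(is_case, "female",
                   np.where(rng.random(n_total) < 0.48, "female", "male"))
    age = np.where(is_case, rng.normal(49.8, 11.6, n_total),
                   rng.normal(41.6, 13.3, n_total)).round(1)
    age = np.clip(age, 18, 95)

    genotypes = GenotypeMatrix(samples=ids, sites=model.sites,
                               dosages=G.astype(np.float32))
    carrier_df = pd.DataFrame(flags.astype(int), columns=list(cfg.carrier_spec))
    metadata = pd.DataFrame({
        "sample_id": ids,
        "status": np.where(is_case, "case", "control"),
        "sex": sex,
        "age": age,
    })
    metadata = pd.concat([metadata, carrier_df], axis=1)
    ancestry = pd.DataFrame(np.round(q, 4), columns=list(ANCESTRIES))
    ancestry.insert(0, "sample_id", ids)
    kinship = pd.DataFrame(pedigree, columns=["sample_a", "sample_b"])
    kinship["degree"] = 1

    truth = TruthSet(
        sample_ids=ids, q=q, z_true=z, liability=lp, status=status.astype(int),
        carrier_flags=pd.DataFrame(flags, columns=list(cfg.carrier_spec)),
        pedigree_edges=pedigree, ancestral_afs=model.P, alpha=alpha,
        raw_mu=model.raw_mu, raw_sd=model.raw_sd, gamma=cfg.gamma,
    )
    return SimulatedCohort(config=cfg, scoring=model.scoring, genotypes=genotypes,
                           metadata=metadata, kinship=kinship, ancestry=ancestry,
                           truth=truth)


def simulate_families(cfg: SimulationConfig, model: _VariantModel, alpha: float,
                      rng: np.random.Generator) -> dict:
    """First-degree family clusters: alternating parent-child pairs and trios.

    Parents are drawn from the admixture model; each offspring receives one
    Mendelian allele per parent per variant (child ALT count =
    Bernoulli(g_mother/2) + Bernoulli(g_father/2)).  Even-numbered families
    contribute a parent-child pair to the cohort, odd-numbered families a
    full trio (the trio's child has two first-degree links, so relatedness
    pruning must remove the whole cluster).  With ``family_offspring`` > 1,
    sibling pairs and their degree-1 edges are included too.
    """
    rows_G, rows_q, ids, edges = [], [], [], []
    for f in range(cfg.n_families):
        qp = _draw_admixture(cfg, rng, 2)
        gp = rng.binomial(2, qp @ model.P).astype(np.int8)
        children_G, children_q = [], []
        for _ in range(cfg.family_offspring):
            gc = (rng.binomial(1, gp[0] / 2.0) + rng.binomial(1, gp[1] / 2.0))
            children_G.append(gc.astype(np.int8))
            children_q.append((qp[0] + qp[1]) / 2.0)
        trio = f % 2 == 1
        fam_ids = [f"F{f:04d}_P0"] + ([f"F{f:04d}_P1"] if trio else [])
        member_G = [gp[0]] + ([gp[1]] if trio else [])
        member_q = [qp[0]] + ([qp[1]] if trio else [])
        for ci in range(cfg.family_offspring):
            cid = f"F{f:04d}_C{ci}"
            fam_ids.append(cid)
            member_G.append(children_G[ci])
            member_q.append(children_q[ci])
            edges.append((f"F{f:04d}_P0", cid))
            if trio:
                edges.append((f"F{f:04d}_P1", cid))
        # full-sib edges among included offspring
        for i in range(cfg.family_offspring):
            for j in range(i + 1, cfg.family_offspring):
                edges.append((f"F{f:04d}_C{i}", f"F{f:04d}_C{j}"))
        ids.extend(fam_ids)
        rows_G.extend(member_G)
        rows_q.extend(member_q)

    G = np.asarray(rows_G, dtype=np.int8)
    q = np.asarray(rows_q, dtype=float)
    z = (G @ model.signed_beta + model.const - model.raw_mu) / model.raw_sd
    gene_freqs = np.array([fr for fr, _ in cfg.carrier_spec.values()])
    flags = rng.random((len(ids), len(gene_freqs))) < gene_freqs
    lp = alpha + cfg.gamma * z + _carrier_logit(flags, cfg)
    status = (rng.random(len(ids)) < expit(lp)).astype(np.int8)
    return {"ids": ids, "G": G, "q": q, "z": z, "flags": flags, "lp": lp,
            "status": status, "edges": edges}


def simulate_family_set(cfg: SimulationConfig, seed: int) -> tuple[pd.DataFrame, GenotypeMatrix, dict]:
    """Standalone family generator: kinship table + member genotypes.

    Draws its own variant model and liability intercept, then delegates to
    :func:`simulate_families`.  Returns ``(kinship_df, genotypes, raw)``
    where ``raw`` is the full per-member dict (ids, G, q, z, flags, status,
    edges).
    """
    rng = np.random.default_rng(seed)
    model = _draw_variant_model(cfg, rng)
    alpha = _solve_alpha(cfg, model, rng)
    fam = simulate_families(cfg, model, alpha, rng)
    fam["ancestral_afs"] = model.P
    kin = pd.DataFrame(fam["edges"], columns=["sample_a", "sample_b"])
    kin["degree"] = 1
    geno = GenotypeMatrix(samples=fam["ids"], sites=model.sites,
                          dosages=fam["G"].astype(np.float32))
    return kin, geno, fam


# ---------------------------------------------------------------------------
# imputation noise
# ---------------------------------------------------------------------------

def add_imputation_noise(
    genotypes: GenotypeMatrix,
    site_afs: np.ndarray,
    scoring: ScoringFile,
    epsilon: float | None = None,
    target_rho: float | None = None,
    seed: int = 0,
    tol: float = 0.005,
    max_iter: int = 40,
) -> tuple[GenotypeMatrix, float, float]:
    """Corrupt genotypes with imputation-style noise.

    With probability ``epsilon`` a genotype is replaced by a fresh
    Binomial(2, p) draw from that sample's individual allele frequency
    ``site_afs`` (per-variant vector or full n x m matrix).  When
    ``target_rho`` is given instead, ``epsilon`` is found by monotone
    bisection on the Spearman correlation between clean and noisy PRS
    (common random draws across iterations, so rho is exactly monotone in
    epsilon).  Returns ``(noisy_genotypes, epsilon_used, achieved_rho)``.
    """
    if (epsilon is None) == (target_rho is None):
        raise ValueError("give exactly one of epsilon or target_rho")
    rng = np.random.default_rng(seed)
    G = genotypes.dosages.astype(np.float32)
    n, m = G.shape
    p = np.broadcast_to(np.asarray(site_afs, dtype=float), (n, m))
    U = rng.random((n, m), dtype=np.float32)
    R = rng.binomial(2, p).astype(np.float32)

    matched = score_engine.match_alleles(scoring, genotypes)
    used = [mv for mv in matched
            if mv.orientation is not score_engine.Orientation.EXCLUDED]
    if not used:
        raise ValueError("no usable scoring variants to calibrate against")
    c = np.zeros(m)
    for mv in used:
        beta = scoring.variants[mv.scoring_index].beta
        sign = 1.0 if mv.orientation is score_engine.Orientation.EFFECT_IS_ALT else -1.0
        c[mv.genotype_column] = beta * sign
    raw0 = G @ c

    def noisy_at(eps: float) -> np.ndarray:
        return np.where(U < eps, R, G)

    def rho_at(eps: float) -> float:
        return compare_scores(raw0, noisy_at(eps) @ c).spearman_rho

    if epsilon is not None:
        eps = float(epsilon)
        achieved = rho_at(eps)
    else:
        lo, hi = 0.0, 1.0
        rho_lo, rho_hi = 1.0, rho_at(1.0)
        if not rho_hi <= target_rho <= rho_lo:
            raise ValueError(
                f"target rho {target_rho} outside achievable range "
                f"[{rho_hi:.3f}, 1.0]")
        eps, achieved = 0.5, rho_at(0.5)
        for _ in range(max_iter):
            if abs(achieved - target_rho) <= tol:
                break
            if achieved > target_rho:
                lo = eps
            else:
                hi = eps
            eps = (lo + hi) / 2.0
            achieved = rho_at(eps)

    noisy = GenotypeMatrix(samples=list(genotypes.samples),
                           sites=list(genotypes.sites),
                           dosages=noisy_at(eps))
    return noisy, float(eps), float(achieved)
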