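"""Variant filtering, allele matching and PRS computation.

The score of sample *s* is the weighted allele count

    raw_s = sum_i beta_i * d_si

with ``d_si`` the dosage of variant *i*'s effect allele (``2 - alt_dosage``
when the effect allele is the VCF REF).  The raw sum is min-max normalized
over its diploid bounds so it ranges over [0, 1]:

    normalized = (raw - 2*sum(beta<0)) / (2*sum(beta>0) - 2*sum(beta<0))

and finally standardized to a z-score against the control distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .formats_io import GenotypeMatrix, ScoringFile, ScoringVariant

AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))


class ScoringError(ValueError):
    """No usable variants or a degenerate score distribution."""


class Orientation(str, Enum):
    EFFECT_IS_ALT = "effect-is-alt"
    EFFECT_IS_REF = "effect-is-ref"
    EXCLUDED = "excluded"


#: allowed exclusion reasons for matched variants and the drop ledger
EXCLUSION_REASONS = (
    "ambiguous-strand", "allele-mismatch", "not-found",
    "maf-filtered", "off-target", "null-beta", "exclusion-list",
)


@dataclass(frozen=True)
class MatchedVariant:
    """Resolution of one scoring variant against the genotype matrix."""

    scoring_index: int
    genotype_column: int | None
    orientation: Orientation
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.orientation is Orientation.EXCLUDED and self.reason not in EXCLUSION_REASONS:
            raise ValueError(f"invalid exclusion reason {self.reason!r}")


@dataclass
class ScoreSet:
    """Raw, normalized and control-standardized PRS values per sample."""

    sample_ids: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    standardized: np.ndarray
    n_variants_used: int

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "raw": self.raw,
            "normalized": self.normalized,
            "standardized": self.standardized,
            "n_variants_used": self.n_variants_used,
        })


# ---------------------------------------------------------------------------
# scoring-variant filters
# ---------------------------------------------------------------------------

def _distance_to_targets(variant: ScoringVariant, targets: dict[str, np.ndarray]) -> float:
    """bp distance from a 1-based variant position to the nearest target base."""
    ivals = targets.get(variant.chrom)
    if ivals is None or len(ivals) == 0:
        return np.inf
    v = variant.pos - 1  # 0-based coordinate
    starts, ends = ivals[:, 0], ivals[:, 1]
    j = np.searchsorted(starts, v, side="right") - 1
    dist = np.inf
    if j >= 0:
        if v < ends[j]:
            return 0.0
        dist = v - (ends[j] - 1)
    if j + 1 < len(starts):
        dist = min(dist, starts[j + 1] - v)
    return float(dist)


def filter_scoring_variants(
    scoring: ScoringFile,
    targets: dict[str, np.ndarray] | None = None,
    max_distance_bp: int = 200,
    maf: dict | None = None,
    maf_min: float = 0.001,
    exclusion_ids: set[str] | None = None,
) -> tuple[ScoringFile, dict[str, int]]:
    """Drop unscorable variants, returning the kept file and a drop ledger.

    Applied in order per variant: zero effect weight (``null-beta``),
    explicit exclusion list (e.g. a pathogenic variant conflating monogenic
    risk, ``exclusion-list``), distance from the exome target regions
    beyond ``max_distance_bp`` (``off-target``), and cohort minor allele
    frequency below ``maf_min`` (``maf-filtered``).  ``maf`` maps variant_id
    or variant key to MAF; variants absent from the map pass the MAF filter.
    """
    if max_distance_bp < 0:
        raise ValueError("max_distance_bp must be >= 0")
    exclusion_ids = exclusion_ids or set()
    kept: list[ScoringVariant] = []
    drops = {r: 0 for r in ("null-beta", "exclusion-list", "off-target", "maf-filtered")}
    for v in scoring.variants:
        if v.beta == 0.0:
            drops["null-beta"] += 1
            continue
        if v.variant_id in exclusion_ids:
            drops["exclusion-list"] += 1
            continue
        if targets is not None and _distance_to_targets(v, targets) > max_distance_bp:
            drops["off-target"] += 1
            continue
        if maf is not None:
            f = maf.get(v.variant_id, maf.get(v.key))
            if f is not None and f < maf_min:
                drops["maf-filtered"] += 1
                continue
        kept.append(v)
    if not kept:
        raise ScoringError("no scorable variants after filtering")
    out = ScoringFile(prs_name=scoring.prs_name, variants=kept,
                      provenance=scoring.provenance)
    return out, drops


# ---------------------------------------------------------------------------
# allele matching
# ---------------------------------------------------------------------------

def match_alleles(
    scoring: ScoringFile,
    genotypes: GenotypeMatrix,
    allow_ambiguous: bool = False,
) -> list[MatchedVariant]:
    """Orient every scoring variant against the VCF REF/ALT of its site.

    A/T and C/G pairs are strand-ambiguous and excluded unless
    ``allow_ambiguous``.  Exclusions are data, not failures: every scoring
    variant yields exactly one :class:`MatchedVariant`.
    """
    site_index = {(s.chrom, s.pos, frozenset((s.ref, s.alt))): j
                  for j, s in enumerate(genotypes.sites)}
    out: list[MatchedVariant] = []
    for i, v in enumerate(scoring.variants):
        pair = frozenset((v.effect_allele, v.other_allele))
        j = site_index.get((v.chrom, v.pos, pair))
        if j is None:
            out.append(MatchedVariant(i, None, Orientation.EXCLUDED, "not-found"))
            continue
        if not allow_ambiguous and pair in AMBIGUOUS_PAIRS:
            out.append(MatchedVariant(i, None, Orientation.EXCLUDED, "ambiguous-strand"))
            continue
        site = genotypes.sites[j]
        if v.effect_allele == site.alt and v.other_allele == site.ref:
            out.append(MatchedVariant(i, j, Orientation.EFFECT_IS_ALT))
        elif v.effect_allele == site.ref and v.other_allele == site.alt:
            out.append(MatchedVariant(i, j, Orientation.EFFECT_IS_REF))
        else:
            out.append(MatchedVariant(i, j, Orientation.EXCLUDED, "allele-mismatch"))
    return out


# ---------------------------------------------------------------------------
# score computation
# ---------------------------------------------------------------------------

def effect_dosages(
    matched: list[MatchedVariant],
    scoring: ScoringFile,
    genotypes: GenotypeMatrix,
    eaf: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Effect-allele dosage matrix for the usable matched variants.

    Returns ``(D, betas)`` with D of shape (n_samples, n_used), missing
    dosages mean-imputed with twice the effect-allele frequency (supplied
    per usable variant via ``eaf``, else estimated from non-missing cohort
    dosages), and everything clamped to [0, 2].
    """
    used = [m for m in matched if m.orientation is not Orientation.EXCLUDED]
    if not used:
        raise ScoringError("no usable matched variants")
    cols = np.array([m.genotype_column for m in used])
    flip = np.array([m.orientation is Orientation.EFFECT_IS_REF for m in used])
    D = genotypes.dosages[:, cols].astype(np.float64)
    D[:, flip] = 2.0 - D[:, flip]
    if eaf is None:
        with np.errstate(invalid="ignore"):
            eaf = np.nanmean(D, axis=0) / 2.0
        eaf = np.where(np.isfinite(eaf), eaf, 0.0)
    fill = np.broadcast_to(2.0 * np.asarray(eaf, dtype=float), D.shape)
    D = np.where(np.isnan(D), fill, D)
    D = np.clip(D, 0.0, 2.0)
    betas = np.array([scoring.variants[m.scoring_index].beta for m in used])
    return D, betas


def normalization_bounds(betas: np.ndarray) -> tuple[float, float]:
    """Diploid min/max of the raw weighted sum: (2*sum(b<0), 2*sum(b>0))."""
    lo = 2.0 * betas[betas < 0].sum()
    hi = 2.0 * betas[betas > 0].sum()
    return float(lo), float(hi)


def compute_scores(
    matched: list[MatchedVariant],
    scoring: ScoringFile,
    genotypes: GenotypeMatrix,
    controls: set[str],
    eaf: np.ndarray | None = None,
) -> ScoreSet:
    """Raw, zero-to-one normalized and control-standardized PRS per sample.

    ``controls`` names the samples whose normalized-score mean and SD
    define the z-standardization; by construction the standardized controls
    have mean 0 and SD 1 exactly.
    """
    D, betas = effect_dosages(matched, scoring, genotypes, eaf=eaf)
    raw = D @ betas
    lo, hi = normalization_bounds(betas)
    if hi - lo <= 0:
        raise ScoringError("degenerate normalization range (no nonzero betas)")
    normalized = (raw - lo) / (hi - lo)

    is_control = np.array([s in controls for s in genotypes.samples])
    if not is_control.any():
        raise ScoringError("no control samples for standardization")
    mu = normalized[is_control].mean()
    sd = normalized[is_control].std(ddof=0)
    if sd == 0:
        raise ScoringError("control score SD is zero; cannot standardize")
    standardized = (normalized - mu) / sd
    return ScoreSet(
        sample_ids=list(genotypes.samples),
        raw=raw,
        normalized=normalized,
        standardized=standardized,
        n_variants_used=len(betas),
    )
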