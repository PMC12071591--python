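"""Effect-size and classification statistics for PRS validation.

Covers: PC-adjusted logistic OR per SD of the control-standardized score;
decile / percentile segmentation ORs against the 40-60% median interval;
closed-form 2x2 carrier ORs with Wald CIs (Haldane-Anscombe corrected on
zero cells); AUC on a stratified holdout split and by stratified 10-fold
cross-validation; and Bonferroni multiplicity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .covariates_pca import PCSet

Z975 = stats.norm.ppf(0.975)

#: percentile-scheme bin edges (%), following the original PRS validation layout
PERCENTILE_EDGES = (0, 1, 5, 10, 20, 40, 60, 80, 90, 95, 99, 100)


class SeparationError(RuntimeError):
    """Logistic fit failed to converge or the outcome is perfectly separated."""


@dataclass
class AssociationResult:
    """One fitted contrast: odds ratio, 95% CI, p-value and diagnostics."""

    contrast: str
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    n_case: int
    n_control: int
    covariates: list[str] = field(default_factory=list)
    pseudo_r2: dict | None = None
    corrected: bool = False  # Haldane-Anscombe zero-cell correction applied

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_ <= self.ci_high):
            raise ValueError("CI must bracket the OR")
        if self.or_ <= 0:
            raise ValueError("OR must be positive")

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast, "or": self.or_,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value, "n_case": self.n_case,
            "n_control": self.n_control, "covariates": list(self.covariates),
            "pseudo_r2": self.pseudo_r2, "corrected": self.corrected,
        }


@dataclass
class BinPartition:
    """Left-open right-closed score bins with a reference (median) interval."""

    kind: str                 # "decile" | "percentile-scheme"
    boundaries: np.ndarray    # ascending interior cutpoints
    assignment: np.ndarray    # sample -> bin index
    reference_bins: frozenset

    def __post_init__(self) -> None:
        if not self.reference_bins:
            raise ValueError("reference_bins must be non-empty")
        if np.any(np.diff(self.boundaries) < 0):
            raise ValueError("boundaries must be ascending")

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) + 1

    def bin_counts(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_bins)


# ---------------------------------------------------------------------------
# logistic machinery
# ---------------------------------------------------------------------------

def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Newton ML fit with explicit separation/convergence diagnostics."""
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            model = sm.Logit(y, X)
            res = model.fit(disp=0, maxiter=100)
    except PerfectSeparationWarning as exc:
        raise SeparationError(f"perfect separation detected: {exc}") from exc
    except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge")
    if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 30):
        raise SeparationError("degenerate logistic fit (separation suspected)")
    return res


def _status_array(status) -> np.ndarray:
    arr = np.asarray(status)
    if arr.dtype.kind in "USO":
        arr = (arr == "case").astype(int)
    arr = arr.astype(int)
    if not set(np.unique(arr)) <= {0, 1}:
        raise ValueError("status must be case/control or 0/1")
    return arr


def or_per_sd(
    scores: np.ndarray,
    status,
    pcs: PCSet | None = None,
    contrast: str = "per-SD",
) -> AssociationResult:
    """Logistic OR per SD of the (control-standardized) score.

    Fits status ~ score + z-scored PCs 1..K by maximum likelihood and
    reports exp(score coefficient) with its Wald 95% CI and two-tailed
    Wald p, plus Nagelkerke (headline) and McFadden pseudo-R².
    """
    y = _status_array(status)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    scores = np.asarray(scores, dtype=float)
    cols = [np.ones_like(scores), scores]
    names = ["const", "score"]
    if pcs is not None:
        cols.extend(pcs.pcs.T)
        names.extend(f"PC{i+1}" for i in range(pcs.k))
    X = np.column_stack(cols)
    res = _fit_logit(y, X)
    b, se = res.params[1], res.bse[1]
    n = len(y)
    ll, ll0 = res.llf, res.llnull
    nagelkerke = (1 - np.exp(2 * (ll0 - ll) / n)) / (1 - np.exp(2 * ll0 / n))
    return AssociationResult(
        contrast=contrast,
        or_=float(np.exp(b)),
        ci_low=float(np.exp(b - Z975 * se)),
        ci_high=float(np.exp(b + Z975 * se)),
        p_value=float(res.pvalues[1]),
        n_case=int(y.sum()),
        n_control=int(n - y.sum()),
        covariates=names[2:],
        pseudo_r2={"nagelkerke": float(nagelkerke), "mcfadden": float(res.prsquared)},
    )


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def make_bins(
    scores: np.ndarray,
    kind: str = "decile",
    boundary_source: str = "control-only",
    status=None,
) -> BinPartition:
    """Assign samples to decile or percentile-scheme bins.

    Boundaries are quantiles of the ``boundary_source`` scores (controls
    by default, matching control-standardization; ``all-samples``
    optional).  Intervals are left-open right-closed: a score equal to a
    boundary falls in the lower bin.  Reference bins span the 40-60%
    median interval.
    """
    scores = np.asarray(scores, dtype=float)
    if boundary_source == "control-only":
        if status is None:
            raise ValueError("control-only boundaries require status")
        base = scores[_status_array(status) == 0]
    elif boundary_source == "all-samples":
        base = scores
    else:
        raise ValueError(f"unknown boundary_source {boundary_source!r}")

    if kind == "decile":
        qs = np.arange(0.1, 1.0, 0.1)
        reference = frozenset({4, 5})          # (40,50] and (50,60]
    elif kind == "percentile-scheme":
        qs = np.asarray(PERCENTILE_EDGES[1:-1]) / 100.0
        reference = frozenset({5})             # the (40,60] bin
    else:
        raise ValueError(f"unknown bin kind {kind!r}")
    boundaries = np.quantile(base, qs)
    assignment = np.searchsorted(boundaries, scores, side="left")
    return BinPartition(kind=kind, boundaries=boundaries,
                        assignment=assignment, reference_bins=reference)


def bin_or(
    partition: BinPartition,
    bin_index: int,
    status,
    pcs: PCSet | None = None,
) -> AssociationResult:
    """OR of one score bin versus the median reference interval.

    Subsets to target-bin plus reference-bin samples, then fits a logistic
    model of status on bin membership (1 = in target bin, 0 = in reference)
    with PC covariates.  Comparing the reference against itself returns OR
    exactly 1 (degenerate self-contrast).
    """
    y_all = _status_array(status)
    target = partition.assignment == bin_index
    in_ref = np.isin(partition.assignment, list(partition.reference_bins))
    label = f"{partition.kind}-bin{bin_index}-vs-ref"
    if bin_index in partition.reference_bins:
        n_case = int(y_all[in_ref].sum())
        return AssociationResult(contrast=label, or_=1.0, ci_low=1.0, ci_high=1.0,
                                 p_value=1.0, n_case=n_case,
                                 n_control=int(in_ref.sum() - n_case))
    mask = target | in_ref
    y = y_all[mask]
    member = target[mask].astype(float)
    cols = [np.ones_like(member), member]
    names = ["const", "membership"]
    if pcs is not None:
        cols.extend(pcs.pcs[mask].T)
        names.extend(f"PC{i+1}" for i in range(pcs.k))
    res = _fit_logit(y, np.column_stack(cols))
    b, se = res.params[1], res.bse[1]
    return AssociationResult(
        contrast=label,
        or_=float(np.exp(b)),
        ci_low=float(np.exp(b - Z975 * se)),
        ci_high=float(np.exp(b + Z975 * se)),
        p_value=float(res.pvalues[1]),
        n_case=int(y.sum()),
        n_control=int(len(y) - y.sum()),
        covariates=names[2:],
    )


def staircase(
    partition: BinPartition,
    status,
    pcs: PCSet | None = None,
) -> list[AssociationResult]:
    """Per-bin ORs against the reference interval, in bin order."""
    return [bin_or(partition, b, status, pcs) for b in range(partition.n_bins)]


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

def two_by_two_or(exposed, status, contrast: str = "exposure") -> AssociationResult:
    """Closed-form OR with Wald CI from the exposure-by-status 2x2 table.

    With a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls: OR = (a*d)/(b*c) and
    CI = exp(ln OR +/- 1.96*sqrt(1/a+1/b+1/c+1/d)).  A zero cell triggers
    the Haldane-Anscombe +0.5 correction, flagged in the result.
    """
    e = np.asarray(exposed).astype(bool)
    y = _status_array(status).astype(bool)
    a = int(np.sum(e & y))
    b = int(np.sum(e & ~y))
    c = int(np.sum(~e & y))
    d = int(np.sum(~e & ~y))
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = ((x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d))
    log_or = np.log(aa * dd / (bb * cc))
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = log_or / se
    return AssociationResult(
        contrast=contrast,
        or_=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z975 * se)),
        ci_high=float(np.exp(log_or + Z975 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        n_case=a + c,
        n_control=b + d,
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def auc_holdout(scores, status, test_fraction: float = 0.25, seed: int = 0) -> float:
    """AUC of the score on a stratified held-out fraction of the cohort."""
    y = _status_array(status)
    idx = np.arange(len(y))
    _, test_idx = train_test_split(idx, test_size=test_fraction,
                                   stratify=y, random_state=seed)
    return float(roc_auc_score(y[test_idx], np.asarray(scores)[test_idx]))


def auc_cv(scores, status, folds: int = 10, seed: int = 0) -> tuple[float, np.ndarray]:
    """Mean and per-fold AUC under stratified k-fold cross-validation."""
    y = _status_array(status)
    scores = np.asarray(scores, dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = np.array([
        roc_auc_score(y[test], scores[test]) for _, test in skf.split(scores, y)
    ])
    return float(per_fold.mean()), per_fold


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m*p)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)
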