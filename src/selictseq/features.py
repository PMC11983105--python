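"""Binding-site feature extraction and ridge regression of edit
determinants.

For each classified off-target site, mismatch and gap counts are taken
over protospacer coordinates (position 1 PAM-distal): the first 5 bp and
first 8 bp capture the PAM-distal end, the seed region (PAM-proximal
positions 11-20 by default) captures tolerance close to the PAM, and the
alignment totals include the PAM columns.  The regression is a linear
probability model: a binary outcome (out-of-protospacer edit present, or
target-strand edit present) against the nine counts, fitted with an L2
penalty on standardized predictors.

Coefficient significance uses the analytic sandwich variance of the
ridge estimator,

    Var(b) = sigma^2 (X'X + lam I)^-1 X'X (X'X + lam I)^-1,

with sigma^2 estimated from residuals on effective degrees of freedom
n - tr(H), and two-sided Student's t p-values.  A permutation mode is
available as a cross-check.  When no penalty is fixed, lambda is chosen
by generalized cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .offtarget import OffTargetCall, PROTOSPACER_LEN

logger = logging.getLogger("selictseq")

FEATURE_NAMES = [
    "first8_mismatch", "first5_mismatch", "first8_gap", "first5_gap",
    "align_mismatch", "align_gap", "seed_mismatch", "seed_gap", "pam_type",
]


@dataclass
class FeatureVector:
    first8_mismatch: int
    first5_mismatch: int
    first8_gap: int
    first5_gap: int
    align_mismatch: int
    align_gap: int
    seed_mismatch: int
    seed_gap: int
    pam_type: int  # 1 = canonical NRG
    outcome: int | None = None

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def extract_features(
    call: OffTargetCall,
    seed_region: tuple[int, int] = (11, 20),
    outcome: str = "out_of_protospacer",
) -> FeatureVector:
    """Feature vector for one call; requires a binding site.

    ``outcome`` selects the modelled response: ``out_of_protospacer`` or
    ``target_strand``.
    """
    binding = call.binding
    if binding is None:
        raise ValueError("call has no binding site; features undefined")
    mismatches = binding.mismatch_positions
    gaps = tuple(binding.target_bulges) + tuple(binding.dna_bulges)
    lo, hi = seed_region
    if outcome == "out_of_protospacer":
        y = int(call.out_of_protospacer)
    elif outcome == "target_strand":
        y = int(call.edit_strand == "target_strand")
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    return FeatureVector(
        first8_mismatch=sum(1 for p in mismatches if p <= 8),
        first5_mismatch=sum(1 for p in mismatches if p <= 5),
        first8_gap=sum(1 for p in gaps if p <= 8),
        first5_gap=sum(1 for p in gaps if p <= 5),
        align_mismatch=len(mismatches) + binding.pam_mismatches,
        align_gap=len(gaps),
        seed_mismatch=sum(1 for p in mismatches if lo <= p <= hi),
        seed_gap=sum(1 for p in gaps if lo <= p <= hi),
        pam_type=int(binding.pam_canonical),
        outcome=y,
    )


def feature_table(
    calls: list[OffTargetCall],
    seed_region: tuple[int, int] = (11, 20),
    outcome: str = "out_of_protospacer",
) -> pd.DataFrame:
    rows = [
        extract_features(c, seed_region, outcome)
        for c in calls
        if c.binding is not None
    ]
    data = pd.DataFrame([r.as_array() for r in rows], columns=FEATURE_NAMES)
    data["outcome"] = [r.outcome for r in rows]
    return data


@dataclass
class RidgeFit:
    lam: float
    features: list[str]
    coefficients: np.ndarray
    std_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    effective_df: float
    intercept: float
    dropped: list[str]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "se": self.std_errors,
                "t": self.t_statistics,
                "p": self.p_values,
                "significant": self.p_values < 0.01,
            },
            index=self.features,
        )


def _gcv_lambda(Xs: np.ndarray, yc: np.ndarray) -> float:
    """Generalized cross-validation over a log-spaced lambda grid."""
    n = Xs.shape[0]
    U, s, _ = np.linalg.svd(Xs, full_matrices=False)
    Uty = U.T @ yc
    best_lam, best_gcv = 0.0, np.inf
    for lam in np.logspace(-4, 4, 81):
        shrink = s**2 / (s**2 + lam)
        fitted = U @ (shrink * Uty)
        rss = float(((yc - fitted) ** 2).sum())
        edf = float(shrink.sum())
        gcv = (rss / n) / (1 - edf / n) ** 2
        if gcv < best_gcv:
            best_gcv, best_lam = gcv, lam
    return best_lam


def ridge_fit(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    lam: float | None = None,
    feature_names: list[str] | None = None,
) -> RidgeFit:
    """Ridge linear regression with analytic coefficient significance.

    Predictors are standardized (mean 0, unit variance) and the response
    centered, so no intercept enters the penalized solve; constant
    columns are dropped with a warning.  ``lam=None`` selects the penalty
    by generalized cross-validation; ``lam=0`` reproduces ordinary least
    squares on the standardized design.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]
    if n < p:
        raise ValueError(f"n={n} observations < {p} features")

    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = [name for name, k in zip(feature_names, keep) if not k]
    if dropped:
        logger.warning("dropping constant feature columns: %s", dropped)
    X = X[:, keep]
    names = [name for name, k in zip(feature_names, keep) if k]
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    Xs = (X - mu) / sd
    ybar = y.mean()
    yc = y - ybar

    if lam is None:
        lam = _gcv_lambda(Xs, yc)

    XtX = Xs.T @ Xs
    A = XtX + lam * np.eye(Xs.shape[1])
    Ainv = np.linalg.inv(A)
    beta = Ainv @ Xs.T @ yc

    H_trace = float(np.trace(Ainv @ XtX))  # hat-matrix trace (plus 1 for the mean)
    edf = n - H_trace - 1
    resid = yc - Xs @ beta
    sigma2 = float(resid @ resid) / max(edf, 1.0)
    cov = sigma2 * (Ainv @ XtX @ Ainv)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2 * stats.t.sf(np.abs(t), df=max(edf, 1.0))
    return RidgeFit(
        lam=float(lam),
        features=names,
        coefficients=beta,
        std_errors=se,
        t_statistics=t,
        p_values=pvals,
        effective_df=edf,
        intercept=float(ybar),
        dropped=dropped,
    )


def permutation_pvalues(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    lam: float | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p-values for the ridge coefficients (cross-check for
    the analytic t-test): fraction of label permutations whose |beta|
    meets or exceeds the observed one."""
    fit = ridge_fit(X, y, lam=lam)
    rng = np.random.default_rng(seed)
    observed = np.abs(fit.coefficients)
    exceed = np.ones_like(observed)
    y = np.asarray(y, dtype=float)
    for _ in range(n_permutations):
        perm_fit = ridge_fit(X, rng.permutation(y), lam=fit.lam)
        exceed += np.abs(perm_fit.coefficients) >= observed
    return exceed / (n_permutations + 1)
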