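"""Case-control association at the FCGR2/3 locus.

Genotype-category counts are compared between cases and controls with
Fisher's exact test; per-variant effect sizes come from additive logistic
regression of case status on the per-individual allele copy count (0-3;
copy numbers above two contribute their own dose level, no capping).
Joint models (multiple logistic regression with collinearity dropping, and
backward selection) assess which variants are independently associated —
the central question at a locus where strong LD makes several variants tag
one another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .locus_model import IndividualGenotype
from .popgen import fisher_exact_rxc

__all__ = [
    "AssociationResult",
    "fisher_genotype_test",
    "additive_logistic",
    "dose_vector",
    "expand_counts",
    "multiple_logistic",
    "backward_selection",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class AssociationResult:
    variant: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    beta: float
    se: float
    model: str = "single"
    n: int = 0
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must contain the odds ratio")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


# ---------------------------------------------------------------------------
# Fisher exact test on genotype-category counts
# ---------------------------------------------------------------------------

def fisher_genotype_test(
    case_counts: Sequence[int],
    control_counts: Sequence[int],
    *,
    seed: int | None = 0,
) -> float:
    """Exact test of independence for an r x 2 genotype-category table."""
    if len(case_counts) != len(control_counts):
        raise ValueError("case and control count vectors differ in length")
    if len(case_counts) < 2:
        raise ValueError("need at least two genotype categories")
    table = np.column_stack([case_counts, control_counts])
    p, _method = fisher_exact_rxc(table, seed=seed)
    return p


# ---------------------------------------------------------------------------
# Additive logistic regression
# ---------------------------------------------------------------------------

def expand_counts(
    case_counts: Sequence[int],
    control_counts: Sequence[int],
    doses: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Expand per-dose genotype counts into individual (dose, status) arrays."""
    doses = list(range(len(case_counts))) if doses is None else list(doses)
    if len(case_counts) != len(doses) or len(control_counts) != len(doses):
        raise ValueError("counts and doses differ in length")
    x, y = [], []
    for d, c in zip(doses, case_counts):
        x += [d] * int(c)
        y += [1] * int(c)
    for d, c in zip(doses, control_counts):
        x += [d] * int(c)
        y += [0] * int(c)
    return np.asarray(x, float), np.asarray(y, float)


def dose_vector(
    genotypes: Sequence[IndividualGenotype], variant_id: str, allele: str
) -> np.ndarray:
    return np.array([g.dosage(variant_id, allele) for g in genotypes], float)


def _fit_logit(X: np.ndarray, y: np.ndarray):
    model = sm.Logit(y, X)
    try:
        return model.fit(disp=0, method="newton", tol=1e-10, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise ValueError(f"logistic fit failed: {exc}") from exc


def additive_logistic(
    doses: Sequence[float],
    status: Sequence[int],
    variant: str = "",
) -> AssociationResult:
    """Additive-model logistic regression of case status on allele dose.

    Returns the per-copy odds ratio with a Wald 95% CI on the log-odds
    scale and the Wald p-value.
    """
    x = np.asarray(doses, float)
    y = np.asarray(status, float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("doses and status must be equal-length vectors")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if len(np.unique(x)) < 2:
        raise ValueError(f"monomorphic dose vector for {variant or 'variant'}")
    res = _fit_logit(sm.add_constant(x), y)
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge (possible separation)")
    beta, se = float(res.params[1]), float(res.bse[1])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
        raise ValueError("unstable fit: perfect or quasi-perfect separation")
    return AssociationResult(
        variant=variant,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        p_value=float(res.pvalues[1]),
        beta=beta,
        se=se,
        model="single",
        n=len(y),
    )


# ---------------------------------------------------------------------------
# Multiple logistic regression and backward selection
# ---------------------------------------------------------------------------

def _drop_collinear(doses: pd.DataFrame, threshold: float) -> tuple[pd.DataFrame, list[str]]:
    dropped: list[str] = []
    keep: list[str] = []
    for col in doses.columns:
        redundant = False
        for k in keep:
            r = np.corrcoef(doses[col], doses[k])[0, 1]
            if abs(r) > threshold:
                dropped.append(f"{col} (|r|={abs(r):.3f} with {k})")
                redundant = True
                break
        if not redundant:
            keep.append(col)
    return doses[keep], dropped


def multiple_logistic(
    doses: pd.DataFrame,
    status: Sequence[int],
    *,
    corr_threshold: float = 0.95,
    model_tag: str = "multiple",
) -> list[AssociationResult]:
    """Joint logistic fit over several variants' dose columns.

    Columns whose pairwise dose correlation exceeds ``corr_threshold`` with
    an earlier column are dropped (recorded in ``dropped`` on every result),
    mirroring the removal of near-perfect LD proxies from joint models.
    """
    y = np.asarray(status, float)
    if len(doses) != len(y):
        raise ValueError("doses and status differ in length")
    X, dropped = _drop_collinear(doses, corr_threshold)
    if X.shape[1] == 0:
        raise ValueError("no variant columns left after collinearity drops")
    arr = sm.add_constant(np.asarray(X, float))
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError(
            f"design matrix rank-deficient after drops; columns: {list(X.columns)}"
        )
    res = _fit_logit(arr, y)
    out = []
    for j, col in enumerate(X.columns, start=1):
        beta, se = float(res.params[j]), float(res.bse[j])
        out.append(
            AssociationResult(
                variant=col,
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - _Z95 * se)),
                ci_high=float(np.exp(beta + _Z95 * se)),
                p_value=float(res.pvalues[j]),
                beta=beta,
                se=se,
                model=model_tag,
                n=len(y),
                dropped=tuple(dropped),
            )
        )
    return out


def backward_selection(
    doses: pd.DataFrame,
    status: Sequence[int],
    alpha: float = 0.05,
    *,
    corr_threshold: float = 0.95,
) -> list[AssociationResult]:
    """Backward elimination: drop the highest-p variant until all p < alpha.

    Deterministic given column order (ties broken by column order).  Returns
    the results of the final model; an empty list if nothing survives.
    """
    y = np.asarray(status, float)
    X, dropped0 = _drop_collinear(doses, corr_threshold)
    cols = list(X.columns)
    while cols:
        results = multiple_logistic(
            X[cols], y, corr_threshold=1.01, model_tag="backward"
        )
        worst = max(
            range(len(results)), key=lambda i: (results[i].p_value, -i)
        )
        if results[worst].p_value < alpha:
            if dropped0:
                results = [
                    AssociationResult(
                        **{**r.__dict__, "dropped": tuple(dropped0)}
                    )
                    for r in results
                ]
            return results
        cols.pop(worst)
    return []
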