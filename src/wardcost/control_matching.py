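"""Standard-care control construction via 1:1 propensity matching.

Propensity scores come from a plain (unpenalized) logistic regression of
group membership on age, gender, and primary ICD-10 diagnosis; matching is
greedy nearest-neighbour without replacement, processing treated subjects in
descending score order.  The algorithmic choices (greedy, no replacement, no
default caliper, diagnosis as categorical indicators at full-code
granularity) are the common reproducible baseline; all are exposed as
arguments or config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "MatchingError",
    "MatchResult",
    "propensity_design",
    "estimate_propensity",
    "match_1to1",
    "balance_table",
]

COVARIATES = ("age", "gender", "icd10")


class MatchingError(RuntimeError):
    """Degenerate design or separation; consider exact matching instead."""


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]
    unmatched_treated: list[str]
    distances: list[float] = field(default_factory=list)
    balance: pd.DataFrame | None = None


def propensity_design(
    treated: pd.DataFrame, control: pd.DataFrame, truncate_icd10: bool = False
) -> tuple[np.ndarray, pd.DataFrame]:
    """Pooled (y, X) design for the membership model.

    X has an intercept, numeric age, a female indicator, and diagnosis
    indicators (first category dropped).  ``truncate_icd10`` collapses codes
    to their 3-character chapter before encoding.
    """
    for frame, name in ((treated, "treated"), (control, "control")):
        missing = [c for c in COVARIATES if c not in frame.columns]
        if missing:
            raise MatchingError(f"{name} covariates missing column(s) {missing}")
    pooled = pd.concat(
        [treated[list(COVARIATES)], control[list(COVARIATES)]], ignore_index=True
    )
    y = np.concatenate([np.ones(len(treated)), np.zeros(len(control))])
    icd = pooled["icd10"].astype(str)
    if truncate_icd10:
        icd = icd.str[:3]
    X = pd.DataFrame(
        {
            "const": 1.0,
            "age": pooled["age"].astype(float),
            "female": (pooled["gender"].astype(str) == "F").astype(float),
        }
    )
    dummies = pd.get_dummies(icd, prefix="icd", drop_first=True, dtype=float)
    X = pd.concat([X, dummies], axis=1)
    return y, X


def estimate_propensity(
    treated: pd.DataFrame, control: pd.DataFrame, truncate_icd10: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Propensity scores in (0, 1) for treated and control subjects.

    Fits logistic regression by maximum likelihood.  Raises
    :class:`MatchingError` on perfect separation or non-convergence, advising
    an exact-matching fallback.
    """
    y, X = propensity_design(treated, control, truncate_icd10=truncate_icd10)
    if len(np.unique(y)) < 2:
        raise MatchingError("need both treated and control subjects to fit scores")
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise MatchingError(
            f"propensity model is degenerate ({exc}); fall back to exact matching"
        ) from exc
    if not fit.mle_retvals.get("converged", False) or np.abs(fit.params).max() > 1e3:
        raise MatchingError(
            "propensity model did not converge (likely separation); "
            "fall back to exact matching"
        )
    scores = np.asarray(fit.predict(X))
    return scores[: len(treated)], scores[len(treated):]


def _smd(x_t: np.ndarray, x_c: np.ndarray) -> float:
    """Standardized mean difference with pooled-variance denominator."""
    if len(x_t) == 0 or len(x_c) == 0:
        return float("nan")
    pooled_sd = np.sqrt((np.var(x_t, ddof=1 if len(x_t) > 1 else 0)
                         + np.var(x_c, ddof=1 if len(x_c) > 1 else 0)) / 2.0)
    diff = float(np.mean(x_t) - np.mean(x_c))
    if pooled_sd == 0:
        return 0.0 if diff == 0 else float("inf")
    return diff / pooled_sd


def _balance_columns(frame: pd.DataFrame, levels: list[str]) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "age": frame["age"].astype(float),
            "female": (frame["gender"].astype(str) == "F").astype(float),
        }
    )
    icd = frame["icd10"].astype(str)
    for level in levels:
        out[f"icd_{level}"] = (icd == level).astype(float)
    return out


def balance_table(
    treated: pd.DataFrame, control: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Per-covariate standardized mean differences before and after matching."""
    levels = sorted(
        set(treated["icd10"].astype(str)) | set(control["icd10"].astype(str))
    )
    t_all = _balance_columns(treated, levels)
    c_all = _balance_columns(control, levels)
    t_idx = treated.set_index("id")
    c_idx = control.set_index("id")
    t_matched = _balance_columns(t_idx.loc[[p[0] for p in pairs]].reset_index(), levels) \
        if pairs else t_all.iloc[:0]
    c_matched = _balance_columns(c_idx.loc[[p[1] for p in pairs]].reset_index(), levels) \
        if pairs else c_all.iloc[:0]
    rows = []
    for col in t_all.columns:
        rows.append(
            {
                "covariate": col,
                "smd_before": _smd(t_all[col].to_numpy(), c_all[col].to_numpy()),
                "smd_after": _smd(t_matched[col].to_numpy(), c_matched[col].to_numpy()),
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def match_1to1(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    treated_scores: np.ndarray,
    control_scores: np.ndarray,
    caliper: float | None = None,
) -> MatchResult:
    """Greedy nearest-neighbour 1:1 matching without replacement.

    Treated subjects are processed in descending score order; each takes the
    closest unused control by absolute score distance (ties go to the
    lower-scoring control).  Pairs beyond the caliper are discarded and the
    treated subject left unmatched.  Deterministic for fixed input ordering.
    """
    if len(control) == 0:
        raise MatchingError("control pool is empty")
    if len(treated) != len(treated_scores) or len(control) != len(control_scores):
        raise ValueError("scores must align with covariate tables")

    t_ids = treated["id"].astype(str).to_numpy()
    c_ids = control["id"].astype(str).to_numpy()
    t_scores = np.asarray(treated_scores, dtype=float)
    c_scores = np.asarray(control_scores, dtype=float)

    c_order = np.argsort(c_scores, kind="stable")
    c_sorted = c_scores[c_order]
    used = np.zeros(len(c_sorted), dtype=bool)

    pairs: list[tuple[str, str]] = []
    distances: list[float] = []
    unmatched: list[str] = []

    # stable sort keeps input order among equal scores
    for ti in np.argsort(-t_scores, kind="stable"):
        pos = int(np.searchsorted(c_sorted, t_scores[ti]))
        best_j = -1
        best_d = np.inf
        left, right = pos - 1, pos
        while left >= 0 or right < len(c_sorted):
            # expand outward; stop once both frontiers are worse than best_d
            left_d = t_scores[ti] - c_sorted[left] if left >= 0 else np.inf
            right_d = c_sorted[right] - t_scores[ti] if right < len(c_sorted) else np.inf
            if best_d <= left_d and best_d <= right_d:
                break
            if left_d <= right_d:
                if not used[left] and left_d < best_d:
                    best_j, best_d = left, left_d
                left -= 1
            else:
                if not used[right] and right_d < best_d:
                    best_j, best_d = right, right_d
                right += 1
        if best_j < 0 or (caliper is not None and best_d > caliper):
            unmatched.append(str(t_ids[ti]))
            continue
        used[best_j] = True
        pairs.append((str(t_ids[ti]), str(c_ids[c_order[best_j]])))
        distances.append(float(best_d))

    balance = balance_table(treated, control, pairs)
    return MatchResult(
        pairs=pairs, unmatched_treated=unmatched, distances=distances, balance=balance
    )
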