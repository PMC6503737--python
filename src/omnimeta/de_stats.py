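"""Per-study differential expression statistics.

Each study is analyzed with a penalized t-statistic,

    t_pen(g) = (mean_case - mean_control) / (se_g + s0),

where se_g is the pooled two-sample standard error and s0 a small
stabilizing constant (default: the median se over genes).  Two-sided
p-values come from label permutations shared across genes, and
standardized effect sizes use the bias-corrected standardized mean
difference (Hedges' g) with its analytic variance, ready for fixed- and
random-effects pooling.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy, InvalidDesignError, StudyCollection

logger = logging.getLogger(__name__)


@dataclass
class PerStudyDE:
    """Per-gene DE statistics for one study.

    ``table`` is indexed by gene with columns t_pen, p_two, direction,
    g (Hedges' g), v (variance of g).
    """

    study_id: str
    table: pd.DataFrame
    s0: float
    B: int
    seed: int | None = None
    exact: bool = False


def harmonize_genes(coll: StudyCollection) -> StudyCollection:
    """Restrict every study to the shared gene intersection, same order.

    Row order follows the first study's gene order restricted to the
    intersection.
    """
    common = set(coll.studies[0].genes)
    for s in coll.studies[1:]:
        common &= set(s.genes)
    if not common:
        raise ValueError("gene intersection across studies is empty")
    ordered = [g for g in coll.studies[0].genes if g in common]
    return StudyCollection([s.subset_genes(ordered) for s in coll])


def _arm_split(study: ExpressionStudy) -> tuple[np.ndarray, np.ndarray]:
    case = study.case_mask()
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 < 2 or n0 < 2:
        raise InvalidDesignError(
            f"study {study.study_id!r}: need >=2 samples per arm"
        )
    return case, ~case


def _pooled_stats(X: np.ndarray, case: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (mean difference, pooled SD, pooled SE) per gene."""
    n1, n0 = case.sum(), (~case).sum()
    m1 = X[:, case].mean(axis=1)
    m0 = X[:, ~case].mean(axis=1)
    ss1 = ((X[:, case] - m1[:, None]) ** 2).sum(axis=1)
    ss0 = ((X[:, ~case] - m0[:, None]) ** 2).sum(axis=1)
    sp = np.sqrt((ss1 + ss0) / (n1 + n0 - 2))
    se = sp * math.sqrt(1 / n1 + 1 / n0)
    return m1 - m0, sp, se


def resolve_s0(study: ExpressionStudy, s0: float | str = "auto") -> float:
    if s0 == "auto":
        case, _ = _arm_split(study)
        _, _, se = _pooled_stats(study.expr.values, case)
        return float(np.median(se))
    return float(s0)


def penalized_t(study: ExpressionStudy, s0: float | str = "auto") -> pd.Series:
    """Penalized t per gene; s0=0 recovers the classical pooled t."""
    case, _ = _arm_split(study)
    diff, _, se = _pooled_stats(study.expr.values, case)
    s0_val = resolve_s0(study, s0)
    return pd.Series(diff / (se + s0_val), index=study.genes, name="t_pen")


def _perm_t(X: np.ndarray, case_masks: np.ndarray, s0: float) -> np.ndarray:
    """Penalized t for each column of boolean case_masks (N x B).

    Vectorized over genes and permutations via matrix products.
    """
    N = X.shape[1]
    M = case_masks.astype(float)
    n1 = M.sum(axis=0)
    n0 = N - n1
    tot = X.sum(axis=1, keepdims=True)
    tot2 = (X**2).sum(axis=1, keepdims=True)
    s1 = X @ M
    q1 = (X**2) @ M
    m1 = s1 / n1
    m0 = (tot - s1) / n0
    ss1 = q1 - s1**2 / n1
    ss0 = (tot2 - q1) - (tot - s1) ** 2 / n0
    sp = np.sqrt((ss1 + ss0) / (n1 + n0 - 2))
    se = sp * np.sqrt(1 / n1 + 1 / n0)
    return (m1 - m0) / (se + s0)


def _all_label_masks(N: int, n1: int) -> np.ndarray:
    combos = list(itertools.combinations(range(N), n1))
    masks = np.zeros((N, len(combos)), dtype=bool)
    for j, idx in enumerate(combos):
        masks[list(idx), j] = True
    return masks


def permutation_pvalues(study: ExpressionStudy, s0: float | str = "auto",
                        B: int | str = 1000, seed: int = 0
                        ) -> tuple[pd.Series, dict]:
    """Two-sided permutation p-values of the penalized t.

    Label permutations are shared across genes within each replicate so
    gene-gene correlation survives into the permutation null.  When the
    number of distinct case-label assignments C(N, n1) is at most B (or
    B="exact"), the full enumeration is used and p is an exact fraction;
    otherwise p = (1 + #{|t_b| >= |t|}) / (B + 1).
    """
    case, _ = _arm_split(study)
    X = study.expr.values
    N = X.shape[1]
    n1 = int(case.sum())
    s0_val = resolve_s0(study, s0)
    t_obs = _perm_t(X, case[:, None], s0_val)[:, 0]

    n_distinct = math.comb(N, n1)
    exact = B == "exact" or (isinstance(B, int) and n_distinct <= B)
    if isinstance(B, int) and B < 1:
        raise ValueError("B must be >= 1")
    if exact:
        if B != "exact":
            logger.warning(
                "study %s: only %d distinct label assignments <= B=%s; "
                "enumerating exactly", study.study_id, n_distinct, B)
        masks = _all_label_masks(N, n1)
        t_perm = _perm_t(X, masks, s0_val)
        p = (np.abs(t_perm) >= np.abs(t_obs)[:, None] - 1e-12).mean(axis=1)
        info = {"B": n_distinct, "exact": True, "s0": s0_val}
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((N, B), dtype=bool)
        for b in range(B):
            masks[rng.permutation(N)[:n1], b] = True
        t_perm = _perm_t(X, masks, s0_val)
        count = (np.abs(t_perm) >= np.abs(t_obs)[:, None] - 1e-12).sum(axis=1)
        p = (1.0 + count) / (B + 1.0)
        info = {"B": B, "exact": False, "s0": s0_val}
    return pd.Series(p, index=study.genes, name="p_two"), info


def effect_size(study: ExpressionStudy) -> pd.DataFrame:
    """Bias-corrected standardized mean difference g and its variance v.

    d = (mean_case - mean_control) / s_pooled, g = d * (1 - 3/(4n - 9))
    with n = n1 + n2, and v = n/(n1*n2) + g^2 / (2n).
    """
    case, ctrl = _arm_split(study)
    n1, n0 = int(case.sum()), int(ctrl.sum())
    diff, sp, _ = _pooled_stats(study.expr.values, case)
    zero = np.flatnonzero(sp == 0)
    if zero.size:
        raise ValueError(
            f"study {study.study_id!r}: zero pooled SD for gene(s) "
            f"{[study.genes[i] for i in zero[:5]]}"
        )
    n = n1 + n0
    d = diff / sp
    correction = 1.0 - 3.0 / (4.0 * n - 9.0)
    g = d * correction
    v = n / (n1 * n0) + g**2 / (2.0 * n)
    return pd.DataFrame({"g": g, "v": v}, index=study.genes)


def analyze_study(study: ExpressionStudy, s0: float | str = "auto",
                  B: int | str = 1000, seed: int = 0) -> PerStudyDE:
    """Full per-study DE analysis: t_pen, permutation p, direction, g, v."""
    t = penalized_t(study, s0=s0)
    p, info = permutation_pvalues(study, s0=s0, B=B, seed=seed)
    es = effect_size(study)
    direction = np.sign(t.values).astype(int)
    table = pd.DataFrame({
        "t_pen": t.values,
        "p_two": p.values,
        "direction": direction,
        "g": es["g"].values,
        "v": es["v"].values,
    }, index=study.genes)
    return PerStudyDE(study_id=study.study_id, table=table,
                      s0=info["s0"], B=info["B"], seed=seed,
                      exact=info["exact"])


def one_sided_pvalues(p_two: np.ndarray, direction: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Directional p-values derived from two-sided p and direction sign.

    p_up = p/2 where the change is up, 1 - p/2 where down (0.5 at ties);
    p_down = 1 - p_up.
    """
    p_up = np.where(direction > 0, p_two / 2.0,
                    np.where(direction < 0, 1.0 - p_two / 2.0, 0.5))
    return p_up, 1.0 - p_up
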