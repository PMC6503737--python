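"""Meta-analysis across studies: p-value, rank, and effect-size combination.

Methods and the hypothesis setting each targets:

==========  =========  =======================================================
method      targets    combined statistic
==========  =========  =======================================================
fisher      HS_B       X = -2 * sum(ln p_k), chi-square with 2K df
stouffer    HS_B       Z = sum(Phi^-1(1 - p_k)) / sqrt(K), standard normal
maxp        HS_A       max_k p_k referred to Beta(K, 1)
rop         HS_r       r-th smallest p_k referred to Beta(r, K - r + 1)
pr / sr     HS_A       product (log-sum) / sum of within-study evidence ranks
fem         HS_B       inverse-variance pooled Hedges' g
rem         HS_r       DerSimonian-Laird random-effects pooled Hedges' g
==========  =========  =======================================================

The one-sided correction (OC) combines direction-aware one-sided
p-values per side and doubles the smaller combined p, so only genes with
concordant direction of change across studies can score well.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import StudyCollection
from .de_stats import PerStudyDE, one_sided_pvalues

logger = logging.getLogger(__name__)

_TINY = 1e-300
HS_BY_METHOD = {
    "fisher": "HS_B", "stouffer": "HS_B", "maxp": "HS_A", "rop": "HS_r",
    "pr": "HS_A", "sr": "HS_A", "fem": "HS_B", "rem": "HS_r",
}


@dataclass
class PValueMatrix:
    """G x K two-sided p-values with matching direction signs."""

    p: pd.DataFrame  # genes x studies
    direction: pd.DataFrame  # genes x studies, in {-1, 0, +1}

    def __post_init__(self) -> None:
        if not self.p.index.equals(self.direction.index) or \
                not self.p.columns.equals(self.direction.columns):
            raise ValueError("p and direction matrices are not aligned")
        vals = self.p.values
        if np.any(vals <= 0) or np.any(vals > 1):
            n_zero = int((vals <= 0).sum())
            if np.any(vals > 1):
                raise ValueError("p-values above 1")
            logger.warning("clamping %d p-values <= 0 to machine minimum", n_zero)
            self.p = self.p.clip(lower=_TINY)

    @property
    def K(self) -> int:
        return self.p.shape[1]

    @classmethod
    def from_per_study(cls, des: list[PerStudyDE]) -> "PValueMatrix":
        p = pd.DataFrame({d.study_id: d.table["p_two"] for d in des})
        direc = pd.DataFrame({d.study_id: d.table["direction"] for d in des})
        return cls(p=p, direction=direc)


@dataclass
class EffectSizeMatrix:
    g: pd.DataFrame  # genes x studies Hedges' g
    v: pd.DataFrame  # matching variances

    def __post_init__(self) -> None:
        if not self.g.index.equals(self.v.index) or \
                not self.g.columns.equals(self.v.columns):
            raise ValueError("g and v matrices are not aligned")
        if np.any(self.v.values <= 0):
            raise ValueError("effect-size variances must be > 0")

    @property
    def K(self) -> int:
        return self.g.shape[1]

    @classmethod
    def from_per_study(cls, des: list[PerStudyDE]) -> "EffectSizeMatrix":
        g = pd.DataFrame({d.study_id: d.table["g"] for d in des})
        v = pd.DataFrame({d.study_id: d.table["v"] for d in des})
        return cls(g=g, v=v)


@dataclass
class MetaResult:
    """Combined evidence per gene for one method.

    ``table`` columns: statistic, p_meta, direction, z and (after
    :func:`estimate_fdr`) q; REM/FEM additionally carry mu_hat, se and
    (REM) tau2_hat.
    """

    method: str
    hs: str
    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def require_q(self) -> pd.Series:
        if "q" not in self.table:
            raise ValueError(f"{self.method}: q-values not computed yet")
        return self.table["q"]


@dataclass
class DESignature:
    """Consensus disease signature: up/down gene lists plus signed scores."""

    up: list[str]
    down: list[str]
    z: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down lists overlap")


# -- helpers ---------------------------------------------------------------------

def _z_from_p(p_meta: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Signed z with |z| = Phi^-1(1 - p/2)."""
    mag = stats.norm.isf(np.clip(p_meta, _TINY, 1.0) / 2.0)
    sign = np.where(direction == 0, 1.0, direction)
    return sign * mag


def _majority_direction(direction: np.ndarray) -> np.ndarray:
    total = direction.sum(axis=1)
    return np.sign(total).astype(int)


def _combine_side(p: np.ndarray, method: str, r: int | None) -> np.ndarray:
    """Combined upper-tail p for one G x K matrix of one-sided p-values."""
    p = np.clip(p, _TINY, 1.0)
    K = p.shape[1]
    if method == "fisher":
        X = -2.0 * np.log(p).sum(axis=1)
        return stats.chi2.sf(X, df=2 * K)
    if method == "stouffer":
        z = stats.norm.isf(np.clip(p, _TINY, 1.0 - 1e-16))
        return stats.norm.sf(z.sum(axis=1) / math.sqrt(K))
    if method == "maxp":  # Beta(K, 1) upper-order statistic, i.e. (max p)^K
        method, r = "rop", K
    if method == "rop":
        p_r = np.sort(p, axis=1)[:, r - 1]
        return stats.beta.cdf(p_r, r, K - r + 1)
    raise ValueError(f"unknown p-value combination method {method!r}")


def _statistic(p: np.ndarray, method: str, r: int | None) -> np.ndarray:
    K = p.shape[1]
    p = np.clip(p, _TINY, 1.0)
    if method == "fisher":
        return -2.0 * np.log(p).sum(axis=1)
    if method == "stouffer":
        z = stats.norm.isf(np.clip(p, _TINY, 1.0 - 1e-16))
        return z.sum(axis=1) / math.sqrt(K)
    if method == "maxp":
        return np.max(p, axis=1)
    if method == "rop":
        return np.sort(p, axis=1)[:, r - 1]
    raise ValueError(method)


def combine_pvalues(P: PValueMatrix, method: str, r: int | None = None,
                    one_sided_correction: bool = False) -> MetaResult:
    """Combine per-study two-sided p-values into one meta p per gene.

    With ``one_sided_correction`` the two-sided p's are split by the
    observed direction into per-side one-sided p's, each side is combined
    separately, and p_meta = min(1, 2 * min(P_up, P_down)) with the
    direction of the winning side.
    """
    method = method.lower()
    if method == "rop":
        if r is None:
            raise ValueError("rop requires the order index r")
        if not 1 <= r <= P.K:
            raise ValueError(f"r={r} outside 1..K={P.K}")
    elif r is not None and method != "rop":
        r = None

    p = P.p.values
    direc = P.direction.values
    if one_sided_correction:
        p_up, p_down = one_sided_pvalues(p, direc)
        P_up = _combine_side(p_up, method, r)
        P_down = _combine_side(p_down, method, r)
        p_meta = np.minimum(1.0, 2.0 * np.minimum(P_up, P_down))
        direction = np.where(P_up <= P_down, 1, -1)
        stat = np.where(P_up <= P_down,
                        _statistic(p_up, method, r),
                        _statistic(p_down, method, r))
    else:
        p_meta = _combine_side(p, method, r)
        direction = _majority_direction(direc)
        stat = _statistic(p, method, r)

    name = method + (".oc" if one_sided_correction else "")
    table = pd.DataFrame({
        "statistic": stat,
        "p_meta": np.clip(p_meta, _TINY, 1.0),
        "direction": direction,
    }, index=P.p.index)
    table["z"] = _z_from_p(table["p_meta"].values, table["direction"].values)
    return MetaResult(method=name, hs=HS_BY_METHOD[method], table=table,
                      params={"r": r, "one_sided": one_sided_correction})


def _rank_stats(ranks: np.ndarray, method: str) -> np.ndarray:
    if method == "pr":  # product of ranks in log space
        return np.log(ranks).sum(axis=1)
    if method == "sr":
        return ranks.sum(axis=1)
    raise ValueError(f"unknown rank combination method {method!r}")


def combine_ranks(P: PValueMatrix, method: str, B_null: int | str = 100,
                  seed: int = 0) -> MetaResult:
    """Product-of-ranks (PR) or sum-of-ranks (SR) combination.

    Genes are ranked ascending by p within each study (rank 1 = most
    significant, average ties).  The null distribution pools the
    statistic over all genes after independently shuffling each study's
    rank column; ``B_null="exact"`` enumerates every per-study rank
    permutation (feasible only for tiny G and K).
    """
    method = method.lower()
    G, K = P.p.shape
    if G < 2:
        raise ValueError("rank combination needs >= 2 genes")
    ranks = np.column_stack([
        stats.rankdata(P.p.values[:, k], method="average") for k in range(K)
    ])
    obs = _rank_stats(ranks, method)

    if B_null == "exact":
        null_vals = []
        base = [stats.rankdata(P.p.values[:, k]) for k in range(K)]
        for perms in itertools.product(
                *[itertools.permutations(col) for col in base]):
            arr = np.column_stack([np.asarray(p) for p in perms])
            null_vals.append(_rank_stats(arr, method))
        null = np.concatenate(null_vals)
        null.sort()
        count = np.searchsorted(null, obs, side="right")
        p_meta = count / null.size
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(B_null * G)
        shuffled = ranks.copy()
        for b in range(B_null):
            for k in range(K):
                rng.shuffle(shuffled[:, k])
            null[b * G:(b + 1) * G] = _rank_stats(shuffled, method)
        null.sort()
        count = np.searchsorted(null, obs, side="right")
        p_meta = (1.0 + count) / (null.size + 1.0)

    direction = _majority_direction(P.direction.values)
    table = pd.DataFrame({
        "statistic": obs,
        "p_meta": np.clip(p_meta, _TINY, 1.0),
        "direction": direction,
    }, index=P.p.index)
    table["z"] = _z_from_p(table["p_meta"].values, table["direction"].values)
    return MetaResult(method=method, hs=HS_BY_METHOD[method], table=table,
                      params={"B_null": B_null, "seed": seed})


def combine_effects(E: EffectSizeMatrix, model: str = "rem") -> MetaResult:
    """Fixed-effect or DerSimonian-Laird random-effects pooling.

    REM estimates the between-study variance as
    tau2 = max(0, (Q - (K-1)) / C) with Q the fixed-effect heterogeneity
    statistic and C = sum(w) - sum(w^2)/sum(w); when Q <= K - 1 the
    estimate clamps to zero and REM coincides with FEM exactly.
    """
    model = model.lower()
    if model not in ("fem", "rem"):
        raise ValueError(f"unknown effect model {model!r}")
    g, v = E.g.values, E.v.values
    K = g.shape[1]
    if model == "rem" and K < 2:
        raise ValueError("rem needs K >= 2 studies")
    w = 1.0 / v
    sw = w.sum(axis=1)
    mu_fem = (w * g).sum(axis=1) / sw
    if model == "fem":
        mu_hat = mu_fem
        se = sw ** -0.5
        tau2 = np.zeros_like(mu_hat)
    else:
        Q = (w * (g - mu_fem[:, None]) ** 2).sum(axis=1)
        C = sw - (w**2).sum(axis=1) / sw
        tau2 = np.maximum(0.0, (Q - (K - 1)) / C)
        w_star = 1.0 / (v + tau2[:, None])
        sws = w_star.sum(axis=1)
        mu_hat = (w_star * g).sum(axis=1) / sws
        se = sws ** -0.5
    z = mu_hat / se
    p_meta = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({
        "statistic": z,
        "p_meta": np.clip(p_meta, _TINY, 1.0),
        "direction": np.sign(mu_hat).astype(int),
        "z": z,
        "mu_hat": mu_hat,
        "se": se,
    }, index=E.g.index)
    if model == "rem":
        table["tau2_hat"] = tau2
    return MetaResult(method=model, hs=HS_BY_METHOD[model], table=table)


def estimate_fdr(result: MetaResult, mode: str = "bh",
                 null_p: np.ndarray | None = None) -> MetaResult:
    """Attach q-values: Benjamini-Hochberg or permutation-based.

    Permutation mode expects ``null_p`` of shape (replicates, G): meta
    p-values recomputed on label-permuted per-study statistics.  Then
    q(p) = median_r #{null_r <= p} / #{observed <= p}, made monotone in p
    and clipped to [0, 1].
    """
    p = result.table["p_meta"].values
    if mode == "bh":
        q = multipletests(p, method="fdr_bh")[1]
    elif mode == "permutation":
        if null_p is None or np.size(null_p) == 0:
            raise ValueError("permutation FDR requires non-empty null_p")
        null_p = np.atleast_2d(np.asarray(null_p, dtype=float))
        order = np.argsort(p, kind="mergesort")
        sorted_p = p[order]
        n_obs = np.arange(1, p.size + 1)
        counts = np.column_stack([
            np.searchsorted(np.sort(row), sorted_p, side="right")
            for row in null_p
        ])
        expected = np.median(counts, axis=1)
        q_sorted = expected / n_obs
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q_sorted = np.clip(q_sorted, 0.0, 1.0)
        q = np.empty_like(q_sorted)
        q[order] = q_sorted
    else:
        raise ValueError(f"unknown FDR mode {mode!r}")
    table = result.table.copy()
    table["q"] = q
    return MetaResult(method=result.method, hs=result.hs, table=table,
                      params={**result.params, "fdr_mode": mode})


def consensus_signature(results: list[MetaResult], fdr: float = 0.05
                        ) -> DESignature:
    """Genes significant (q < fdr) with concordant direction in every result.

    Direction conflicts exclude a gene (counted in the log, not an
    error).  Signed z scores come from the first effect-size result if
    one is supplied, else from the first result.
    """
    if not results:
        raise ValueError("need at least one MetaResult")
    genes = results[0].genes
    for res in results[1:]:
        if not res.genes.equals(genes):
            genes = genes.intersection(res.genes)
    sig = np.ones(len(genes), dtype=bool)
    direction = None
    conflicts = np.zeros(len(genes), dtype=bool)
    for res in results:
        tab = res.table.loc[genes]
        sig &= (res.require_q().loc[genes].values < fdr)
        d = tab["direction"].values
        if direction is None:
            direction = d.copy()
        else:
            conflicts |= (d != direction)
    conflicts |= (direction == 0)
    n_conflicts = int((sig & conflicts).sum())
    if n_conflicts:
        logger.info("consensus: %d significant genes dropped for direction "
                    "conflict", n_conflicts)
    keep = sig & ~conflicts
    z_source = next((r for r in results if r.method in ("fem", "rem")),
                    results[0])
    z = z_source.table.loc[genes, "z"]
    up = [g for g, k, d in zip(genes, keep, direction) if k and d > 0]
    down = [g for g, k, d in zip(genes, keep, direction) if k and d < 0]
    return DESignature(
        up=up, down=down, z=z,
        provenance={"methods": [r.method for r in results], "fdr": fdr,
                    "direction_conflicts": n_conflicts},
    )


def method_concordance(results: list[MetaResult]) -> pd.DataFrame:
    """Method x method Spearman correlation of meta p-values."""
    if len(results) < 2:
        raise ValueError("need >= 2 results for a concordance matrix")
    genes = results[0].genes
    for res in results[1:]:
        genes = genes.intersection(res.genes)
    # positional concat: method names may repeat (e.g. a result vs itself)
    mat = np.column_stack([r.table.loc[genes, "p_meta"].values
                           for r in results])
    rho = stats.spearmanr(mat).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    labels = [r.method for r in results]
    out = pd.DataFrame(rho, index=labels, columns=labels)
    np.fill_diagonal(out.values, 1.0)
    return out


def compare_signatures(z_a: pd.Series, z_b: pd.Series) -> float:
    """Spearman rho of two per-gene signed score vectors on shared genes."""
    shared = z_a.index.intersection(z_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    return float(stats.spearmanr(z_a.loc[shared], z_b.loc[shared]).statistic)


def rop_default_r(K: int, frac: float = 0.7) -> int:
    """Default order index for rOP: ceil(frac * K), the 'most studies' rule."""
    return max(1, math.ceil(frac * K))
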