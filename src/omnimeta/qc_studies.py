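"""Study-level QC: six quality measures, SMR summary, and exclusion.

Each measure is expressed as -log10 of a permutation or Fisher-exact
p-value so that larger always means better and rank aggregation is
well defined:

* **IQC** — homogeneity of co-expression structure: Spearman correlation
  between a study's gene-gene correlations (over the top pooled-variance
  common genes) and the element-wise mean of the other studies',
  referred to a gene-identity permutation null.
* **EQC** — consistency of co-expression with a gene-set collection:
  within-set mean absolute correlation versus size-matched random sets.
* **AQCg / AQCp** — accuracy of DE gene / enriched-pathway detection:
  Fisher-exact overlap of the study's findings with a leave-one-out
  meta-analysis reference.
* **CQCg / CQCp** — consistency of DE gene / pathway ranking: Spearman
  correlation with the leave-one-out reference ranking, permutation p.

Within the QC module DE evidence uses analytic pooled-t p-values and the
leave-one-out reference combines them with Fisher's method; this keeps
the six measures cheap enough to permute.  A standardized mean rank
(SMR, mean of the six within-collection ranks, 1 = best) summarizes each
study; the worst ceil(f*K) studies by SMR are excluded (default f=0.2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection, StudyCollection
from .de_stats import harmonize_genes
from .downstream import ora_test

logger = logging.getLogger(__name__)

MEASURES = ("IQC", "EQC", "AQCg", "AQCp", "CQCg", "CQCp")


@dataclass
class StudyQCReport:
    measures: pd.DataFrame  # K x 6
    ranks: pd.DataFrame  # per-measure within-collection ranks, 1 = best
    smr: pd.Series  # mean rank per study
    excluded: list[str]
    exclusion_fraction: float
    biplot_scores: pd.DataFrame | None = None
    biplot_loadings: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.measures.copy()
        out = out.join(self.ranks.add_prefix("rank."))
        out["SMR"] = self.smr
        out["excluded"] = out.index.isin(self.excluded)
        return out.rename_axis("study")


def _perm_pvalue(count_ge: int, n_perm: int) -> float:
    return (1.0 + count_ge) / (1.0 + n_perm)


def _neglog10(p: float) -> float:
    return float(-math.log10(p))


def _hypergeom_overlap_p(a: set, b: set, universe_size: int) -> float:
    """Upper-tail p of observing >= |a & b| under random draws."""
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(b), len(a)))


def _study_t_pvalues(study, genes: pd.Index) -> np.ndarray:
    X = study.expr.loc[genes].values
    case = study.case_mask()
    res = stats.ttest_ind(X[:, case], X[:, ~case], axis=1, equal_var=True)
    return np.clip(res.pvalue, 1e-300, 1.0)


def _fisher_loo(pmat: np.ndarray, k: int) -> np.ndarray:
    others = np.delete(pmat, k, axis=1)
    X = -2.0 * np.log(others).sum(axis=1)
    return stats.chi2.sf(X, df=2 * others.shape[1])


def _spearman_perm_p(x: np.ndarray, y: np.ndarray, n_perm: int,
                     rng: np.random.Generator) -> float:
    """Permutation p for positive Spearman correlation of x with fixed y."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:  # constant ranking carries no evidence
        return 1.0
    obs = np.corrcoef(rx, ry)[0, 1]
    count = 0
    shuffled = rx.copy()
    for _ in range(n_perm):
        rng.shuffle(shuffled)
        if np.corrcoef(shuffled, ry)[0, 1] >= obs:
            count += 1
    return _perm_pvalue(count, n_perm)


def compute_qc_measures(coll: StudyCollection, gene_sets: GeneSetCollection,
                        n_top_genes: int = 200, n_perm: int = 200,
                        seed: int = 0, de_alpha: float = 0.05,
                        q_alpha: float = 0.05) -> pd.DataFrame:
    """Six QC measures per study, each on the -log10(p) scale.

    Permutation p-values use the +1 correction p = (1 + b) / (1 + B), so
    every permutation-based measure is bounded by log10(n_perm + 1).
    """
    if coll.K < 3:
        raise ValueError(f"study-level QC needs K >= 3 studies, got {coll.K}")
    harm = harmonize_genes(coll)
    # canonical gene and sample order so measures are order-invariant
    ordered = sorted(harm.studies[0].genes)
    harm = StudyCollection([
        s.subset_genes(ordered).subset_samples(sorted(s.samples))
        for s in harm
    ])
    genes = harm.studies[0].genes
    G = len(genes)
    if G < n_top_genes:
        n_top_genes = G
    rng = np.random.default_rng(seed)
    K = harm.K

    # top pooled-variance common genes for co-expression structure
    var_pool = np.mean([s.expr.values.var(axis=1, ddof=1) for s in harm],
                       axis=0)
    top_idx = np.sort(np.argsort(var_pool)[::-1][:n_top_genes])
    iu = np.triu_indices(n_top_genes, k=1)

    corr_top = []
    for s in harm:
        C = np.corrcoef(s.expr.values[top_idx])
        corr_top.append(C)
    upper = np.array([C[iu] for C in corr_top])  # K x n_pairs

    # analytic per-study DE p-values over all common genes
    pmat = np.column_stack([_study_t_pvalues(s, genes) for s in harm])

    sets = gene_sets.restricted(genes, min_size=3)
    set_names = sets.names()
    gene_pos = {g: i for i, g in enumerate(genes)}
    set_idx = {n: np.array(sorted(gene_pos[g] for g in sets.sets[n]))
               for n in set_names}

    rows = {}
    for k, study in enumerate(harm):
        sid = study.study_id
        row = {}

        # IQC: co-expression homogeneity vs the other studies
        ref = upper[np.arange(K) != k].mean(axis=0)
        ref_rank = stats.rankdata(ref)
        obs_rank = stats.rankdata(upper[k])
        if obs_rank.std() == 0 or ref_rank.std() == 0:
            row["IQC"] = 0.0
        else:
            obs_rho = np.corrcoef(obs_rank, ref_rank)[0, 1]
            Ck = corr_top[k]
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(n_top_genes)
                u_perm = Ck[np.ix_(perm, perm)][iu]
                if np.corrcoef(stats.rankdata(u_perm),
                               ref_rank)[0, 1] >= obs_rho:
                    count += 1
            row["IQC"] = _neglog10(_perm_pvalue(count, n_perm))

        # EQC: within-set coexpression vs size-matched random sets
        if set_names:
            Cfull = np.corrcoef(study.expr.values)
            def set_stat(indices_list):
                vals = []
                for idx in indices_list:
                    sub = np.abs(Cfull[np.ix_(idx, idx)])
                    m = len(idx)
                    vals.append((sub.sum() - m) / (m * (m - 1)))
                return float(np.mean(vals))
            obs_stat = set_stat([set_idx[n] for n in set_names])
            sizes = [len(set_idx[n]) for n in set_names]
            count = 0
            for _ in range(n_perm):
                rand = [rng.choice(G, size=m, replace=False) for m in sizes]
                if set_stat(rand) >= obs_stat:
                    count += 1
            row["EQC"] = _neglog10(_perm_pvalue(count, n_perm))
            del Cfull
        else:
            logger.warning("study %s: no usable gene sets; EQC set to 0", sid)
            row["EQC"] = 0.0

        # leave-one-out meta reference
        p_loo = _fisher_loo(pmat, k)
        q_loo = multipletests(p_loo, method="fdr_bh")[1]
        meta_genes = set(genes[q_loo < q_alpha])
        study_genes = set(genes[pmat[:, k] < de_alpha])

        # AQCg: Fisher-exact overlap of study DE genes with LOO meta genes
        if study_genes and meta_genes:
            row["AQCg"] = _neglog10(
                _hypergeom_overlap_p(study_genes, meta_genes, G))
        else:
            logger.warning("study %s: empty DE overlap universe; AQCg=0", sid)
            row["AQCg"] = 0.0

        # pathway-level quantities
        if set_names:
            ora_k = ora_test(study_genes or set(genes[:1]), list(genes), sets)
            ora_loo = ora_test(meta_genes or set(genes[:1]), list(genes), sets)
            sets_k = set(ora_k.index[ora_k["q"] < q_alpha])
            sets_loo = set(ora_loo.index[ora_loo["q"] < q_alpha])
            if sets_k and sets_loo:
                row["AQCp"] = _neglog10(
                    _hypergeom_overlap_p(sets_k, sets_loo, len(set_names)))
            else:
                logger.warning("study %s: empty enriched-set overlap; AQCp=0",
                               sid)
                row["AQCp"] = 0.0
            row["CQCp"] = _neglog10(_spearman_perm_p(
                -np.log10(ora_k["p"].values),
                -np.log10(ora_loo["p"].values), n_perm, rng))
        else:
            row["AQCp"] = 0.0
            row["CQCp"] = 0.0

        # CQCg: ranking consistency with the LOO meta ranking
        row["CQCg"] = _neglog10(_spearman_perm_p(
            -np.log10(pmat[:, k]), -np.log10(np.clip(p_loo, 1e-300, 1.0)),
            n_perm, rng))

        rows[sid] = row

    return pd.DataFrame.from_dict(rows, orient="index")[list(MEASURES)]


def summarize_smr(measures: pd.DataFrame, exclusion_fraction: float = 0.2
                  ) -> StudyQCReport:
    """Rank studies per measure (1 = best), average into SMR, exclude worst.

    Ties receive average ranks; the exclusion tie-break is study-id
    order.  Exactly ceil(f * K) studies with the largest SMR are
    excluded.
    """
    if not 0 <= exclusion_fraction < 1:
        raise ValueError("exclusion_fraction must be in [0, 1)")
    ranks = pd.DataFrame(np.column_stack([
        stats.rankdata(-measures[c].values, method="average")
        for c in measures.columns
    ]), index=measures.index, columns=measures.columns)
    smr = ranks.mean(axis=1)
    n_excl = math.ceil(exclusion_fraction * len(measures))
    order = sorted(measures.index, key=lambda sid: (-smr[sid], sid))
    excluded = order[:n_excl]
    if n_excl and smr[excluded].nunique() < len(excluded):
        logger.info("SMR ties at the exclusion boundary broken by study id")
    scores, loadings = biplot_coordinates(measures)
    return StudyQCReport(
        measures=measures, ranks=ranks, smr=smr, excluded=excluded,
        exclusion_fraction=exclusion_fraction,
        biplot_scores=scores, biplot_loadings=loadings,
    )


def biplot_coordinates(measures: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First two principal components of the column-standardized measures.

    Returns per-study scores and per-measure loadings.  Sign convention:
    each loading vector's largest-magnitude element is positive.  Zero
    variance columns are dropped with a warning.
    """
    if len(measures) < 3:
        raise ValueError("biplot needs K >= 3 studies")
    sd = measures.std(ddof=1)
    keep = sd.index[sd > 0]
    dropped = [c for c in measures.columns if c not in set(keep)]
    if dropped:
        logger.warning("dropping zero-variance QC measure columns %s", dropped)
    X = measures[keep]
    Z = (X - X.mean()) / X.std(ddof=1)
    U, S, Vt = np.linalg.svd(Z.values, full_matrices=False)
    n_comp = min(2, len(S))
    scores = U[:, :n_comp] * S[:n_comp]
    load = Vt[:n_comp].T
    for j in range(n_comp):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{i + 1}" for i in range(n_comp)]
    return (pd.DataFrame(scores, index=measures.index, columns=cols),
            pd.DataFrame(load, index=keep, columns=cols))
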