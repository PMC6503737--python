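"""Synthetic multi-study expression collections with known ground truth.

The generator emulates the statistical structure the meta-analysis
assumes: K two-arm studies over a shared gene space, a fraction of
genes differentially expressed with standardized effects drawn around
``+-mu`` with between-study variance ``tau2``, and effects carried by
all studies (HS_A), by one or more randomly chosen studies (HS_B), or
by a fixed fraction of studies (HS_r).  Separate planting steps corrupt
individual samples (for sample-level QC) or whole studies (for
study-level QC), and companion generators produce gene sets enriched in
true DE genes and compound perturbation signatures that reverse the
planted disease signature.
"""

from __future__ import annotations

import copy
import math

import numpy as np
import pandas as pd

from .datatypes import (
    CASE,
    CONTROL,
    CompoundInstance,
    CompoundSignatureLibrary,
    ExpressionStudy,
    GeneSetCollection,
    StudyCollection,
    SyntheticConfig,
    TruthTable,
)

# cosmetic metadata cycled over studies; irrelevant to any statistic
_PLATFORMS = ("Affymetrix.HG-U133_Plus_2", "Illumina.HiSeq2000",
              "Affymetrix.HuGene-1_0-st-v1", "Illumina.HiSeq2500")
_REGIONS = ("PFC", "Striatum", "Hippocampus", "Cerebellum", "ACC", "OFC")

BASELINE_MEAN = 7.0
BASELINE_SD = 1.5


def _gene_ids(G: int) -> list[str]:
    width = max(5, len(str(G)))
    return [f"G{i:0{width}d}" for i in range(1, G + 1)]


def generate_collection(config: SyntheticConfig
                        ) -> tuple[StudyCollection, TruthTable]:
    """Generate K studies plus the truth table of planted effects.

    Per gene, baseline log2 expression is drawn Normal(7, 1.5) and shared
    across studies; residual noise is Normal(0, sigma).  For each DE gene
    a direction sign is drawn once (Bernoulli 1/2) and shared by all
    carrying studies; the per-study standardized effect is
    delta_gk ~ Normal(sign*mu, tau2), added to the case arm as
    ``delta_gk * sigma``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    G, K = config.G, config.K
    genes = _gene_ids(G)
    n_case, n_control = config.arm_sizes()
    study_ids = [f"STUDY{k + 1:02d}" for k in range(K)]

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=G)

    n_de = int(round(config.pi_de * G))
    de_idx = np.sort(rng.choice(G, size=n_de, replace=False))
    is_de = np.zeros(G, dtype=bool)
    is_de[de_idx] = True
    sign = np.zeros(G, dtype=int)
    sign[de_idx] = rng.choice([-1, 1], size=n_de)

    # which studies carry each DE gene's effect
    carriers = np.zeros((G, K), dtype=bool)
    if config.scenario == "HS_A":
        carriers[de_idx, :] = True
    elif config.scenario == "HS_r":
        m = math.ceil(config.r_frac * K)
        for g in de_idx:
            carriers[g, rng.choice(K, size=m, replace=False)] = True
    else:  # HS_B: one or more studies, uniform count
        for g in de_idx:
            m = int(rng.integers(1, K + 1))
            carriers[g, rng.choice(K, size=m, replace=False)] = True

    delta = np.zeros((G, K))
    tau = math.sqrt(config.tau2)
    for k in range(K):
        carr = carriers[:, k]
        delta[carr, k] = rng.normal(config.mu * sign[carr], tau)

    studies = []
    for k, sid in enumerate(study_ids):
        n1, n0 = n_case[k], n_control[k]
        N = n1 + n0
        samples = [f"{sid}_S{j + 1:03d}" for j in range(N)]
        group = pd.Series([CONTROL] * n0 + [CASE] * n1, index=samples)
        X = baseline[:, None] + rng.normal(0.0, config.sigma, size=(G, N))
        X[:, n0:] += (delta[:, k] * config.sigma)[:, None]
        metadata = pd.DataFrame({
            "platform": _PLATFORMS[k % len(_PLATFORMS)],
            "region": _REGIONS[k % len(_REGIONS)],
        }, index=samples)
        studies.append(ExpressionStudy(
            study_id=sid,
            expr=pd.DataFrame(X, index=genes, columns=samples),
            group=group,
            metadata=metadata,
        ))

    truth = TruthTable(
        genes=genes,
        study_ids=study_ids,
        is_de=pd.Series(is_de, index=genes),
        delta=pd.DataFrame(delta, index=genes, columns=study_ids),
        direction=pd.Series(sign, index=genes),
    )
    coll = StudyCollection(studies)

    if config.n_outlier_samples:
        coll, truth = plant_outlier_samples(
            coll, truth, config.n_outlier_samples,
            seed=_child_seed(config.seed, 1))
    if config.n_bad_studies:
        coll, truth = plant_corrupted_study(
            coll, truth, config.n_bad_studies,
            seed=_child_seed(config.seed, 2))
    return coll, truth


def _child_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def _copy_collection(coll: StudyCollection) -> StudyCollection:
    studies = [ExpressionStudy(
        study_id=s.study_id,
        expr=s.expr.copy(),
        group=s.group.copy(),
        metadata=None if s.metadata is None else s.metadata.copy(),
    ) for s in coll]
    return StudyCollection(studies)


def plant_outlier_samples(coll: StudyCollection, truth: TruthTable,
                          n: int, seed: int
                          ) -> tuple[StudyCollection, TruthTable]:
    """Replace n random samples by marginal-matched independent noise.

    The replacement keeps each sample's own mean and SD across genes but
    ignores the per-gene baselines, which destroys its correlation with
    every other sample; the inter-array-correlation QC is built to catch
    exactly this.
    """
    smallest = min(s.n_samples for s in coll)
    if n >= smallest:
        raise ValueError(
            f"cannot plant {n} outliers: smallest study has {smallest} samples"
        )
    out = _copy_collection(coll)
    truth = copy.deepcopy(truth)
    if n == 0:
        return out, truth
    rng = np.random.default_rng(seed)
    pool = [(s.study_id, smp) for s in out for smp in s.samples]
    chosen = rng.choice(len(pool), size=n, replace=False)
    for idx in sorted(int(i) for i in chosen):
        sid, smp = pool[idx]
        study = out[sid]
        col = study.expr[smp].values
        study.expr[smp] = rng.normal(col.mean(), col.std(ddof=0), size=col.shape)
        truth.outlier_samples.setdefault(sid, []).append(smp)
    return out, truth


def plant_corrupted_study(coll: StudyCollection, truth: TruthTable,
                          n: int, seed: int
                          ) -> tuple[StudyCollection, TruthTable]:
    """Independently permute each sample's gene values in n studies.

    Per-sample marginal distributions are preserved but gene identity is
    scrambled independently per sample, destroying both co-expression
    structure and any case/control signal.
    """
    if n >= coll.K:
        raise ValueError(f"cannot corrupt {n} of {coll.K} studies")
    out = _copy_collection(coll)
    truth = copy.deepcopy(truth)
    if n == 0:
        return out, truth
    rng = np.random.default_rng(seed)
    chosen = rng.choice(coll.K, size=n, replace=False)
    for k in sorted(int(i) for i in chosen):
        study = out.studies[k]
        X = study.expr.values
        for j in range(X.shape[1]):
            X[:, j] = rng.permutation(X[:, j])
        truth.corrupted_studies.append(study.study_id)
    return out, truth


def generate_gene_sets(truth: TruthTable, n_sets: int = 50,
                       set_size_range: tuple[int, int] = (15, 40),
                       n_enriched: int = 5, enrich_frac: float = 0.8,
                       seed: int = 0) -> GeneSetCollection:
    """Random gene sets, n_enriched of them biased toward true DE genes."""
    rng = np.random.default_rng(seed)
    universe = np.asarray(truth.genes)
    G = len(universe)
    lo, hi = set_size_range
    if hi > G:
        raise ValueError("set sizes cannot exceed the gene universe")
    de = np.asarray(truth.de_genes())
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    enriched: list[str] = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"SET{i + 1:03d}"
        if i < n_enriched:
            k_de = int(round(enrich_frac * size))
            if k_de > len(de):
                raise ValueError(
                    f"enrich_frac*size = {k_de} exceeds {len(de)} DE genes"
                )
            members = set(rng.choice(de, size=k_de, replace=False))
            rest = np.setdiff1d(universe, np.asarray(sorted(members)))
            members |= set(rng.choice(rest, size=size - k_de, replace=False))
            enriched.append(name)
            descriptions[name] = "enriched"
        else:
            members = set(rng.choice(universe, size=size, replace=False))
            descriptions[name] = "random"
        sets[name] = {str(m) for m in members}
    truth.enriched_sets = enriched
    return GeneSetCollection(sets=sets, descriptions=descriptions,
                             source="synthetic")


_CELL_LINES = ("A375", "MCF7", "PC3", "HT29", "VCAP")
_DOSES = ("1uM", "10uM")


def generate_compound_library(disease_up: set[str], disease_down: set[str],
                              universe: list[str], n_compounds: int = 20,
                              n_instances_per_compound: int = 6,
                              n_reversal: int = 2, overlap_frac: float = 0.8,
                              set_size: int = 30, seed: int = 0,
                              truth: TruthTable | None = None
                              ) -> CompoundSignatureLibrary:
    """Compound perturbation instances; reversal compounds oppose the disease.

    A reversal instance's up-set draws ``overlap_frac`` of its members from
    ``disease_down`` (and its down-set from ``disease_up``); all other
    instances are uniform draws from the universe.
    """
    if not disease_up or not disease_down:
        raise ValueError("disease signatures must be non-empty")
    if not 0 <= overlap_frac <= 1:
        raise ValueError("overlap_frac must be in [0, 1]")
    if n_reversal > n_compounds:
        raise ValueError("n_reversal cannot exceed n_compounds")
    rng = np.random.default_rng(seed)
    universe_arr = np.asarray(universe)
    up_arr = np.asarray(sorted(disease_up))
    down_arr = np.asarray(sorted(disease_down))

    def biased_set(source: np.ndarray, avoid: set[str]) -> set[str]:
        source = np.asarray([g for g in source if g not in avoid])
        k = min(int(round(overlap_frac * set_size)), len(source))
        members = set(rng.choice(source, size=k, replace=False))
        pool = np.asarray([g for g in universe_arr
                           if g not in members and g not in avoid])
        members |= set(rng.choice(pool, size=set_size - k, replace=False))
        return {str(m) for m in members}

    def random_set(avoid: set[str]) -> set[str]:
        pool = np.asarray([g for g in universe_arr if g not in avoid])
        return {str(m) for m in rng.choice(pool, size=set_size, replace=False)}

    instances = []
    reversal_names = []
    for c in range(n_compounds):
        compound = f"CPD{c + 1:03d}"
        is_rev = c < n_reversal
        if is_rev:
            reversal_names.append(compound)
        for i in range(n_instances_per_compound):
            cell = _CELL_LINES[i % len(_CELL_LINES)]
            dose = _DOSES[(i // len(_CELL_LINES)) % len(_DOSES)]
            if is_rev:
                up = biased_set(down_arr, avoid=set())
                down = biased_set(up_arr, avoid=up)
            else:
                up = random_set(avoid=set())
                down = random_set(avoid=up)
            instances.append(CompoundInstance(
                compound=compound, cell_line=cell, dose=f"{dose}.{i + 1}",
                up=up, down=down,
            ))
    if truth is not None:
        truth.reversal_compounds = reversal_names
    return CompoundSignatureLibrary(instances)
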