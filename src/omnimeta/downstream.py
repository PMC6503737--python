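"""Downstream interpretation: pathway over-representation and compound
signature-reversal prioritization.

Over-representation analysis (ORA) refers the overlap between a DE gene
list and each gene set to the hypergeometric upper tail within a stated
universe (the harmonized common-gene space, not the whole genome), with
Benjamini-Hochberg q-values across the collection.

Compound prioritization scores each perturbation instance (compound x
cell line x dose) by the same hypergeometric test in both reversal
directions — disease-up genes against the compound's down set, and
disease-down genes against the compound's up set — BH-adjusts across all
instances and directions, counts significant instances per compound, and
reports compounds whose total exceeds ``min_sum``.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    CompoundInstance,
    CompoundSignatureLibrary,
    GeneSetCollection,
)


def ora_test(de_genes: Iterable[str], universe: Iterable[str],
             sets: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of de_genes in each gene set.

    Gene sets are intersected with the universe before testing; the
    returned table (indexed by set name) carries overlap, set_size,
    universe_size, de_size, p and BH q.
    """
    universe = set(universe)
    de = set(de_genes)
    if not universe:
        raise ValueError("empty universe")
    if not de:
        raise ValueError("empty DE gene list")
    if not de <= universe:
        raise ValueError("DE genes must be a subset of the universe")
    M, N = len(universe), len(de)
    rows = {}
    for name in sets.names():
        members = sets.sets[name] & universe
        n = len(members)
        k = len(members & de)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows[name] = {"overlap": k, "set_size": n, "universe_size": M,
                      "de_size": N, "p": min(p, 1.0)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["q"] = multipletests(out["p"].values, method="fdr_bh")[1]
    return out.rename_axis("set")


def score_compound_instance(sig, instance: CompoundInstance,
                            universe: Iterable[str]) -> tuple[float, float]:
    """Reversal p-values for one instance.

    Returns ``(p_up_down, p_down_up)``: the hypergeometric upper-tail p
    for the overlap of the disease up-genes with the instance's down set,
    and of the disease down-genes with the instance's up set.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    up = set(sig.up) & universe
    down = set(sig.down) & universe
    if not up or not down:
        raise ValueError("disease signature empty within the universe")
    M = len(universe)
    inst_up = instance.up & universe
    inst_down = instance.down & universe

    def tail(de: set, target: set) -> float:
        if not target:
            return 1.0
        k = len(de & target)
        return float(stats.hypergeom.sf(k - 1, M, len(target), len(de)))

    return tail(up, inst_down), tail(down, inst_up)


def prioritize_compounds(sig, library: CompoundSignatureLibrary,
                         universe: Iterable[str], alpha: float = 0.01,
                         min_sum: int = 5) -> pd.DataFrame:
    """Count significant reversal instances per compound and rank.

    Both directions of every instance are BH-adjusted together across the
    library; an instance counts toward a direction when its adjusted p is
    below ``alpha``.  Rows with total count strictly greater than
    ``min_sum`` are returned sorted by the total (descending), ties
    broken by compound name.
    """
    if not len(library):
        raise ValueError("empty compound library")
    universe = set(universe)
    records = []
    for inst in library.instances:
        p_ud, p_du = score_compound_instance(sig, inst, universe)
        records.append((inst.compound, inst.name, "sigup_l1000down", p_ud))
        records.append((inst.compound, inst.name, "sigdown_l1000up", p_du))
    df = pd.DataFrame(records,
                      columns=["compound", "instance", "direction", "p"])
    df["p_adj"] = multipletests(df["p"].values, method="fdr_bh")[1]
    df["significant"] = df["p_adj"] < alpha

    counts = (df[df["significant"]]
              .groupby(["compound", "direction"]).size().unstack(fill_value=0))
    for col in ("sigdown_l1000up", "sigup_l1000down"):
        if col not in counts:
            counts[col] = 0
    counts = counts.rename(columns={
        "sigdown_l1000up": "n_sigdown_l1000up",
        "sigup_l1000down": "n_sigup_l1000down",
    })[["n_sigdown_l1000up", "n_sigup_l1000down"]]
    counts["sum"] = counts.sum(axis=1)
    counts = counts[counts["sum"] > min_sum]
    counts = counts.reset_index().sort_values(
        ["sum", "compound"], ascending=[False, True]).set_index("compound")
    return counts
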