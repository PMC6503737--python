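"""Core data containers shared across the meta-analysis pipeline.

A *study* is one normalized, log-scale gene x sample expression matrix
with a two-arm (case/control) design.  A *collection* is an ordered set
of studies sharing (part of) a gene space; meta-analysis operates on the
intersection of their gene identifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"
SCENARIOS = ("HS_A", "HS_B", "HS_r")


class InvalidDesignError(ValueError):
    """Raised when a study design cannot support a two-sample comparison."""


@dataclass
class ExpressionStudy:
    """One study: genes x samples expression plus per-sample labels.

    Parameters
    ----------
    study_id : unique identifier within a collection.
    expr : DataFrame, rows indexed by gene id, columns by sample id,
        values on a normalized log2 scale.
    group : Series mapping sample id -> ``"case"`` or ``"control"``.
    metadata : optional per-sample table (platform, region, ...).
    """

    study_id: str
    expr: pd.DataFrame
    group: pd.Series
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.expr.isna().any().any():
            raise ValueError(f"study {self.study_id!r}: missing values in expr")
        if not self.expr.index.is_unique:
            raise ValueError(f"study {self.study_id!r}: duplicate gene ids")
        self.group = self.group.reindex(self.expr.columns)
        if self.group.isna().any():
            raise InvalidDesignError(
                f"study {self.study_id!r}: samples without group label"
            )
        bad = set(self.group.unique()) - {CASE, CONTROL}
        if bad:
            raise InvalidDesignError(
                f"study {self.study_id!r}: unknown group labels {sorted(bad)}"
            )
        counts = self.group.value_counts()
        if counts.get(CASE, 0) < 2 or counts.get(CONTROL, 0) < 2:
            raise InvalidDesignError(
                f"study {self.study_id!r}: need >=2 samples per arm, got "
                f"{counts.to_dict()}"
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def case_mask(self) -> np.ndarray:
        return (self.group.values == CASE)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionStudy":
        samples = list(samples)
        meta = self.metadata.loc[samples] if self.metadata is not None else None
        return ExpressionStudy(
            study_id=self.study_id,
            expr=self.expr[samples],
            group=self.group.loc[samples],
            metadata=meta,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionStudy":
        return ExpressionStudy(
            study_id=self.study_id,
            expr=self.expr.loc[list(genes)],
            group=self.group,
            metadata=self.metadata,
        )


@dataclass
class StudyCollection:
    studies: list[ExpressionStudy]

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate study ids in collection")
        if not ids:
            raise ValueError("empty collection")

    @property
    def K(self) -> int:
        return len(self.studies)

    @property
    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]

    def __iter__(self):
        return iter(self.studies)

    def __getitem__(self, study_id: str) -> ExpressionStudy:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    def common_genes(self) -> pd.Index:
        common = self.studies[0].genes
        for s in self.studies[1:]:
            common = common.intersection(s.genes)
        return common


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for the multi-study generator.

    ``mu`` is the mean standardized effect (in units of the residual SD
    ``sigma``) planted in carrying studies, ``tau2`` the between-study
    variance of that effect, and ``scenario`` selects which studies carry
    each differentially expressed gene (all / one-or-more / a fraction
    ``r_frac``).
    """

    K: int = 6
    G: int = 2000
    n_case: int | Sequence[int] = 15
    n_control: int | Sequence[int] = 15
    pi_de: float = 0.1
    scenario: str = "HS_r"
    r_frac: float = 0.7
    mu: float = 1.0
    tau2: float = 0.1
    sigma: float = 1.0
    n_outlier_samples: int = 0
    n_bad_studies: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pi_de <= 1:
            raise ValueError("pi_de must be in [0, 1]")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not 0 < self.r_frac <= 1:
            raise ValueError("r_frac must be in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.K < 1 or self.G < 1:
            raise ValueError("K and G must be >= 1")

    def arm_sizes(self) -> tuple[list[int], list[int]]:
        def expand(x) -> list[int]:
            if isinstance(x, (int, np.integer)):
                return [int(x)] * self.K
            x = [int(v) for v in x]
            if len(x) != self.K:
                raise ValueError("per-study arm sizes must have length K")
            return x

        n1, n0 = expand(self.n_case), expand(self.n_control)
        if min(n1) < 2 or min(n0) < 2:
            raise InvalidDesignError("each arm needs >= 2 samples")
        return n1, n0


@dataclass
class TruthTable:
    """Bookkeeping of everything the generator planted."""

    genes: list[str]
    study_ids: list[str]
    is_de: pd.Series = None  # bool per gene
    delta: pd.DataFrame = None  # genes x studies true standardized effects
    direction: pd.Series = None  # {-1, 0, +1} per gene
    outlier_samples: dict[str, list[str]] = field(default_factory=dict)
    corrupted_studies: list[str] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)
    reversal_compounds: list[str] = field(default_factory=list)

    def de_genes(self) -> list[str]:
        return list(self.is_de.index[self.is_de])

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "study_ids": self.study_ids,
            "is_de": self.is_de.astype(bool).to_dict(),
            "delta": self.delta.to_dict(orient="split"),
            "direction": self.direction.astype(int).to_dict(),
            "outlier_samples": self.outlier_samples,
            "corrupted_studies": self.corrupted_studies,
            "enriched_sets": self.enriched_sets,
            "reversal_compounds": self.reversal_compounds,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TruthTable":
        delta = pd.DataFrame(
            d["delta"]["data"], index=d["delta"]["index"],
            columns=d["delta"]["columns"],
        )
        return cls(
            genes=list(d["genes"]),
            study_ids=list(d["study_ids"]),
            is_de=pd.Series(d["is_de"]).reindex(d["genes"]).astype(bool),
            delta=delta,
            direction=pd.Series(d["direction"]).reindex(d["genes"]).astype(int),
            outlier_samples={k: list(v) for k, v in d["outlier_samples"].items()},
            corrupted_studies=list(d["corrupted_studies"]),
            enriched_sets=list(d["enriched_sets"]),
            reversal_compounds=list(d["reversal_compounds"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class GeneSetCollection:
    """Named gene sets, GMT-style (name, description, members)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def restricted(self, universe: Iterable[str], min_size: int = 1
                   ) -> "GeneSetCollection":
        uni = set(universe)
        kept = {n: s & uni for n, s in self.sets.items() if len(s & uni) >= min_size}
        return GeneSetCollection(
            sets=kept,
            descriptions={n: self.descriptions.get(n, "") for n in kept},
            source=self.source,
        )


@dataclass
class CompoundInstance:
    """One perturbation instance: a compound in one cell line at one dose."""

    compound: str
    cell_line: str
    dose: str
    up: set[str]
    down: set[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError(
                f"instance {self.name}: up and down sets overlap"
            )

    @property
    def name(self) -> str:
        return f"{self.compound}|{self.cell_line}|{self.dose}"


@dataclass
class CompoundSignatureLibrary:
    instances: list[CompoundInstance]

    def __post_init__(self) -> None:
        names = [i.name for i in self.instances]
        if len(set(names)) != len(names):
            raise ValueError("duplicate instance names in compound library")

    def compounds(self) -> list[str]:
        seen: dict[str, None] = {}
        for inst in self.instances:
            seen.setdefault(inst.compound, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.instances)
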