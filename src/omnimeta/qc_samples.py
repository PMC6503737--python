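"""Sample-level QC by inter-array correlation (IAC).

The IAC of two samples is the Pearson correlation of their full
expression vectors.  A sample whose mean IAC with all other samples
falls more than ``c`` standard deviations below the study's overall mean
IAC (default c = 3) is flagged as divergent and removed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy, InvalidDesignError


class UndefinedCorrelationError(ValueError):
    pass


@dataclass
class SampleQCReport:
    study_id: str
    iac_matrix: pd.DataFrame  # N x N Pearson correlations, unit diagonal
    mean_iac: pd.Series  # per-sample mean of off-diagonal IACs
    overall_mean: float
    overall_sd: float
    c: float | None = None
    cutoff: float | None = None
    flagged: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"mean_iac": self.mean_iac})
        out["cutoff"] = self.cutoff if self.cutoff is not None else np.nan
        out["flagged"] = (
            out.index.isin(self.flagged) if self.flagged is not None else False
        )
        return out.rename_axis("sample")


def compute_iac(study: ExpressionStudy) -> SampleQCReport:
    """All pairwise sample-sample Pearson correlations over all genes."""
    if study.n_samples < 3:
        raise InvalidDesignError(
            f"study {study.study_id!r}: IAC QC needs >= 3 samples"
        )
    X = study.expr.values
    sds = X.std(axis=0)
    constant = np.flatnonzero(sds == 0)
    if constant.size:
        names = [study.samples[i] for i in constant]
        raise UndefinedCorrelationError(
            f"study {study.study_id!r}: constant expression vector(s) "
            f"{names}; correlation undefined"
        )
    iac = np.corrcoef(X.T)
    np.fill_diagonal(iac, 1.0)
    N = iac.shape[0]
    mean_iac = (iac.sum(axis=1) - 1.0) / (N - 1)
    return SampleQCReport(
        study_id=study.study_id,
        iac_matrix=pd.DataFrame(iac, index=study.samples, columns=study.samples),
        mean_iac=pd.Series(mean_iac, index=study.samples),
        overall_mean=float(mean_iac.mean()),
        overall_sd=float(mean_iac.std(ddof=1)),
    )


def flag_outliers(report: SampleQCReport, c: float = 3.0) -> SampleQCReport:
    """Flag samples with mean IAC below overall_mean - c * overall_sd.

    A zero overall SD (e.g. identical samples) yields no flags.
    """
    cutoff = report.overall_mean - c * report.overall_sd
    if report.overall_sd < 1e-12:  # degenerate: effectively identical samples
        flagged: list[str] = []
    else:
        flagged = list(report.mean_iac.index[report.mean_iac < cutoff])
    return replace(report, c=c, cutoff=float(cutoff), flagged=flagged)


def drop_flagged(study: ExpressionStudy, report: SampleQCReport
                 ) -> ExpressionStudy:
    if report.flagged is None:
        raise ValueError("flags not computed; call flag_outliers first")
    keep = [s for s in study.samples if s not in set(report.flagged)]
    if len(keep) == study.n_samples:
        return study
    groups = study.group.loc[keep].value_counts()
    if groups.min() < 2 or len(groups) < 2:
        raise InvalidDesignError(
            f"study {study.study_id!r}: removing flagged samples leaves "
            f"<2 samples in a group"
        )
    return study.subset_samples(keep)


def mds_coordinates(report: SampleQCReport, k: int = 2) -> pd.DataFrame:
    """Classical MDS of the 1 - IAC dissimilarity, exported for inspection
    only; no flagging decision is derived from it."""
    D = 1.0 - report.iac_matrix.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    coords = v[:, order] * np.sqrt(np.clip(w[order], 0, None))
    return pd.DataFrame(coords, index=report.iac_matrix.index,
                        columns=[f"MDS{i + 1}" for i in range(k)])
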