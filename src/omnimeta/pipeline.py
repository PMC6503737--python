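"""End-to-end orchestration: sample QC -> study QC -> per-study DE ->
meta combination -> consensus signature -> ORA -> compound prioritization.

Every stage writes its table under the run directory and contributes
counts to a machine-readable manifest.  All randomness derives from the
single configured seed through named child streams, so a rerun with the
same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import (
    CompoundSignatureLibrary,
    GeneSetCollection,
    StudyCollection,
    SyntheticConfig,
    TruthTable,
)
from . import de_stats, downstream, io, meta, qc_samples, qc_studies, syndata

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("fisher", "stouffer", "maxp", "rop", "rop.oc",
                   "pr", "sr", "fem", "rem")


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Inputs come either from ``input_dir`` (TSV studies plus optional GMT
    files) or from ``synthetic`` (the generator configuration); exactly
    one must be provided.
    """

    seed: int = 0
    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None
    gmt_path: str | None = None
    compound_up_gmt: str | None = None
    compound_down_gmt: str | None = None
    # sample QC
    sample_qc_c: float = 3.0
    # study QC
    exclusion_fraction: float = 0.2
    qc_n_perm: int = 200
    qc_n_top_genes: int = 200
    skip_study_qc: bool = False
    # per-study DE
    s0: float | str = "auto"
    B: int = 1000
    # meta
    methods: tuple[str, ...] = DEFAULT_METHODS
    rop_r: int | str = "auto"
    fdr_mode: str = "bh"
    alpha: float = 0.05
    consensus_methods: tuple[str, ...] = ("rop.oc", "rem")
    pr_sr_B_null: int = 20
    # downstream
    compound_alpha: float = 0.01
    compound_min_sum: int = 5
    # synthetic fixtures for gene sets / compounds when none supplied
    syn_gene_sets: dict = field(default_factory=lambda: dict(
        n_sets=50, set_size_range=(15, 40), n_enriched=5, enrich_frac=0.8))
    syn_compounds: dict = field(default_factory=lambda: dict(
        n_compounds=20, n_instances_per_compound=6, n_reversal=2,
        overlap_frac=0.8, set_size=30))

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.compound_alpha < 1:
            raise ValueError("alpha thresholds must be in (0, 1)")
        if not 0 <= self.exclusion_fraction < 1:
            raise ValueError("exclusion_fraction must be in [0, 1)")
        if self.synthetic is None and self.input_dir is None:
            raise ValueError("provide either synthetic config or input_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        for key in ("methods", "consensus_methods"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d


def child_seed(seed: int, *streams) -> int:
    """Deterministic child seed, kept below 2**31 for portability."""
    key = [int(seed)] + [zlib.crc32(str(s).encode()) for s in streams]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def _feasible_gene_set_kwargs(truth: TruthTable, kwargs: dict) -> dict:
    """Shrink enriched-set demands to what the planted truth can supply."""
    kw = dict(kwargs)
    n_de = int(truth.is_de.sum())
    lo, hi = kw.get("set_size_range", (15, 40))
    frac = kw.get("enrich_frac", 0.8)
    if kw.get("n_enriched", 5) > 0 and n_de > 0 and frac > 0:
        max_size = int(n_de / frac)
        if max_size < hi:
            hi = max(max_size, 2)
            lo = min(lo, hi)
            logger.warning("capping enriched gene-set sizes at %d to fit "
                           "%d planted DE genes", hi, n_de)
            kw["set_size_range"] = (lo, hi)
    if n_de == 0 and kw.get("n_enriched", 5) > 0:
        logger.warning("no planted DE genes; generating unenriched sets only")
        kw["n_enriched"] = 0
    return kw


def run_meta_methods(P: meta.PValueMatrix, E: meta.EffectSizeMatrix,
                     methods, rop_r="auto", fdr_mode: str = "bh",
                     pr_sr_B_null: int = 20, seed: int = 0
                     ) -> dict[str, meta.MetaResult]:
    """Run each requested combination method and attach q-values."""
    K = P.K
    r = meta.rop_default_r(K) if rop_r == "auto" else int(rop_r)
    results: dict[str, meta.MetaResult] = {}
    for name in methods:
        base, _, suffix = name.partition(".")
        oc = suffix == "oc"
        if base in ("fisher", "stouffer", "maxp", "rop"):
            res = meta.combine_pvalues(P, base, r=r if base == "rop" else None,
                                       one_sided_correction=oc)
        elif base in ("pr", "sr"):
            res = meta.combine_ranks(P, base, B_null=pr_sr_B_null,
                                     seed=child_seed(seed, "ranks", base))
        elif base in ("fem", "rem"):
            res = meta.combine_effects(E, base)
        else:
            raise ValueError(f"unknown meta method {name!r}")
        results[name] = meta.estimate_fdr(res, mode=fdr_mode)
    return results


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full workflow; returns the run directory.

    Any stage failure raises :class:`StageError` naming the stage;
    partial outputs written so far are left in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
    }
    truth: TruthTable | None = None

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # ---- inputs -----------------------------------------------------------
    name = stage("inputs")
    try:
        if config.synthetic is not None:
            coll, truth = syndata.generate_collection(config.synthetic)
        else:
            coll = io.read_collection(config.input_dir)
        if config.gmt_path:
            gene_sets = io.read_gmt(config.gmt_path)
        elif truth is not None:
            gene_sets = syndata.generate_gene_sets(
                truth, seed=child_seed(config.seed, "gene_sets"),
                **_feasible_gene_set_kwargs(truth, config.syn_gene_sets))
        else:
            gene_sets = None
        manifest["stages"][name] = {
            "n_studies": coll.K,
            "n_samples": int(sum(s.n_samples for s in coll)),
            "n_gene_sets": len(gene_sets) if gene_sets else 0,
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(name, exc) from exc

    # ---- sample QC --------------------------------------------------------
    name = stage("sample_qc")
    try:
        kept = []
        sample_rows = []
        removed = 0
        for study in coll:
            report = qc_samples.flag_outliers(
                qc_samples.compute_iac(study), c=config.sample_qc_c)
            frame = report.to_frame()
            frame.insert(0, "study", study.study_id)
            sample_rows.append(frame.reset_index())
            removed += len(report.flagged)
            for smp in report.flagged:
                logger.info("sample_qc: removing %s/%s (mean IAC %.4f < %.4f)",
                            study.study_id, smp,
                            report.mean_iac[smp], report.cutoff)
            kept.append(qc_samples.drop_flagged(study, report))
        coll = StudyCollection(kept)
        _write_tsv(pd.concat(sample_rows, ignore_index=True).set_index("study"),
                   out / "sample_qc.tsv")
        manifest["stages"][name] = {"samples_removed": removed,
                                    "c": config.sample_qc_c}
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, exc) from exc

    # ---- study QC ---------------------------------------------------------
    name = stage("study_qc")
    try:
        if config.skip_study_qc or gene_sets is None:
            manifest["stages"][name] = {"skipped": True, "studies_excluded": 0}
        else:
            measures = qc_studies.compute_qc_measures(
                coll, gene_sets, n_top_genes=config.qc_n_top_genes,
                n_perm=config.qc_n_perm,
                seed=child_seed(config.seed, "study_qc"))
            report = qc_studies.summarize_smr(
                measures, exclusion_fraction=config.exclusion_fraction)
            _write_tsv(report.to_frame(), out / "study_qc.tsv")
            if report.biplot_scores is not None:
                _write_tsv(report.biplot_scores.rename_axis("study"),
                           out / "study_qc_biplot_scores.tsv")
                _write_tsv(report.biplot_loadings.rename_axis("measure"),
                           out / "study_qc_biplot_loadings.tsv")
            for sid in report.excluded:
                logger.info("study_qc: excluding %s (SMR %.2f)", sid,
                            report.smr[sid])
            coll = StudyCollection(
                [s for s in coll if s.study_id not in set(report.excluded)])
            manifest["stages"][name] = {
                "studies_excluded": len(report.excluded),
                "excluded": list(report.excluded),
            }
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, exc) from exc

    # ---- per-study DE -----------------------------------------------------
    name = stage("de")
    try:
        coll = de_stats.harmonize_genes(coll)
        genes = list(coll.studies[0].genes)
        des = []
        for study in coll:
            de = de_stats.analyze_study(
                study, s0=config.s0, B=config.B,
                seed=child_seed(config.seed, "de", study.study_id))
            des.append(de)
            tab = de.table.rename_axis("gene")
            _write_tsv(tab, out / f"{study.study_id}.de.tsv")
        manifest["stages"][name] = {
            "genes_tested": len(genes), "n_studies": coll.K, "B": config.B,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, exc) from exc

    # ---- meta -------------------------------------------------------------
    name = stage("meta")
    try:
        P = meta.PValueMatrix.from_per_study(des)
        E = meta.EffectSizeMatrix.from_per_study(des)
        results = run_meta_methods(
            P, E, config.methods, rop_r=config.rop_r,
            fdr_mode=config.fdr_mode, pr_sr_B_null=config.pr_sr_B_null,
            seed=config.seed)
        frames = []
        for mname, res in results.items():
            tab = res.table.copy()
            tab.insert(0, "method", mname)
            frames.append(tab.rename_axis("gene").reset_index())
        _write_tsv(pd.concat(frames, ignore_index=True).set_index("method"),
                   out / "meta.tsv")
        concordance = meta.method_concordance(list(results.values()))
        _write_tsv(concordance.rename_axis("method"),
                   out / "method_concordance.tsv")
        manifest["stages"][name] = {
            "methods": list(results),
            "n_significant": {m: int((r.table["q"] < config.alpha).sum())
                              for m, r in results.items()},
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, exc) from exc

    # ---- consensus --------------------------------------------------------
    name = stage("consensus")
    try:
        chosen = [results[m] for m in config.consensus_methods]
        signature = meta.consensus_signature(chosen, fdr=config.alpha)
        sig_tab = pd.DataFrame({
            "z": signature.z,
            "call": ["up" if g in set(signature.up)
                     else "down" if g in set(signature.down) else ""
                     for g in signature.z.index],
        }).rename_axis("gene")
        _write_tsv(sig_tab, out / "consensus.tsv")
        manifest["stages"][name] = {
            "methods": list(config.consensus_methods),
            "n_up": len(signature.up), "n_down": len(signature.down),
            "direction_conflicts": signature.provenance["direction_conflicts"],
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, exc) from exc

    # ---- enrichment -------------------------------------------------------
    name = stage("enrichment")
    try:
        de_list = set(signature.up) | set(signature.down)
        if gene_sets is not None and de_list:
            enr = downstream.ora_test(de_list, genes, gene_sets)
            _write_tsv(enr, out / "enrichment.tsv")
            n_enr = int((enr["q"] < config.alpha).sum())
        else:
            n_enr = 0
        manifest["stages"][name] = {"n_de_genes": len(de_list),
                                    "n_enriched_sets": n_enr}
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, exc) from exc

    # ---- compounds --------------------------------------------------------
    name = stage("compounds")
    try:
        library = None
        if config.compound_up_gmt and config.compound_down_gmt:
            library = io.read_compound_library(
                config.compound_up_gmt, config.compound_down_gmt)
        elif truth is not None and signature.up and signature.down:
            library = syndata.generate_compound_library(
                set(signature.up), set(signature.down), genes,
                seed=child_seed(config.seed, "compounds"),
                truth=truth, **config.syn_compounds)
        if library is not None and signature.up and signature.down:
            ranking = downstream.prioritize_compounds(
                signature, library, genes, alpha=config.compound_alpha,
                min_sum=config.compound_min_sum)
            _write_tsv(ranking, out / "compounds.tsv")
            manifest["stages"][name] = {
                "n_instances": len(library),
                "n_compounds_reported": int(len(ranking)),
            }
        else:
            manifest["stages"][name] = {"skipped": True}
    except Exception as exc:  # noqa: BLE001
        raise StageError(name, exc) from exc

    if truth is not None:
        truth.to_json(out / "truth.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def simulate_to_dir(config: SyntheticConfig, out_dir: str | Path,
                    force: bool = False, gene_sets_kwargs: dict | None = None,
                    compounds_kwargs: dict | None = None) -> Path:
    """Generate a synthetic dataset directory usable by every subcommand."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    coll, truth = syndata.generate_collection(config)
    io.write_collection(coll, out)
    gs_kwargs = _feasible_gene_set_kwargs(truth, gene_sets_kwargs or {})
    sets = syndata.generate_gene_sets(
        truth, seed=child_seed(config.seed, "gene_sets"), **gs_kwargs)
    io.write_gmt(sets, out / "gene_sets.gmt")
    de_up = {g for g in truth.de_genes() if truth.direction[g] > 0}
    de_down = {g for g in truth.de_genes() if truth.direction[g] < 0}
    if de_up and de_down:
        lib = syndata.generate_compound_library(
            de_up, de_down, truth.genes,
            seed=child_seed(config.seed, "compounds"), truth=truth,
            **(compounds_kwargs or {}))
        io.write_compound_library(lib, out / "compounds_up.gmt",
                                  out / "compounds_down.gmt")
    truth.to_json(out / "truth.json")
    return out
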