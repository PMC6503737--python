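"""Readers and writers for the plain-text interchange formats.

Per study: ``<id>.expr.tsv`` (first column the gene id, one column per
sample) and ``<id>.meta.tsv`` (sample, group, plus free metadata
columns).  Gene sets and compound signatures use GMT (tab-separated:
name, description, members); compound libraries are paired
``*_up.gmt`` / ``*_down.gmt`` files whose set names encode
``compound|cell_line|dose``.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .datatypes import (
    CompoundInstance,
    CompoundSignatureLibrary,
    ExpressionStudy,
    GeneSetCollection,
    StudyCollection,
)


# -- expression studies ---------------------------------------------------------

def write_study(study: ExpressionStudy, outdir: str | Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr_path = outdir / f"{study.study_id}.expr.tsv"
    meta_path = outdir / f"{study.study_id}.meta.tsv"
    # %.17g round-trips float64 exactly
    study.expr.rename_axis("gene").to_csv(expr_path, sep="\t",
                                          float_format="%.17g")
    meta = pd.DataFrame({"group": study.group})
    if study.metadata is not None:
        meta = meta.join(study.metadata)
    meta.rename_axis("sample").to_csv(meta_path, sep="\t")
    return expr_path, meta_path


def read_study(expr_path: str | Path, meta_path: str | Path,
               study_id: str | None = None) -> ExpressionStudy:
    expr_path = Path(expr_path)
    if study_id is None:
        study_id = expr_path.name.removesuffix(".expr.tsv")
    expr = pd.read_csv(expr_path, sep="\t", index_col=0,
                       float_precision="round_trip")
    expr.index = expr.index.astype(str).rename(None)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str).rename(None)
    group = meta["group"].astype(str)
    extra = meta.drop(columns=["group"])
    return ExpressionStudy(
        study_id=study_id,
        expr=expr,
        group=group,
        metadata=extra if extra.shape[1] else None,
    )


def write_collection(coll: StudyCollection, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    for study in coll:
        write_study(study, outdir)
    return outdir


def read_collection(indir: str | Path) -> StudyCollection:
    indir = Path(indir)
    studies = []
    for expr_path in sorted(indir.glob("*.expr.tsv")):
        sid = expr_path.name.removesuffix(".expr.tsv")
        meta_path = indir / f"{sid}.meta.tsv"
        if not meta_path.exists():
            raise FileNotFoundError(f"missing metadata table {meta_path}")
        studies.append(read_study(expr_path, meta_path, study_id=sid))
    if not studies:
        raise FileNotFoundError(f"no *.expr.tsv studies under {indir}")
    return StudyCollection(studies)


# -- GMT gene sets --------------------------------------------------------------

def write_gmt(sets: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sets.names():
            desc = sets.descriptions.get(name, "")
            members = "\t".join(sorted(sets.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
    return path


def read_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line in {path}: {line[:60]!r}")
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r} in {path}")
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions,
                             source=source or os.fspath(path))


# -- compound signature libraries ------------------------------------------------

def write_compound_library(lib: CompoundSignatureLibrary,
                           up_path: str | Path, down_path: str | Path) -> None:
    up = GeneSetCollection(
        sets={i.name: i.up for i in lib.instances},
        descriptions={i.name: i.compound for i in lib.instances},
    )
    down = GeneSetCollection(
        sets={i.name: i.down for i in lib.instances},
        descriptions={i.name: i.compound for i in lib.instances},
    )
    write_gmt(up, up_path)
    write_gmt(down, down_path)


def read_compound_library(up_path: str | Path,
                          down_path: str | Path) -> CompoundSignatureLibrary:
    up = read_gmt(up_path)
    down = read_gmt(down_path)
    if set(up.names()) != set(down.names()):
        raise ValueError("up/down GMT files list different instances")
    instances = []
    for name in up.names():
        parts = name.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"instance name {name!r} is not 'compound|cell_line|dose'"
            )
        instances.append(CompoundInstance(
            compound=parts[0], cell_line=parts[1], dose=parts[2],
            up=set(up.sets[name]), down=set(down.sets[name]),
        ))
    return CompoundSignatureLibrary(instances)
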