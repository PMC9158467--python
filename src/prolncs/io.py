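"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression as TSV (first column = gene id) or GCT 1.2, gene sets as GMT,
survival/purity tables as TSV, ground truth and signature models as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import CohortTruth, ExpressionMatrix, GeneSetCollection, SurvivalTable

__all__ = [
    "write_expression_tsv",
    "read_expression_tsv",
    "write_expression_gct",
    "read_expression_gct",
    "write_survival_tsv",
    "read_survival_tsv",
    "write_gmt",
    "read_gmt",
    "write_truth_json",
    "read_truth_json",
]


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path, space: str = "mRNA") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return ExpressionMatrix(df, space=space)


def write_expression_gct(expr: ExpressionMatrix, path) -> None:
    """GCT 1.2: two header lines then NAME/Description + sample columns."""
    df = expr.values
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        cols = "\t".join(df.columns)
        fh.write(f"NAME\tDescription\t{cols}\n")
        for gid, row in df.iterrows():
            vals = "\t".join(format(v, ".6g") for v in row)
            fh.write(f"{gid}\tna\t{vals}\n")


def read_expression_gct(path, space: str = "mRNA") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
    df = df.drop(columns=["Description"])
    return ExpressionMatrix(df, space=space)


def write_survival_tsv(surv: SurvivalTable, path) -> None:
    surv.data.to_csv(path, sep="\t", index_label="sample_id")


def read_survival_tsv(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return SurvivalTable(df)


def write_gmt(sets: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path) -> GeneSetCollection:
    out: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        out[fields[0]] = [g for g in fields[2:] if g]
    return GeneSetCollection(out)


def write_truth_json(truth: CohortTruth, path) -> None:
    payload = {
        "subtype_of_sample": truth.subtype_of_sample,
        "modulator_pairs": sorted(list(p) for p in truth.modulator_pairs),
        "prognostic_lnc": truth.prognostic_lnc,
        "purity": truth.purity,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path) -> CohortTruth:
    payload = json.loads(Path(path).read_text())
    return CohortTruth(
        subtype_of_sample=payload["subtype_of_sample"],
        modulator_pairs={tuple(p) for p in payload["modulator_pairs"]},
        prognostic_lnc=payload["prognostic_lnc"],
        purity=payload["purity"],
        seed=payload["seed"],
    )
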