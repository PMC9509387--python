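"""TSV dialect shared across the pipeline.

Matrices (beta, detection p) are written probes x samples with the probe
ID in the first column; phenotype, proportion, and result tables are
written with their index as the first column.  Everything is plain
tab-separated text so intermediate artifacts are diffable and portable.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

PHENOTYPE_COLUMNS = ["donor_id", "region", "age", "sex", "batch",
                     "braak_nft", "cerad", "thal", "braak_lb", "tdp43"]


def write_matrix(df: pd.DataFrame, path, index_name="probe_id"):
    df = df.copy()
    df.index.name = index_name
    df.to_csv(path, sep="\t")


def read_matrix(path, index_name="probe_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_name
    return df


def write_phenotypes(pheno: pd.DataFrame, path):
    missing = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    out = pheno[PHENOTYPE_COLUMNS].copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_phenotypes(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", index_col=0)
    pheno.index.name = "sample_id"
    return pheno


def write_table(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj: dict, path):
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
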