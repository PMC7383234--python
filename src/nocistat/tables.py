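"""TSV dialects shared across the analyses.

All exchange formats are UTF-8 tab-separated tables with a header row and
"." (or "NA" for Cq matrices) as the missing-value sentinel.  Readers
validate the header and report schema problems by column name; writers are
exact inverses of the readers on round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ephys_fits import Sweep, SweepSeries
from .expression_calls import CqMatrix

__all__ = [
    "SchemaError",
    "SNP_COLUMNS",
    "read_snp_table",
    "write_snp_table",
    "write_results",
    "write_cascade_report",
    "read_comparisons",
    "write_comparisons",
    "read_sweeps",
    "write_sweeps",
    "read_cq_matrix",
    "write_cq_matrix",
]


class SchemaError(ValueError):
    """An input table does not match its documented dialect."""


SNP_COLUMNS = [
    "snp_id",
    "gene",
    "consequence",
    "in_gene_set",
    "ortholog_common_flag",
    "artifact_flag",
    "n_assessed",
    "rare_allele_count",
    "carrier_count",
    "ref_freq",
    "ref_freq_kind",
    "ref_cohort_size",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_snp_table(path) -> pd.DataFrame:
    """Read the per-SNP cohort table; "." marks an absent field."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    _require(df, SNP_COLUMNS, path)
    out = pd.DataFrame()
    out["snp_id"] = df["snp_id"]
    out["gene"] = df["gene"].fillna("")
    out["consequence"] = df["consequence"].fillna("other")
    for col in ("in_gene_set", "ortholog_common_flag"):
        out[col] = (
            df[col].fillna("false").str.lower().map(_BOOL)
        )
        if out[col].isna().any():
            bad = df.loc[out[col].isna(), col].iloc[0]
            raise SchemaError(f"{path}: column {col} has non-boolean value {bad!r}")
    out["artifact_flag"] = df["artifact_flag"].fillna("none")
    for col in ("n_assessed", "rare_allele_count", "carrier_count"):
        try:
            out[col] = df[col].astype(int)
        except (TypeError, ValueError) as err:
            raise SchemaError(f"{path}: column {col} must be integer: {err}") from err
    out["ref_freq"] = pd.to_numeric(df["ref_freq"], errors="coerce")
    out["ref_freq_kind"] = df["ref_freq_kind"].fillna("allele")
    out["ref_cohort_size"] = pd.to_numeric(df["ref_cohort_size"], errors="coerce")
    return out


def write_snp_table(records: pd.DataFrame, path) -> None:
    df = records.copy()
    for col in ("in_gene_set", "ortholog_common_flag"):
        df[col] = df[col].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def write_results(results: pd.DataFrame, path) -> None:
    """Write scan results (one row per SNP, corrected p-values included)."""
    results.to_csv(path, sep="\t", index=False, na_rep=".")


def write_cascade_report(report, path) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)


COMPARISON_COLUMNS = ["label", "family", "n1", "mean1", "sd1", "n2", "mean2", "sd2"]


def read_comparisons(path) -> pd.DataFrame:
    """Read a summary-statistic comparison table (one outcome per row)."""
    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False)
    _require(df, COMPARISON_COLUMNS, path)
    return df


def write_comparisons(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep=".")


def write_sweeps(series: SweepSeries, path) -> None:
    """Write a sweep series as long TSV plus a JSON metadata sidecar."""
    path = Path(path)
    rows = []
    for idx, s in enumerate(series.sweeps):
        rows.append(
            pd.DataFrame(
                {"sweep": idx, "time_ms": s.time, "value": s.value}
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
    meta = {
        "protocol": series.protocol,
        "holding": series.holding,
        "commands": [s.command for s in series.sweeps],
        "metadata": {
            k: v
            for k, v in series.metadata.items()
            if isinstance(v, (int, float, str, bool, type(None), list, tuple))
        },
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_sweeps(path) -> SweepSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require(df, ["sweep", "time_ms", "value"], path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not meta_path.exists():
        raise SchemaError(f"{path}: missing metadata sidecar {meta_path.name}")
    meta = json.loads(meta_path.read_text())
    commands = meta["commands"]
    sweeps = []
    for idx, group in df.groupby("sweep", sort=True):
        sweeps.append(
            Sweep(
                command=float(commands[int(idx)]),
                time=group["time_ms"].to_numpy(),
                value=group["value"].to_numpy(),
            )
        )
    return SweepSeries(
        protocol=meta["protocol"],
        sweeps=sweeps,
        holding=meta.get("holding", -90.0),
        metadata=meta.get("metadata", {}),
    )


def write_cq_matrix(m: CqMatrix, path) -> None:
    """Genes x cells TSV; columns are "POP:cell" ids, "NA" = no amplification.

    A sidecar JSON records the housekeeping gene and bath-control columns.
    """
    path = Path(path)
    m.cq.to_csv(path, sep="\t", index_label="gene", na_rep="NA")
    sidecar = {
        "housekeeping": m.housekeeping,
        "control_cells": list(m.control_cells),
        "populations": m.populations.to_dict(),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def read_cq_matrix(path) -> CqMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    _require(df, ["gene"], path)
    df = df.set_index("gene")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not meta_path.exists():
        raise SchemaError(f"{path}: missing metadata sidecar {meta_path.name}")
    meta = json.loads(meta_path.read_text())
    return CqMatrix(
        cq=df.astype(float),
        populations=pd.Series(meta["populations"]),
        housekeeping=meta["housekeeping"],
        control_cells=tuple(meta["control_cells"]),
    )
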