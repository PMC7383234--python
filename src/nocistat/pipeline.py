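"""End-to-end genetics pipeline: scan -> corrections -> cascade -> combine.

The pipeline mirrors the study's analysis chain on a SNP table: per-SNP
chi-square scan against reference frequencies with Bonferroni/BH
correction, the annotation filter cascade with per-stage counts, and an
optional pooled discovery+replication carrier test.  Runs are deterministic
given config and seed; the effective config is echoed into the output
directory next to the results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import snp_enrichment as snp
from . import tables

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_genetics_pipeline"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Validated configuration of a genetics pipeline run."""

    snp_table: str
    out_dir: str
    ref_kind: str | None = None  # None = per-record declaration
    layout: str = "auto"
    alpha: float = 0.05
    use: str = "q"  # significance gate column: "q" | "bonferroni"
    stages: tuple[str, ...] = snp.DEFAULT_STAGES
    min_coverage: int = 1
    combine: dict | None = None  # {discovery: [c, n], replication: [c, n],
    #                               ref_carrier_freq: f, ref_cohort_size: N}
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ValueError(
                f"config schema_version {self.schema_version} unsupported"
            )
        if self.use not in ("q", "bonferroni"):
            raise ValueError("use must be 'q' or 'bonferroni'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.stages = tuple(self.stages)
        for stage in self.stages:
            if stage not in snp.DEFAULT_STAGES:
                raise ValueError(f"unknown cascade stage {stage!r}")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def run_genetics_pipeline(config: RunConfig) -> dict:
    """Execute the full genetics chain and write outputs under out_dir.

    Returns a dict with the scan results, cascade survivors, the
    :class:`~nocistat.snp_enrichment.CascadeReport` and (when configured)
    the combined-cohort result.  An empty SNP table produces empty outputs
    and a logged warning rather than an error.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = tables.read_snp_table(config.snp_table)
    logger.info("pipeline: %d SNP records read", len(records))
    if records.empty:
        logger.warning("pipeline: empty SNP table, producing empty results")

    scan_cfg = snp.ScanConfig(
        min_coverage=config.min_coverage,
        layout=config.layout,
        ref_kind_override=config.ref_kind,
    )
    results = snp.snp_scan(records, scan_cfg)
    n_tested = int(results["tested"].sum()) if not results.empty else 0
    logger.info("pipeline: %d of %d SNPs tested", n_tested, len(results))
    tables.write_results(results, out_dir / "scan_results.tsv")

    if results.empty:
        survivors = results
        report = snp.CascadeReport()
    else:
        survivors, report = snp.filter_cascade(
            results, records, stages=config.stages, alpha=config.alpha, use=config.use
        )
    for stage in report.stages:
        logger.info(
            "pipeline: stage %-16s %d -> %d", stage.name, stage.n_in, stage.n_out
        )
    tables.write_results(survivors, out_dir / "cascade_survivors.tsv")
    tables.write_cascade_report(report, out_dir / "cascade_report.tsv")

    combined = None
    if config.combine:
        c = config.combine
        combined = snp.combine_cohorts(
            tuple(c["discovery"]),
            tuple(c["replication"]),
            c["ref_carrier_freq"],
            c.get("ref_cohort_size"),
            round_reference=c.get("round_reference", True),
        )
        logger.info(
            "pipeline: combined carriers %d/%d expected %.4f chi2 %.3f p %.4f",
            combined.carriers,
            combined.n,
            combined.expected_carriers,
            combined.chisq.chi2,
            combined.chisq.p_two_tail,
        )
        (out_dir / "combined_cohort.json").write_text(
            json.dumps(
                {
                    "carriers": combined.carriers,
                    "n": combined.n,
                    "expected_carriers": combined.expected_carriers,
                    "chi2": combined.chisq.chi2,
                    "p_two_tail": combined.chisq.p_two_tail,
                    "layout": combined.chisq.layout,
                },
                indent=1,
            )
        )

    echo = dataclasses.asdict(config)
    echo["stages"] = list(echo["stages"])
    (out_dir / "config_echo.json").write_text(json.dumps(echo, indent=1, sort_keys=True))
    return {
        "results": results,
        "survivors": survivors,
        "report": report,
        "combined": combined,
    }
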