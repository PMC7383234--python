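"""Cohort-vs-reference SNP allele-frequency enrichment testing.

The scan asks, per SNP, whether the rare-allele (or carrier) count observed
in a phenotyped cohort deviates from the count expected at the population
reference frequency.  Deviation is assessed with a two-tailed chi-square
test with Yates continuity correction, either as a 2x2 contingency test
against the reference cohort (when its size is known) or as a one-sample
goodness-of-fit test against expected counts.  Raw p-values are adjusted
over the whole tested set with both Bonferroni and Benjamini-Hochberg FDR,
and candidate SNPs are then reduced through an annotation filter cascade
(significance -> protein-changing -> gene-set -> ortholog conservation ->
artifact flags).  A discovery and a replication cohort can be pooled into a
single combined carrier-enrichment test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CONSEQUENCES",
    "PROTEIN_CHANGING",
    "ARTIFACT_FLAGS",
    "SNPRecord",
    "ChiSqResult",
    "CombinedCohortResult",
    "CascadeReport",
    "ScanConfig",
    "expected_carrier_count",
    "yates_chisq_gof",
    "yates_chisq_2x2",
    "bonferroni_adjust",
    "bh_fdr",
    "snp_scan",
    "filter_cascade",
    "combine_cohorts",
    "DEFAULT_STAGES",
]

CONSEQUENCES = frozenset(
    {
        "missense_deleterious",
        "missense_tolerated",
        "nonsense",
        "splice",
        "start_loss",
        "inframe_indel",
        "synonymous",
        "other",
    }
)

#: Consequence classes counted as clear-cut protein changing.
PROTEIN_CHANGING = frozenset(
    {"missense_deleterious", "nonsense", "splice", "start_loss", "inframe_indel"}
)

ARTIFACT_FLAGS = frozenset({"none", "allele_calling_error", "homolog_misalignment"})


@dataclass(frozen=True)
class SNPRecord:
    """One SNP's cohort counts, coverage, reference frequency and annotations."""

    snp_id: str
    gene: str = ""
    consequence: str = "other"
    in_gene_set: bool = False
    ortholog_common_flag: bool = False
    artifact_flag: str = "none"
    n_assessed: int = 0
    rare_allele_count: int = 0
    carrier_count: int = 0
    ref_freq: float | None = None
    ref_freq_kind: str = "allele"
    ref_cohort_size: int | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.artifact_flag not in ARTIFACT_FLAGS:
            raise ValueError(f"unknown artifact_flag {self.artifact_flag!r}")
        if self.ref_freq_kind not in ("allele", "carrier"):
            raise ValueError(f"ref_freq_kind must be 'allele' or 'carrier'")
        if self.n_assessed < 0 or self.rare_allele_count < 0 or self.carrier_count < 0:
            raise ValueError("counts must be nonnegative")
        if self.carrier_count > self.n_assessed:
            raise ValueError("carrier_count exceeds n_assessed")
        if self.rare_allele_count > 2 * self.n_assessed:
            raise ValueError("rare_allele_count exceeds 2 * n_assessed")
        if self.rare_allele_count < self.carrier_count:
            raise ValueError("rare_allele_count below carrier_count")
        if self.ref_freq is not None and not 0.0 <= self.ref_freq <= 1.0:
            raise ValueError("ref_freq outside [0, 1]")


@dataclass(frozen=True)
class ChiSqResult:
    """Chi-square statistic with layout and two-tailed p-value (df = 1)."""

    chi2: float
    df: int
    p_two_tail: float
    layout: str  # "goodness_of_fit" | "contingency_2x2"
    expected_counts: tuple[float, ...]


@dataclass(frozen=True)
class CombinedCohortResult:
    """Pooled discovery + replication carrier test against a reference."""

    carriers: int
    n: int
    expected_carriers: float
    chisq: ChiSqResult


@dataclass(frozen=True)
class CascadeStage:
    name: str
    n_in: int
    n_out: int
    removed_snp_ids: tuple[str, ...]


@dataclass
class CascadeReport:
    """Per-stage survivor counts of the annotation filter cascade."""

    stages: list[CascadeStage] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "removed_snp_ids": ";".join(s.removed_snp_ids),
                }
                for s in self.stages
            ]
        )


def expected_carrier_count(n: float, carrier_freq: float) -> float:
    """Expected number of rare-allele carriers among ``n`` individuals.

    Returned unrounded; one-decimal display rounding is the caller's concern
    (``158 * 0.0072 = 1.1376`` displays as 1.1).
    """
    if not 0.0 <= carrier_freq <= 1.0:
        raise ValueError(f"carrier_freq {carrier_freq} outside [0, 1]")
    if n < 0:
        raise ValueError("n must be nonnegative")
    return n * carrier_freq


def _yates_term(observed: float, expected: float) -> float:
    # Continuity-corrected deviation, floored at zero when |O - E| < 0.5.
    return max(abs(observed - expected) - 0.5, 0.0)


def yates_chisq_gof(
    observed: tuple[float, float], expected: tuple[float, float]
) -> ChiSqResult:
    """Yates-corrected goodness-of-fit chi-square on a pair of counts.

    chi2 = sum_i (|O_i - E_i| - 0.5)^2 / E_i with the corrected deviation
    floored at zero; df = 1; two-tailed p from the chi-square upper tail.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != (2,) or e.shape != (2,):
        raise ValueError("observed and expected must each hold two counts")
    if np.any(e <= 0):
        raise ValueError("degenerate input: expected counts must be positive")
    if not math.isclose(o.sum(), e.sum(), rel_tol=1e-6, abs_tol=1e-6):
        raise ValueError("observed and expected totals differ")
    chi2 = float(sum(_yates_term(oi, ei) ** 2 / ei for oi, ei in zip(o, e)))
    return ChiSqResult(
        chi2=chi2,
        df=1,
        p_two_tail=float(stats.chi2.sf(chi2, 1)),
        layout="goodness_of_fit",
        expected_counts=tuple(e),
    )


def yates_chisq_2x2(table) -> ChiSqResult:
    """Yates-corrected chi-square on a 2x2 table [[a, b], [c, d]].

    chi2 = N (|ad - bc| - N/2)^2 / [(a+b)(c+d)(a+c)(b+d)], the corrected
    cross-product deviation floored at zero; df = 1.  Cells may be
    nonnegative reals (unrounded reference counts are allowed).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    (a, b), (c, d) = t
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise ValueError("degenerate input: zero marginal")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2 * n
    chi2 = float(num / (rows[0] * rows[1] * cols[0] * cols[1]))
    expected = tuple((np.outer(rows, cols) / n).ravel())
    return ChiSqResult(
        chi2=chi2,
        df=1,
        p_two_tail=float(stats.chi2.sf(chi2, 1)),
        layout="contingency_2x2",
        expected_counts=expected,
    )


def bonferroni_adjust(p) -> np.ndarray:
    """Bonferroni family-wise adjustment: p * m, capped at 1, order kept."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="bonferroni")[1]


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScanConfig:
    """Configuration for :func:`snp_scan`.

    min_coverage
        Minimum per-SNP number of assessed individuals; records below it are
        skipped (counted in the cascade's coverage stage).
    small_expected_floor
        Records with expected rare count below this are still tested but
        flagged ``small_expected`` in the output.
    layout
        "auto" uses the 2x2 contingency test whenever the reference cohort
        size is known and falls back to goodness-of-fit otherwise; "gof" or
        "2x2" force one layout ("2x2" errors on missing reference size).
    ref_kind_override
        When set ("allele"/"carrier"), overrides each record's declared
        reference-frequency kind.
    """

    min_coverage: int = 1
    small_expected_floor: float = 0.5
    layout: str = "auto"
    ref_kind_override: str | None = None

    def __post_init__(self) -> None:
        if self.layout not in ("auto", "gof", "2x2"):
            raise ValueError("layout must be 'auto', 'gof' or '2x2'")
        if self.ref_kind_override not in (None, "allele", "carrier"):
            raise ValueError("ref_kind_override must be None, 'allele' or 'carrier'")


def _scan_one(row: pd.Series, config: ScanConfig) -> dict | None:
    kind = config.ref_kind_override or row["ref_freq_kind"]
    n = int(row["n_assessed"])
    if kind == "allele":
        trials = 2 * n
        observed = float(row["rare_allele_count"])
    else:
        trials = n
        observed = float(row["carrier_count"])
    if trials <= 0:
        return None
    freq = float(row["ref_freq"])
    expected = trials * freq
    ref_size = row.get("ref_cohort_size")
    has_ref = ref_size is not None and np.isfinite(ref_size) and ref_size > 0
    layout = config.layout
    if layout == "2x2" and not has_ref:
        raise ValueError(f"{row['snp_id']}: layout '2x2' needs ref_cohort_size")
    use_2x2 = has_ref if layout == "auto" else layout == "2x2"
    if use_2x2:
        ref_trials = (2 if kind == "allele" else 1) * float(ref_size)
        ref_rare = ref_trials * freq
        chisq = yates_chisq_2x2(
            [[observed, trials - observed], [ref_rare, ref_trials - ref_rare]]
        )
    else:
        if expected <= 0 or expected >= trials:
            return None
        chisq = yates_chisq_gof(
            (observed, trials - observed), (expected, trials - expected)
        )
    return {
        "observed": observed,
        "expected": expected,
        "chi2": chisq.chi2,
        "p": chisq.p_two_tail,
        "layout": chisq.layout,
        "small_expected": expected < config.small_expected_floor,
    }


def snp_scan(records: pd.DataFrame, config: ScanConfig | None = None) -> pd.DataFrame:
    """Test every SNP's observed rare count against its reference frequency.

    ``records`` carries one row per SNP with the columns of the SNP-table
    dialect (see :mod:`nocistat.tables`).  Returns one row per input SNP;
    rows that could not be tested (missing reference frequency, coverage
    below the configured minimum, or degenerate expectations) have
    ``tested == False`` and NaN statistics.  Bonferroni and BH corrections
    are computed over the set of SNPs actually tested in this run.
    """
    config = config or ScanConfig()
    columns = [
        "snp_id", "tested", "observed", "expected", "chi2", "p", "layout",
        "small_expected", "skip_reason", "p_bonferroni", "q_bh",
    ]
    if records.empty:
        return pd.DataFrame(columns=columns)
    out_rows = []
    for _, row in records.iterrows():
        base = {
            "snp_id": row["snp_id"],
            "tested": False,
            "observed": np.nan,
            "expected": np.nan,
            "chi2": np.nan,
            "p": np.nan,
            "layout": "",
            "small_expected": False,
            "skip_reason": "",
        }
        ref_freq = row.get("ref_freq")
        if ref_freq is None or not np.isfinite(ref_freq):
            logger.warning("snp_scan: %s skipped (missing ref_freq)", row["snp_id"])
            base["skip_reason"] = "missing_ref_freq"
        elif int(row["n_assessed"]) < config.min_coverage:
            logger.warning("snp_scan: %s skipped (coverage)", row["snp_id"])
            base["skip_reason"] = "low_coverage"
        else:
            res = _scan_one(row, config)
            if res is None:
                base["skip_reason"] = "degenerate_expected"
            else:
                base.update(res)
                base["tested"] = True
        out_rows.append(base)
    out = pd.DataFrame(out_rows)
    out["p_bonferroni"] = np.nan
    out["q_bh"] = np.nan
    mask = out["tested"].to_numpy()
    if mask.any():
        p = out.loc[mask, "p"].to_numpy()
        out.loc[mask, "p_bonferroni"] = bonferroni_adjust(p)
        out.loc[mask, "q_bh"] = bh_fdr(p)
    # stable ranked order: raw p then snp_id breaks ties deterministically
    out = out.sort_values(["p", "snp_id"], kind="stable", na_position="last")
    return out.reset_index(drop=True)


DEFAULT_STAGES = (
    "significance",
    "protein_changing",
    "gene_set",
    "ortholog",
    "artifact",
)


def _stage_mask(stage: str, merged: pd.DataFrame, alpha: float, use: str) -> pd.Series:
    if stage == "significance":
        col = "q_bh" if use == "q" else "p_bonferroni"
        return merged[col] < alpha
    if stage == "protein_changing":
        return merged["consequence"].isin(PROTEIN_CHANGING)
    if stage == "gene_set":
        return merged["in_gene_set"].astype(bool)
    if stage == "ortholog":
        return ~merged["ortholog_common_flag"].astype(bool)
    if stage == "artifact":
        return merged["artifact_flag"] == "none"
    raise ValueError(f"unknown cascade stage {stage!r}")


def filter_cascade(
    results: pd.DataFrame,
    records: pd.DataFrame,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    alpha: float = 0.05,
    use: str = "q",
) -> tuple[pd.DataFrame, CascadeReport]:
    """Apply the annotation filter cascade, recording counts at every stage.

    Stages run in the given order; each removes the SNPs failing its
    predicate.  ``use`` selects the significance gate column ("q" for BH
    q-values, "bonferroni" for Bonferroni-adjusted p).  Returns the
    surviving results (with a ``filter_trace`` column of ``stage:flag``
    pairs) and the :class:`CascadeReport`.
    """
    if use not in ("q", "bonferroni"):
        raise ValueError("use must be 'q' or 'bonferroni'")
    for stage in stages:
        if stage not in DEFAULT_STAGES:
            raise ValueError(f"unknown cascade stage {stage!r}")
    ann_cols = [
        "snp_id",
        "consequence",
        "in_gene_set",
        "ortholog_common_flag",
        "artifact_flag",
    ]
    merged = results.merge(records[ann_cols], on="snp_id", how="left", validate="1:1")
    merged = merged[merged["tested"]] if "tested" in merged else merged
    trace = {snp: [] for snp in merged["snp_id"]}
    report = CascadeReport()
    current = merged
    for stage in stages:
        keep = _stage_mask(stage, current, alpha, use).fillna(False)
        removed = tuple(current.loc[~keep, "snp_id"])
        for snp, ok in zip(current["snp_id"], keep):
            trace[snp].append(f"{stage}:{'pass' if ok else 'fail'}")
        report.stages.append(
            CascadeStage(stage, len(current), int(keep.sum()), removed)
        )
        current = current[keep]
    survivors = results[results["snp_id"].isin(current["snp_id"])].copy()
    survivors["filter_trace"] = [
        ";".join(trace[snp]) for snp in survivors["snp_id"]
    ]
    return survivors.reset_index(drop=True), report


def combine_cohorts(
    discovery: tuple[int, int],
    replication: tuple[int, int],
    ref_carrier_freq: float,
    ref_cohort_size: int | None = None,
    round_reference: bool = True,
) -> CombinedCohortResult:
    """Pool discovery and replication carriers into one enrichment test.

    ``discovery`` and ``replication`` are ``(carriers, n)`` pairs.  The
    pooled carrier count is tested against the reference carrier frequency:
    a 2x2 contingency test against ``round(ref_carrier_freq *
    ref_cohort_size)`` reference carriers by default (``round_reference=
    False`` keeps the unrounded product), or a goodness-of-fit test when
    the reference cohort size is unknown.
    """
    (c1, n1), (c2, n2) = discovery, replication
    if n1 <= 0 or n2 <= 0:
        raise ValueError("cohort sizes must be positive")
    if not (0 <= c1 <= n1 and 0 <= c2 <= n2):
        raise ValueError("carriers must lie within [0, n]")
    carriers, n = c1 + c2, n1 + n2
    expected = expected_carrier_count(n, ref_carrier_freq)
    if ref_cohort_size is None:
        logger.info("combine_cohorts: no reference cohort size, using goodness-of-fit")
        chisq = yates_chisq_gof(
            (carriers, n - carriers), (expected, n - expected)
        )
    else:
        ref_carriers = ref_carrier_freq * ref_cohort_size
        if round_reference:
            ref_carriers = round(ref_carriers)
        chisq = yates_chisq_2x2(
            [
                [carriers, n - carriers],
                [ref_carriers, ref_cohort_size - ref_carriers],
            ]
        )
    return CombinedCohortResult(
        carriers=carriers, n=n, expected_carriers=expected, chisq=chisq
    )
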