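"""Single-cell qRT-PCR expression calling and co-expression summaries.

A gene is called expressed in a cell when its quantification cycle (Cq)
value is present and strictly below a cycle threshold (default 35).  Cells
qualify for analysis only when the housekeeping gene (internal positive
control, e.g. Gapdh) calls positive; bath-collected negative-control
samples must call negative everywhere or the run is flagged as
contaminated.  Co-expression is summarized per neuron population (e.g.
thoracolumbar TL vs lumbosacral LS) as the percentage of cells positive
for an anchor gene and, among anchor-positive cells, for each partner gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NO_AMP",
    "CqMatrix",
    "CallMatrix",
    "call_positive",
    "qc_cells",
    "make_calls",
    "coexpression_summary",
]

#: Sentinel for "no amplification within the run".
NO_AMP = float("nan")


@dataclass
class CqMatrix:
    """Genes x cells Cq values with population tags and a housekeeping gene.

    ``cq`` rows are genes, columns are cell identifiers; missing
    amplification is NaN.  ``populations`` maps each analysed cell to its
    population tag.  ``control_cells`` lists bath/negative-control columns
    (present in ``cq`` but excluded from summaries).
    """

    cq: pd.DataFrame
    populations: pd.Series
    housekeeping: str
    control_cells: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.housekeeping not in self.cq.index:
            raise ValueError(f"housekeeping gene {self.housekeeping!r} not in matrix")
        analysed = [c for c in self.cq.columns if c not in self.control_cells]
        missing = [c for c in analysed if c not in self.populations.index]
        if missing:
            raise ValueError(f"cells without population tag: {missing[:5]}")
        vals = self.cq.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValueError("Cq values must be positive where present")

    @property
    def analysed_cells(self) -> list[str]:
        return [c for c in self.cq.columns if c not in self.control_cells]


@dataclass
class CallMatrix:
    """Boolean calls (genes x cells) with per-cell QC and a run-level flag."""

    calls: pd.DataFrame
    qc_pass: pd.Series
    populations: pd.Series
    contaminated: bool = False


def call_positive(cq, threshold: float = 35.0):
    """True where a Cq value is present and strictly below ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    arr = np.asarray(cq, dtype=float)
    result = np.isfinite(arr) & (arr < threshold)
    return bool(result) if np.isscalar(cq) or arr.ndim == 0 else result


def qc_cells(m: CqMatrix, threshold: float = 35.0) -> pd.Series:
    """Per-cell QC mask: housekeeping gene must call positive."""
    hk = m.cq.loc[m.housekeeping, m.analysed_cells]
    return pd.Series(call_positive(hk.to_numpy(), threshold), index=hk.index)


def make_calls(m: CqMatrix, threshold: float = 35.0) -> CallMatrix:
    """Apply the Cq threshold and QC to produce a call matrix.

    Calls are defined (and kept) only for QC-passing analysed cells.  Any
    positive call in a bath-control column sets the run-level
    ``contaminated`` flag.
    """
    qc = qc_cells(m, threshold)
    contaminated = False
    if m.control_cells:
        ctrl = m.cq.loc[:, list(m.control_cells)].to_numpy()
        contaminated = bool(call_positive(ctrl, threshold).any())
    cells = [c for c in m.analysed_cells if qc[c]]
    calls = pd.DataFrame(
        call_positive(m.cq.loc[:, cells].to_numpy(), threshold),
        index=m.cq.index,
        columns=cells,
    )
    return CallMatrix(
        calls=calls,
        qc_pass=qc,
        populations=m.populations.loc[cells],
        contaminated=contaminated,
    )


def coexpression_summary(
    calls: CallMatrix,
    anchor: str,
    partners: list[str],
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Anchor prevalence and anchor-conditional partner prevalence.

    For each population: the percentage of QC-passing cells positive for
    ``anchor`` (denominator = population size), then for each partner the
    percentage of anchor-positive cells also positive for it (denominator
    = anchor-positive count).  Percentages are ``round(100 * count /
    denominator)`` to the nearest integer; a zero denominator yields NaN
    (undefined), never 0.
    """
    if anchor not in calls.calls.index:
        raise ValueError(f"anchor gene {anchor!r} not in call matrix")
    pops = populations or sorted(calls.populations.unique())
    rows = []
    for pop in pops:
        cells = calls.populations.index[calls.populations == pop]
        denom = len(cells)
        anchor_pos = [c for c in cells if calls.calls.loc[anchor, c]]
        rows.append(
            {
                "population": pop,
                "gene": anchor,
                "denominator": denom,
                "count": len(anchor_pos),
                "percent": _pct(len(anchor_pos), denom),
            }
        )
        for gene in partners:
            n_pos = int(calls.calls.loc[gene, anchor_pos].sum()) if anchor_pos else 0
            rows.append(
                {
                    "population": pop,
                    "gene": gene,
                    "denominator": len(anchor_pos),
                    "count": n_pos,
                    "percent": _pct(n_pos, len(anchor_pos)),
                }
            )
    return pd.DataFrame(rows)


def _pct(count: int, denom: int) -> float:
    if denom == 0:
        return float("nan")
    return float(round(100.0 * count / denom))
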