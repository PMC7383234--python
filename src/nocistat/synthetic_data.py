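"""Synthetic inputs with the statistical structure each analysis assumes.

Every generator is a pure function of its spec and a seed, and emits the
ground truth alongside the data so downstream tests are closed-loop
(generate -> analyse -> compare to truth):

* genotype cohorts: per-SNP binomial sampling at reference frequencies
  (log-uniform by default), optional spiked enrichment multipliers and
  per-individual coverage dropout;
* two-group Gaussian QST samples at stated (n, mean, SD);
* voltage-clamp sweep families built from the Boltzmann / double-Boltzmann
  / exponential-recovery forms plus ohmic leak and Gaussian noise, and
  paired pre/post-toxin series where the post series lacks one component;
* current-clamp ramp and step traces from a leaky integrate-and-fire (LIF)
  cell (a minimal spiking stand-in, not a biophysical channel model);
* genes x cells Cq matrices with Bernoulli positivity, anchor-conditional
  partner probabilities and an always-positive housekeeping gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_calls import NO_AMP
from .ephys_fits import (
    BoltzmannParams,
    DoubleBoltzmannParams,
    RecoveryFit,
    Sweep,
    SweepSeries,
    boltzmann,
    double_boltzmann,
)

__all__ = [
    "CohortSpec",
    "LIFCell",
    "gen_cohort",
    "gen_qst_groups",
    "gen_activation_series",
    "gen_inactivation_points",
    "gen_recovery_points",
    "gen_sctx_pair",
    "simulate_lif",
    "gen_ramp_trace",
    "gen_step_family",
    "gen_capsaicin_trace",
    "gen_cq_matrix",
]


# ---------------------------------------------------------------------------
# genotype cohorts


@dataclass
class CohortSpec:
    """Study conditions for a synthetic genotyped cohort.

    Defaults mirror a discovery cohort of 100 exomes scanned over a panel
    of SNPs whose reference rare-allele frequencies are log-uniform on
    [1e-4, 0.5].  ``spikes`` maps SNP index -> enrichment multiplier
    (cohort frequency = min(multiplier x reference, 1)).  ``dropout`` is
    the per-individual per-SNP probability of an unusable call.
    """

    n_individuals: int = 100
    n_snps: int = 2000
    freq_range: tuple[float, float] = (1e-4, 0.5)
    freq_dist: str = "loguniform"  # "loguniform" | "uniform"
    spikes: dict[int, float] = field(default_factory=dict)
    dropout: float = 0.0
    kind: str = "carrier"  # "carrier" | "allele"
    ref_cohort_size: int | None = None
    gene_set_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.kind not in ("carrier", "allele"):
            raise ValueError("kind must be 'carrier' or 'allele'")
        if self.freq_dist not in ("loguniform", "uniform"):
            raise ValueError("freq_dist must be 'loguniform' or 'uniform'")
        if any(m < 0 for m in self.spikes.values()):
            raise ValueError("enrichment multipliers must be >= 0")


def gen_cohort(spec: CohortSpec, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic SNP table plus its ground-truth spike labels.

    Carrier mode draws carrier counts Binomial(n_assessed, f) directly
    (all carriers heterozygous); allele mode draws per-individual genotypes
    Binomial(2, f) under Hardy-Weinberg and aggregates allele and carrier
    counts.  Returns ``(records, truth)`` where truth carries the
    generating frequency, multiplier and spike flag per SNP.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.freq_range
    if spec.freq_dist == "loguniform":
        freqs = 10 ** rng.uniform(np.log10(lo), np.log10(hi), spec.n_snps)
    else:
        freqs = rng.uniform(lo, hi, spec.n_snps)
    mult = np.ones(spec.n_snps)
    for idx, m in spec.spikes.items():
        mult[idx] = m
    f_cohort = np.minimum(freqs * mult, 1.0)

    n = spec.n_individuals
    if spec.dropout > 0:
        n_assessed = n - rng.binomial(n, spec.dropout, spec.n_snps)
    else:
        n_assessed = np.full(spec.n_snps, n)

    if spec.kind == "carrier":
        carrier = rng.binomial(n_assessed, f_cohort)
        rare = carrier.copy()  # heterozygous carriers, one rare allele each
    else:
        carrier = np.zeros(spec.n_snps, dtype=int)
        rare = np.zeros(spec.n_snps, dtype=int)
        for i in range(spec.n_snps):
            g = rng.binomial(2, f_cohort[i], n_assessed[i])
            rare[i] = int(g.sum())
            carrier[i] = int((g > 0).sum())

    gene_set = np.zeros(spec.n_snps, dtype=bool)
    gene_set[list(spec.gene_set_indices)] = True
    records = pd.DataFrame(
        {
            "snp_id": [f"snp{i:05d}" for i in range(spec.n_snps)],
            "gene": [f"GENE{i:05d}" for i in range(spec.n_snps)],
            "consequence": "missense_deleterious",
            "in_gene_set": gene_set,
            "ortholog_common_flag": False,
            "artifact_flag": "none",
            "n_assessed": n_assessed,
            "rare_allele_count": rare,
            "carrier_count": carrier,
            "ref_freq": freqs,
            "ref_freq_kind": spec.kind,
            "ref_cohort_size": np.nan if spec.ref_cohort_size is None else spec.ref_cohort_size,
        }
    )
    truth = pd.DataFrame(
        {
            "snp_id": records["snp_id"],
            "ref_freq": freqs,
            "multiplier": mult,
            "is_spiked": mult != 1.0,
        }
    )
    return records, truth


# ---------------------------------------------------------------------------
# QST groups


def gen_qst_groups(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent Gaussian samples at the stated group parameters."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    rng = np.random.default_rng(seed)
    return rng.normal(mean1, sd1, n1), rng.normal(mean2, sd2, n2)


# ---------------------------------------------------------------------------
# voltage-clamp sweep families

E_K = -90.0  # potassium reversal used by the current generators, mV


def gen_activation_series(
    params: BoltzmannParams,
    voltages=np.arange(-80, 41, 10),
    g_max: float = 50.0,
    tail_voltage: float = -60.0,
    step_ms: float = 200.0,
    tail_ms: float = 200.0,
    dt: float = 0.5,
    tau_deact: float = 50.0,
    leak_g: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    holding: float = -90.0,
) -> SweepSeries:
    """Activation protocol: depolarizing steps followed by a fixed tail.

    Step current is the Boltzmann open fraction times g_max (V - E_K) plus
    ohmic leak; the tail current is proportional to the open fraction at
    the step voltage, decaying exponentially at the tail potential.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, step_ms + tail_ms, dt)
    sweeps = []
    for v in np.asarray(voltages, dtype=float):
        a = float(boltzmann(v, params.top, params.v_half, params.slope))
        i = np.where(
            t < step_ms,
            a * g_max * (v - E_K) + leak_g * v,
            a * g_max * (tail_voltage - E_K) * np.exp(-(t - step_ms) / tau_deact)
            + leak_g * tail_voltage,
        )
        i = i + rng.normal(0.0, noise_sd * g_max, i.shape) if noise_sd else i
        sweeps.append(Sweep(command=float(v), time=t.copy(), value=i))
    return SweepSeries(
        protocol="activation",
        sweeps=sweeps,
        holding=holding,
        metadata={
            "tail_start_ms": step_ms,
            "tail_voltage": tail_voltage,
            "truth": params,
        },
    )


def gen_inactivation_points(
    params: BoltzmannParams | DoubleBoltzmannParams,
    voltages=np.linspace(-110, 40, 16),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Steady-state availability points from a (double-)Boltzmann curve.

    Returns rows ``(prepulse_voltage, normalized_test_current)`` drawn from
    the same functional forms the fitters use, so noiseless data are
    recovered exactly.  (Availability is stored in the fitters' ascending
    orientation; plotting against depolarizing prepulse voltage simply
    mirrors the curve.)
    """
    v = np.asarray(voltages, dtype=float)
    if isinstance(params, DoubleBoltzmannParams):
        y = double_boltzmann(
            v,
            params.top,
            params.fraction,
            params.v_half_1,
            params.slope_1,
            params.v_half_2,
            params.slope_2,
        )
    else:
        y = boltzmann(v, params.top, params.v_half, params.slope)
    rng = np.random.default_rng(seed)
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, y.shape)
    return np.column_stack([v, y])


def gen_recovery_points(
    fit: RecoveryFit,
    intervals=np.array([25.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0, 3200.0]),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Recovery-from-inactivation ratios at the given interpulse intervals."""
    t = np.asarray(intervals, dtype=float)
    y = 1.0 - fit.amplitude * np.exp(-t / fit.tau)
    rng = np.random.default_rng(seed)
    if noise_sd:
        y = np.clip(y + rng.normal(0.0, noise_sd, y.shape), 0.0, 1.2)
    return np.column_stack([t, y])


def gen_sctx_pair(
    sensitive: BoltzmannParams,
    resistant: BoltzmannParams,
    voltages=np.arange(-40, 41, 10),
    g_sensitive: float = 45.4,
    g_resistant: float = 40.0,
    step_ms: float = 200.0,
    dt: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SweepSeries, SweepSeries, SweepSeries]:
    """Pre-toxin, post-toxin and true toxin-sensitive step series.

    The pre-toxin current is the sum of a toxin-sensitive component (to be
    recovered by subtraction) and a toxin-resistant component; the
    post-toxin series retains only the resistant component.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, step_ms, dt)
    pre, post, true = [], [], []
    for v in np.asarray(voltages, dtype=float):
        i_sens = float(boltzmann(v, sensitive.top, sensitive.v_half, sensitive.slope))
        i_res = float(boltzmann(v, resistant.top, resistant.v_half, resistant.slope))
        a = i_sens * g_sensitive * (v - E_K) * np.ones_like(t)
        b = i_res * g_resistant * (v - E_K) * np.ones_like(t)
        noise = rng.normal(0.0, noise_sd, t.shape) if noise_sd else 0.0
        pre.append(Sweep(float(v), t.copy(), a + b + noise))
        post.append(Sweep(float(v), t.copy(), b.copy()))
        true.append(Sweep(float(v), t.copy(), a + noise))
    return (
        SweepSeries("step", pre, metadata={}),
        SweepSeries("step", post, metadata={}),
        SweepSeries("step", true, metadata={"sctx_sensitive": True}),
    )


# ---------------------------------------------------------------------------
# leaky integrate-and-fire current clamp


@dataclass(frozen=True)
class LIFCell:
    """Leaky integrate-and-fire cell: V_rest/V_th in mV, R in MOhm, tau in ms.

    A minimal spiking stand-in for a sensory neuron; analytic rheobase for
    a long step is ``(v_th - v_rest) / r`` (pA when R is in GOhm-scaled
    units: R [MOhm] x I [pA] = V [uV], so r is stored as mV/pA).
    """

    v_rest: float = -60.0
    v_th: float = -40.0
    r_mohm: float = 100.0
    tau_ms: float = 10.0
    spike_peak: float = 30.0
    spike_ms: float = 1.0
    refractory_ms: float = 2.0

    @property
    def r_mv_per_pa(self) -> float:
        # 1 MOhm x 1 pA = 1e-6 V = 1e-3 mV
        return self.r_mohm * 1e-3

    @property
    def rheobase_pa(self) -> float:
        return (self.v_th - self.v_rest) / self.r_mv_per_pa


def simulate_lif(
    cell: LIFCell, current: np.ndarray, dt: float, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Euler-integrated LIF membrane voltage under an injected current (pA).

    On threshold crossing a stereotyped spike is painted (linear rise to
    ``spike_peak`` then reset to rest) so that downstream dV/dt + overshoot
    spike detection sees a realistic waveform.
    """
    rng = np.random.default_rng(seed)
    n = len(current)
    v = np.empty(n)
    v[0] = cell.v_rest
    spike_steps = max(int(round(cell.spike_ms / dt)), 1)
    refrac_steps = max(int(round(cell.refractory_ms / dt)), 1)
    i = 1
    while i < n:
        dv = (-(v[i - 1] - cell.v_rest) + cell.r_mv_per_pa * current[i - 1]) / cell.tau_ms
        v[i] = v[i - 1] + dt * dv
        if noise_sd:
            v[i] += rng.normal(0.0, noise_sd * np.sqrt(dt))
        if v[i] >= cell.v_th:
            up = np.linspace(v[i], cell.spike_peak, spike_steps + 1)[1:]
            down = np.linspace(cell.spike_peak, cell.v_rest, spike_steps + 1)[1:]
            wave = np.concatenate([up, down, np.full(refrac_steps, cell.v_rest)])
            stop = min(i + len(wave), n)
            v[i:stop] = wave[: stop - i]
            i = stop
        else:
            i += 1
    return v


def gen_ramp_trace(
    cell: LIFCell,
    i0: float = 0.0,
    i1: float = 1000.0,
    duration_ms: float = 1000.0,
    dt: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Sweep, tuple[float, float, float]]:
    """Voltage response to a linear current ramp (default 0 -> 1 nA in 1 s)."""
    t = np.arange(0.0, duration_ms, dt)
    current = i0 + (i1 - i0) * t / duration_ms
    v = simulate_lif(cell, current, dt, noise_sd, seed)
    return Sweep(command=i1, time=t, value=v), (i0, i1, duration_ms)


def gen_step_family(
    cell: LIFCell,
    i_max: float = 500.0,
    di: float = 10.0,
    step_ms: float = 50.0,
    dt: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SweepSeries:
    """Family of square current steps (default +10 pA increments, 50 ms)."""
    t = np.arange(0.0, step_ms, dt)
    sweeps = []
    for k, amp in enumerate(np.arange(di, i_max + di / 2, di)):
        current = np.full_like(t, amp)
        v = simulate_lif(cell, current, dt, noise_sd, seed + k)
        sweeps.append(Sweep(command=float(amp), time=t.copy(), value=v))
    return SweepSeries("step", sweeps, metadata={"step_ms": step_ms})


def gen_capsaicin_trace(
    responder: bool,
    window: tuple[float, float] = (5000.0, 10000.0),
    total_ms: float = 15000.0,
    dt: float = 10.0,
    amplitude_pa: float = 200.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Voltage-clamp current trace with an optional in-window inward current."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, total_ms, dt)
    i = rng.normal(0.0, noise_sd, t.shape)
    if responder:
        t0, t1 = window
        i[(t >= t0) & (t <= t1)] -= amplitude_pa
    return t, i


# ---------------------------------------------------------------------------
# Cq matrices


def gen_cq_matrix(
    populations: dict[str, int],
    gene_probs: dict[str, float | dict[str, float]],
    cq_means: dict[str, float],
    seed: int,
    housekeeping: str = "Gapdh",
    cq_sd: float = 1.5,
    n_qc_fail: int = 0,
    n_bath_controls: int = 2,
    conditional: dict[str, tuple[str, float, float]] | None = None,
):
    """Genes x cells Cq matrix with known positivity probabilities.

    ``populations`` maps tag -> cell count; ``gene_probs`` maps gene ->
    positivity probability (scalar, or per-population dict).  Positive
    cells draw Gaussian Cq around ``cq_means[gene]`` truncated below 35;
    negatives get the no-amplification sentinel.  The housekeeping gene is
    always positive except in the ``n_qc_fail`` trailing cells of each
    population; ``conditional`` maps gene -> (anchor, p_if_anchor_pos,
    p_if_anchor_neg).  Returns a :class:`~nocistat.expression_calls.CqMatrix`.
    """
    from .expression_calls import CqMatrix

    rng = np.random.default_rng(seed)
    conditional = conditional or {}
    genes = list(dict.fromkeys([housekeeping, *gene_probs, *conditional]))
    columns: list[str] = []
    pop_tags: dict[str, str] = {}
    data: dict[str, np.ndarray] = {}

    def draw_cq(gene: str) -> float:
        mean = cq_means.get(gene, 25.0)
        val = rng.normal(mean, cq_sd)
        while val >= 35.0 or val <= 0:
            val = rng.normal(mean, cq_sd)
        return val

    for pop, n_cells in populations.items():
        for j in range(n_cells):
            cell = f"{pop}:{j:03d}"
            columns.append(cell)
            pop_tags[cell] = pop
            col = {}
            qc_fail = j >= n_cells - n_qc_fail
            col[housekeeping] = NO_AMP if qc_fail else draw_cq(housekeeping)
            pos: dict[str, bool] = {}
            for gene, prob in gene_probs.items():
                if gene == housekeeping:
                    continue
                p = prob[pop] if isinstance(prob, dict) else prob
                pos[gene] = rng.random() < p
            for gene, (anchor, p_pos, p_neg) in conditional.items():
                p = p_pos if pos.get(anchor, False) else p_neg
                pos[gene] = rng.random() < p
            for gene, is_pos in pos.items():
                col[gene] = draw_cq(gene) if is_pos else NO_AMP
            data[cell] = np.array([col.get(g, NO_AMP) for g in genes])

    controls = []
    for j in range(n_bath_controls):
        cell = f"bath:{j:03d}"
        columns.append(cell)
        controls.append(cell)
        data[cell] = np.full(len(genes), NO_AMP)

    cq = pd.DataFrame({c: data[c] for c in columns}, index=pd.Index(genes, name="gene"))
    pops = pd.Series(pop_tags)
    return CqMatrix(
        cq=cq,
        populations=pops,
        housekeeping=housekeeping,
        control_cells=tuple(controls),
    )
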