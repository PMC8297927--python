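"""Plasmid persistence analytics and the serial-batch-transfer simulator.

Quantities measured in plasmid experimental evolution:

* **loss frequency** ``F`` — fraction of plasmid-free colonies after an
  overnight assay, and the **per-generation segregational loss rate**
  ``lambda`` obtained by inverting the neutral loss model
  ``F = 1 - (1 - lambda)^g`` over ``g`` growth generations;
* **relative fitness** ``w`` — ratio of Malthusian parameters of a
  plasmid-carrying strain versus a plasmid-free competitor in a pairwise
  competition over one growth cycle;
* **plasmid copy number** (PCN) — plasmid amplicons per chromosomal
  amplicon from efficiency-corrected ddCt qPCR;
* **growth rate** ``r`` — from a logistic fit to OD600 time series;
* **serial-transfer dynamics** — the frequency of plasmid hosts across
  repeated grow/dilute cycles under segregational loss, selection against
  the host, and (optionally) death of plasmid-free cells when the plasmid is
  essential; observed through a replica-plating layer.

The deterministic per-generation recursion for the plasmid-host frequency
``p`` is::

    p' = w*p*(1-lam) / (w*p*(1-lam) + w*p*lam*s + (1-p)),   s = 0 if essential else 1

which for ``w = 1`` and non-essential plasmids collapses to
``p_g = p0*(1-lam)^g``.  The stochastic simulator is the finite-population
counterpart (branching growth, binomial segregational loss, binomial
bottleneck) whose mean converges to the recursion for large bottlenecks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


# ---------------------------------------------------------------------------
# Loss assays
# ---------------------------------------------------------------------------

@dataclass
class LossAssay:
    """Colony counts from one overnight plasmid-loss assay."""

    n_total: int
    n_resistant: int
    generations: float = 8.5  # overnight growth, ~12 h

    def __post_init__(self) -> None:
        if not 0 <= self.n_resistant <= self.n_total:
            raise ValueError("need 0 <= n_resistant <= n_total")
        if self.generations <= 0:
            raise ValueError("generations must be positive")


def loss_frequency_estimate(assay: LossAssay) -> tuple[float, float]:
    """Loss frequency (plasmid-free colonies / total) and its binomial SE."""
    if assay.n_total == 0:
        raise ValueError("no colonies tested")
    f = (assay.n_total - assay.n_resistant) / assay.n_total
    se = math.sqrt(f * (1.0 - f) / assay.n_total)
    return f, se


def per_generation_loss_rate(frequency: float, generations: float) -> float:
    """Invert ``F = 1 - (1-lam)^g`` for the per-division loss rate lam."""
    if not 0.0 <= frequency < 1.0:
        raise ValueError("frequency must be in [0, 1)")
    if generations <= 0:
        raise ValueError("generations must be positive")
    return 1.0 - (1.0 - frequency) ** (1.0 / generations)


def expected_plasmid_frequency(p0: float, lambda_loss: float, w: float,
                               generations: float, essential: bool = False,
                               ) -> float:
    """Deterministic plasmid-host frequency after ``generations`` of growth.

    Iterates the per-generation recursion; a fractional final generation
    uses the per-unit-generation rates ``w**frac`` and
    ``1-(1-lam)**frac``, so the ``w = 1`` closed form
    ``p0*(1-lam)**g`` holds for real-valued ``g`` as well.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    if not 0.0 <= lambda_loss <= 1.0:
        raise ValueError("lambda_loss must be in [0, 1]")
    if w <= 0 or generations < 0:
        raise ValueError("w must be positive and generations non-negative")

    def step(p: float, lam: float, wg: float) -> float:
        s = 0.0 if essential else 1.0
        num = wg * p * (1.0 - lam)
        den = wg * p * (1.0 - lam) + wg * p * lam * s + (1.0 - p)
        return num / den if den > 0 else 0.0

    p = p0
    whole, frac = int(generations), generations - int(generations)
    for _ in range(whole):
        p = step(p, lambda_loss, w)
    if frac > 0:
        p = step(p, 1.0 - (1.0 - lambda_loss) ** frac, w ** frac)
    return p


# ---------------------------------------------------------------------------
# Replica plating observation
# ---------------------------------------------------------------------------

def replica_plating_observe(p_true: float, n_colonies: int = 500,
                            rng: np.random.Generator | None = None,
                            seed: int | None = None,
                            adaptive: bool = True, n_max: int = 1000) -> float:
    """Observed plasmid-host frequency from replica plating ~n colonies.

    Binomial sampling of plated colonies; when the first estimate falls
    below 0.5 the plating is adaptively topped up to ``n_max`` colonies,
    mirroring the practice of plating more cells at low plasmid frequency.
    """
    if not 0.0 <= p_true <= 1.0:
        raise ValueError("p_true must be in [0, 1]")
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    k = rng.binomial(n_colonies, p_true)
    n = n_colonies
    if adaptive and k / n < 0.5 and n < n_max:
        extra = n_max - n
        k += rng.binomial(extra, p_true)
        n = n_max
    return k / n


# ---------------------------------------------------------------------------
# Serial batch transfer
# ---------------------------------------------------------------------------

@dataclass
class TransferParams:
    """Configuration of the serial-transfer evolution experiment.

    Defaults mirror the standard protocol: 1:100,000 daily dilution (about
    16.6 regrowth generations per cycle), 23 transfers, replica plating of
    ~500 colonies every 7 transfers.
    """

    dilution: float = 1e-5
    n_transfers: int = 23
    lambda_loss: float = 0.0
    w: float = 1.0
    essential: bool = False
    p0: float = 1.0
    plating_n: int = 500
    report_every: int = 7
    n_saturation: float = 1e9
    generations_per_transfer: float | None = None  # default: log2(1/dilution)
    rescue_transfers: tuple = ()  # antibiotic-rescue cycles: plasmid-free -> 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.dilution < 1.0:
            raise ValueError("dilution must be in (0, 1)")
        if not 0.0 <= self.lambda_loss <= 1.0:
            raise ValueError("lambda_loss must be in [0, 1]")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")
        if self.w <= 0:
            raise ValueError("w must be positive")
        if self.n_transfers < 1:
            raise ValueError("n_transfers must be >= 1")

    @property
    def generations(self) -> float:
        if self.generations_per_transfer is not None:
            return self.generations_per_transfer
        return math.log2(1.0 / self.dilution)


@dataclass
class TransferTrajectory:
    """Per-transfer plasmid-host frequency, true and replica-plating-observed."""

    transfers: np.ndarray            # 0 .. n_transfers
    p_true: np.ndarray
    p_observed: np.ndarray           # NaN at unreported transfers
    cumulative_generations: np.ndarray
    extinct: bool = False
    params: TransferParams | None = None

    def frame(self):
        import pandas as pd

        return pd.DataFrame({
            "transfer": self.transfers,
            "p_true": self.p_true,
            "p_observed": self.p_observed,
            "cumulative_generations": self.cumulative_generations,
        })


def _grow_stochastic(n_plus: int, n_minus: int, generations: float,
                     lam: float, w: float, essential: bool,
                     rng: np.random.Generator) -> tuple[int, int]:
    """Branching growth for ``generations`` doublings of the reference type."""

    def one_generation(npls: int, nmin: int, lam_g: float, w_g: float,
                       factor: float) -> tuple[int, int]:
        off_plus = rng.poisson(factor * w_g * npls) if npls > 0 else 0
        lost = rng.binomial(off_plus, lam_g) if off_plus > 0 else 0
        keep_plus = off_plus - lost
        off_minus = rng.poisson(factor * nmin) if nmin > 0 else 0
        if not essential:
            off_minus += lost  # segregants join the plasmid-free pool
        return keep_plus, off_minus

    whole, frac = int(generations), generations - int(generations)
    for _ in range(whole):
        n_plus, n_minus = one_generation(n_plus, n_minus, lam, w, 2.0)
    if frac > 0:
        n_plus, n_minus = one_generation(
            n_plus, n_minus, 1.0 - (1.0 - lam) ** frac, w ** frac, 2.0 ** frac)
    return n_plus, n_minus


def simulate_serial_transfer(params: TransferParams,
                             mode: str = "stochastic") -> TransferTrajectory:
    """Simulate the serial-transfer experiment.

    Stochastic mode tracks integer plasmid-carrying / plasmid-free cell
    counts through regrowth (Poisson offspring weighted by ``w``, binomial
    segregational loss, death-on-loss when the plasmid is essential) and a
    binomial 1:1/dilution bottleneck each cycle; deterministic mode reduces
    to :func:`expected_plasmid_frequency`.  The observation layer applies
    replica plating at transfer 0, every ``report_every``-th transfer and
    the final one.  Total-population extinction truncates the trajectory
    and sets ``extinct``.
    """
    if mode not in ("stochastic", "deterministic"):
        raise ValueError("mode must be 'stochastic' or 'deterministic'")
    rng = np.random.default_rng(params.seed)
    g = params.generations
    n0 = int(round(params.n_saturation * params.dilution))
    t = np.arange(params.n_transfers + 1)
    p_true = np.full(params.n_transfers + 1, np.nan)
    p_obs = np.full(params.n_transfers + 1, np.nan)
    cumgen = t * g
    extinct = False

    reported = {0, params.n_transfers} | {
        k for k in range(params.n_transfers + 1)
        if params.report_every and k % params.report_every == 0}

    if mode == "deterministic":
        p = params.p0
        p_true[0] = p
        for k in range(1, params.n_transfers + 1):
            if k in params.rescue_transfers:
                p = 1.0 if p > 0 else p
            p = expected_plasmid_frequency(p, params.lambda_loss, params.w, g,
                                           params.essential)
            p_true[k] = p
        p_obs = p_true.copy()
        return TransferTrajectory(t, p_true, p_obs, cumgen, False, params)

    n_plus = int(rng.binomial(n0, params.p0))
    n_minus = n0 - n_plus
    if params.essential:
        n_minus = 0
    p_true[0] = n_plus / max(n_plus + n_minus, 1)
    p_obs[0] = replica_plating_observe(p_true[0], params.plating_n, rng=rng)
    for k in range(1, params.n_transfers + 1):
        if k in params.rescue_transfers:
            n_minus = 0  # one selective transfer kills plasmid-free cells
        if n_plus + n_minus == 0:
            extinct = True
            break
        n_plus, n_minus = _grow_stochastic(
            n_plus, n_minus, g, params.lambda_loss, params.w,
            params.essential, rng)
        grown = n_plus + n_minus
        if grown == 0:
            extinct = True
            break
        # the culture regrows to saturation before each transfer, so the
        # bottleneck draws n_saturation*dilution cells at the grown frequency
        p_grown = n_plus / grown
        n_plus = int(rng.binomial(n0, p_grown))
        n_minus = n0 - n_plus
        p_true[k] = n_plus / n0
        if k in reported:
            p_obs[k] = replica_plating_observe(p_true[k], params.plating_n, rng=rng)
    return TransferTrajectory(t, p_true, p_obs, cumgen, extinct, params)


# ---------------------------------------------------------------------------
# Relative fitness
# ---------------------------------------------------------------------------

def relative_fitness(count_a_t0: float, count_a_tf: float,
                     count_b_t0: float, count_b_tf: float) -> float:
    """Relative fitness w = ln(A_f/A_0) / ln(B_f/B_0) (Malthusian ratio).

    A is the focal (plasmid-carrying) strain, B the reference competitor.
    """
    for c in (count_a_t0, count_a_tf, count_b_t0, count_b_tf):
        if c <= 0:
            raise ValueError("all counts must be positive")
    if count_b_tf <= count_b_t0:
        raise ValueError("reference strain must grow over the interval")
    return math.log(count_a_tf / count_a_t0) / math.log(count_b_tf / count_b_t0)


# ---------------------------------------------------------------------------
# qPCR copy number
# ---------------------------------------------------------------------------

@dataclass
class QpcrSample:
    """Paired Ct values for the plasmid and chromosomal amplicons."""

    ct_target: float   # plasmid amplicon (e.g. nptII)
    ct_ref: float      # chromosomal single-copy amplicon (e.g. idnT)
    eff_target: float = 2.0
    eff_ref: float = 2.0

    def __post_init__(self) -> None:
        if self.ct_target < 0 or self.ct_ref < 0:
            raise ValueError("Ct values must be non-negative")
        for e in (self.eff_target, self.eff_ref):
            if not 1.0 < e <= 2.0:
                raise ValueError("amplification efficiencies must be in (1, 2]")


def pcn_ddct(sample: QpcrSample) -> float:
    """Plasmid copy number by the efficiency-corrected comparative-Ct method.

    Template amount scales as ``eff**(-Ct)``, so
    ``PCN = eff_ref**ct_ref / eff_target**ct_target``; with equal
    efficiencies this is ``eff**(ct_ref - ct_target)``.
    """
    return (sample.eff_ref ** sample.ct_ref
            / sample.eff_target ** sample.ct_target)


def pcn_summary(values) -> dict:
    """Median and coefficient of variation (sample sd / mean) of PCN values."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 PCN values")
    mean = float(np.mean(v))
    if mean == 0:
        raise ValueError("mean PCN is zero; CV undefined")
    return {
        "median": float(np.median(v)),
        "mean": mean,
        "cv": float(np.std(v, ddof=1) / mean),
        "n": int(v.size),
    }


# ---------------------------------------------------------------------------
# Logistic growth
# ---------------------------------------------------------------------------

def logistic(t, K, r, n0):
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - n0) / n0) * np.exp(-r * t))


@dataclass
class LogisticFit:
    K: float
    r: float
    n0: float
    rmse: float
    n_points: int
    converged: bool = True


def fit_logistic(times, od, max_restarts: int = 6) -> LogisticFit:
    """Least-squares logistic fit N(t) = K / (1 + ((K-N0)/N0) e^{-rt}).

    Multi-start Levenberg-Marquardt over a grid of growth-rate guesses;
    raises on flat series or non-convergence after all restarts.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.size != y.size or t.size < 5:
        raise ValueError("need >= 5 matching time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.ptp(y) < 1e-6:
        raise ValueError("flat OD series: logistic parameters unidentifiable")
    if np.any(y <= 0):
        raise ValueError("OD values must be positive")

    k0 = float(np.max(y)) * 1.05
    n00 = max(float(y[0]), 1e-6)
    # crude early-phase rate guess from the steepest log-OD increment
    with np.errstate(divide="ignore"):
        slopes = np.diff(np.log(y)) / np.diff(t)
    r_guess = float(np.nanmax(slopes)) if np.any(np.isfinite(slopes)) else 0.5
    guesses = [max(r_guess, 1e-3)] + [0.1, 0.3, 0.5, 1.0, 2.0][:max_restarts - 1]

    best: LogisticFit | None = None
    for r0 in guesses:
        try:
            popt, _ = curve_fit(
                logistic, t, y, p0=[k0, r0, n00],
                bounds=([1e-9, 1e-9, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=20000, xtol=1e-13, ftol=1e-13)
        except (RuntimeError, ValueError):
            continue
        resid = y - logistic(t, *popt)
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        fit = LogisticFit(K=float(popt[0]), r=float(popt[1]), n0=float(popt[2]),
                          rmse=rmse, n_points=int(t.size))
        if best is None or fit.rmse < best.rmse:
            best = fit
    if best is None:
        raise RuntimeError("logistic fit failed to converge after restarts")
    return best
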