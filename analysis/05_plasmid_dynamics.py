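"""Plasmid-stability experiments in silico.

Runs the quantitative analyses of the experimental-evolution arm on
synthetic readouts:

1. overnight loss assays for an unstable plasmid (segregational loss rate
   lambda ~ 0.027 per division, i.e. ~21% loss over ~8.5 generations) and
   a stabilized variant;
2. serial-transfer evolution (1:100,000 daily dilution, 23 transfers) for
   the unstable/stable plasmid in a dispensable-plasmid host and in a host
   whose survival requires the plasmid;
3. pairwise competitions recovering the relative fitness of ancestral
   (w = 0.69) and evolved (w = 0.93) plasmid carriers;
4. efficiency-corrected ddCt copy-number estimates for ancestral (high,
   variable PCN) and evolved (low PCN) populations;
5. logistic growth-curve fits recovering the wild-type growth rate
   (r = 0.42 per hour).

Usage: python analysis/05_plasmid_dynamics.py [--seed 0]
"""

import argparse

import numpy as np
import pandas as pd

from analysis_util import results_dir, say
from plasmidess import (
    LossAssay, TransferParams, fit_logistic, loss_frequency_estimate,
    pcn_ddct, pcn_summary, per_generation_loss_rate, relative_fitness,
    simulate_serial_transfer,
)
from plasmidess.synth import (
    generate_competition_data, generate_growth_curve, generate_qpcr_data,
)

LAMBDA_UNSTABLE = 0.0274   # per-division segregational loss, unstable plasmid
LAMBDA_STABLE = 0.0005
OVERNIGHT_GENERATIONS = 8.5


def loss_assays(seed: int) -> None:
    rng = np.random.default_rng(seed)
    say("-- overnight loss assays (6 replicates each) --")
    rows = []
    for name, lam in (("unstable", LAMBDA_UNSTABLE), ("stable", LAMBDA_STABLE)):
        freqs = []
        for rep in range(6):
            p_free = 1.0 - (1.0 - lam) ** OVERNIGHT_GENERATIONS
            n_total = 300
            n_res = n_total - int(rng.binomial(n_total, p_free))
            f, se = loss_frequency_estimate(
                LossAssay(n_total, n_res, OVERNIGHT_GENERATIONS))
            freqs.append(f)
            rows.append({"plasmid": name, "replicate": rep, "n_total": n_total,
                         "n_resistant": n_res, "loss_frequency": f, "se": se})
        mean_f = float(np.mean(freqs))
        lam_hat = per_generation_loss_rate(mean_f, OVERNIGHT_GENERATIONS)
        say(f"  {name}: loss {mean_f:.1%} -> lambda = {lam_hat:.4f} "
            f"per division (planted {lam})")
    pd.DataFrame(rows).to_csv(results_dir() / "loss_assays.tsv", sep="\t",
                              index=False)


def evolution_experiment(seed: int) -> None:
    say("-- serial-transfer evolution (23 transfers, 1:100,000) --")
    trajs = []
    for host, essential in (("dispensable", False), ("essential", True)):
        for name, lam in (("unstable", LAMBDA_UNSTABLE),
                          ("stable", LAMBDA_STABLE)):
            params = TransferParams(lambda_loss=lam, essential=essential,
                                    seed=seed)
            traj = simulate_serial_transfer(params)
            df = traj.frame()
            df.insert(0, "plasmid", name)
            df.insert(0, "host", host)
            trajs.append(df)
            final = traj.p_true[-1]
            say(f"  {host} host, {name} plasmid: final host frequency "
                f"{final:.3g} after ~{traj.cumulative_generations[-1]:.0f} "
                f"generations")
    pd.concat(trajs).to_csv(results_dir() / "transfer_trajectories.tsv",
                            sep="\t", index=False)


def competitions(seed: int) -> None:
    say("-- pairwise competitions vs plasmid-free wild type --")
    rows = []
    for pop, w_true in (("ancestral", 0.69), ("evolved", 0.93)):
        df = generate_competition_data(w_true, n0_each=2000, generations=10,
                                       plating_noise=True, seed=seed,
                                       n_replicates=4)
        ws = [relative_fitness(r.count_a_t0, r.count_a_tf,
                               r.count_b_t0, r.count_b_tf)
              for r in df.itertuples()]
        say(f"  {pop}: w = {np.mean(ws):.2f} "
            f"(4 replicates, planted {w_true})")
        rows.append({"population": pop, "w_mean": float(np.mean(ws)),
                     "w_sd": float(np.std(ws, ddof=1)), "w_planted": w_true})
    pd.DataFrame(rows).to_csv(results_dir() / "competitions.tsv", sep="\t",
                              index=False)


def copy_number(seed: int) -> None:
    say("-- plasmid copy number (efficiency-corrected ddCt, n = 9) --")
    rows = []
    for pop, pcn_true, spread in (("ancestral", 20.0, 0.5),
                                  ("evolved", 2.0, 0.25)):
        rng = np.random.default_rng(seed + hash(pop) % 1000)
        values = []
        for rep in range(9):
            pcn_rep = float(pcn_true * np.exp(rng.normal(0.0, spread)))
            (s,) = generate_qpcr_data(pcn_rep, eff_target=1.95, eff_ref=1.93,
                                      ct_noise_sd=0.1,
                                      seed=int(rng.integers(2**31 - 1)))
            values.append(pcn_ddct(s))
        summ = pcn_summary(values)
        rows.append({"population": pop, **summ})
        say(f"  {pop}: median PCN {summ['median']:.1f}, CV {summ['cv']:.2f}")
    df = pd.DataFrame(rows)
    df.to_csv(results_dir() / "copy_number.tsv", sep="\t", index=False)
    fold = df.loc[0, "median"] / df.loc[1, "median"]
    say(f"  median PCN decreased {fold:.1f}-fold over the experiment")


def growth_curves(seed: int) -> None:
    say("-- logistic growth fits (24 h OD600) --")
    t = np.linspace(0.0, 24.0, 49)
    rows = []
    for strain, (K, r, n0) in (("wild_type", (1.0, 0.42, 0.01)),
                               ("plasmid_carrier", (0.95, 0.36, 0.01))):
        fits = []
        for rep in range(3):
            od = generate_growth_curve(K, r, n0, noise_sd=0.005, times=t,
                                       seed=seed + rep)
            fits.append(fit_logistic(t, od))
        r_hat = float(np.mean([f.r for f in fits]))
        say(f"  {strain}: r = {r_hat:.3f} per hour (planted {r})")
        rows.append({"strain": strain, "r_mean": r_hat,
                     "K_mean": float(np.mean([f.K for f in fits])),
                     "r_planted": r})
    pd.DataFrame(rows).to_csv(results_dir() / "growth_fits.tsv", sep="\t",
                              index=False)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    loss_assays(args.seed)
    evolution_experiment(args.seed)
    competitions(args.seed)
    copy_number(args.seed)
    growth_curves(args.seed)


if __name__ == "__main__":
    main()
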