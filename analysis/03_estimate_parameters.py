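"""Two-stage parameter estimation on the synthetic campaign.

Runs the full estimation chain — temperature stage (70 cardinal grid
starts), light stage (1,000 lattice starts), final multi-experiment ODE
fit — and compares the recovered parameters with the generating truth.
With ``--jackknife`` it adds the delete-2 uncertainty analysis
(C(15,2) = 105 warm-started refits; takes several minutes).

Writes results/estimates.json and a campaign-results CSV.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from algrow.dataprep import calibrate_experiment, prepare_experiment, reorganize_datasets
from algrow.estimate import (
    build_search_range,
    combine_candidates,
    estimate_temperature_stage,
    final_estimate,
    jackknife_delete2,
)
from algrow.io import read_campaign
from algrow.model import GrowthParameters
from algrow.reactor import pilot_reactor, photon_supply_density
from algrow.simulate import euler_at_times, mape, productivity
from algrow.synthetic import reference_parameters

ROOT = Path(__file__).resolve().parent.parent
MANIFEST = ROOT / "scratch" / "campaign" / "manifest.yaml"
RESULTS = ROOT / "results"


def main(jackknife: bool = False) -> None:
    geometry = pilot_reactor()
    truth = reference_parameters()
    experiments = read_campaign(MANIFEST)
    for e in experiments:
        calibrate_experiment(e)
    prepared = [prepare_experiment(e, geometry) for e in experiments]
    pooled = pd.concat(prepared, ignore_index=True)
    srange = build_search_range(pooled["T_C"], pooled["mu_bar"], pooled["q_ph"])
    clusters = reorganize_datasets(prepared)

    temp_cands = estimate_temperature_stage(clusters, srange)
    print(f"temperature stage: {len(temp_cands)} converged runs, best "
          f"J = {temp_cands[0].J_temperature:.3e}")
    candidates = combine_candidates(
        temp_cands, srange, q_ph_labels=[c.q_ph for c in clusters]
    )
    for i, c in enumerate(candidates, 1):
        print(f"  initial candidate {i}: mu_max={c.mu_max:.2f} K={c.K_S_ph:.2f} "
              f"m={c.m_ph:.3f} T=({c.T_min:.1f}, {c.T_opt:.1f}, {c.T_max:.1f})")

    fit = final_estimate(experiments, candidates, geometry, max_iter=1000, restarts=2)
    est = fit.params
    print(f"final fit: J = {fit.J:.4e} from {fit.n_starts} starts")
    print(f"{'parameter':8s} {'true':>8s} {'estimate':>9s}")
    for name in GrowthParameters.PARAM_NAMES:
        print(f"{name:8s} {getattr(truth, name):8.3f} {getattr(est, name):9.3f}")

    S = photon_supply_density(geometry)
    pr_meas, pr_mod, rows = [], [], []
    for e, c0 in zip(experiments, fit.c_X0):
        c = e.biomass()
        span = e.times[-1] - e.times[0]
        sim = euler_at_times(c0, e.times, e.temperature, est.as_vector(), S)
        pr_meas.append(productivity(c[0], c[-1], span))
        pr_mod.append(productivity(sim[0], sim[-1], span))
        rows.append(
            {
                "experiment": e.experiment_id, "t_cyc_d": e.t_cyc,
                "c_x0_hat_gpl": round(float(c0), 3),
                "pr_data_gpld": round(pr_meas[-1], 3),
                "pr_model_gpld": round(pr_mod[-1], 3),
                "ape_pct": round(mape([pr_meas[-1]], [pr_mod[-1]]), 1),
            }
        )
    overall_mape = mape(pr_meas, pr_mod)
    print(f"campaign MAPE = {overall_mape:.1f}% "
          f"(mean Pr measured {np.mean(pr_meas):.2f}, modeled {np.mean(pr_mod):.2f})")

    report = {
        "parameters": {n: getattr(est, n) for n in GrowthParameters.PARAM_NAMES},
        "true_parameters": {n: getattr(truth, n) for n in GrowthParameters.PARAM_NAMES},
        "J": fit.J,
        "mape_pct": overall_mape,
    }

    if jackknife:
        print("delete-2 jackknife over 15 experiments (105 refits)...")

        def refit(subset):
            sub = final_estimate(
                subset, [est.as_vector()], geometry, max_iter=400, restarts=1
            )
            return sub.params.as_vector()

        jk = jackknife_delete2(experiments, refit)
        sigma = dict(zip(GrowthParameters.PARAM_NAMES, map(float, jk["sigma"])))
        report["jackknife_sigma"] = sigma
        report["jackknife_ci95"] = {
            n: [float(lo), float(hi)]
            for n, lo, hi in zip(GrowthParameters.PARAM_NAMES, *jk["ci95"])
        }
        covered = {
            n: bool(lo <= getattr(truth, n) <= hi)
            for n, (lo, hi) in report["jackknife_ci95"].items()
        }
        report["ci_covers_truth"] = covered
        print("jackknife sigma:", {k: round(v, 3) for k, v in sigma.items()})
        print("CI covers generating value:", covered)

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "estimates.json").write_text(json.dumps(report, indent=2))
    pd.DataFrame(rows).to_csv(RESULTS / "campaign_fit.csv", index=False)


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--jackknife", action="store_true")
    main(**vars(ap.parse_args()))
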