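"""Prepare the campaign for estimation.

Calibrates the per-experiment OD -> dry-weight correlations, computes
the smoothed central-difference growth rates, pools all experiments and
reorganizes them into the q_ph cluster datasets that the temperature
stage of the initial estimation fits.  Writes the cluster datasets and
the pooled search-range inputs under results/.
"""

from pathlib import Path

import pandas as pd

from algrow.dataprep import calibrate_experiment, prepare_experiment, reorganize_datasets
from algrow.estimate import build_search_range
from algrow.io import read_campaign
from algrow.reactor import pilot_reactor

ROOT = Path(__file__).resolve().parent.parent
MANIFEST = ROOT / "scratch" / "campaign" / "manifest.yaml"
RESULTS = ROOT / "results"


def main() -> None:
    geometry = pilot_reactor()
    experiments = read_campaign(MANIFEST)
    for e in experiments:
        calibrate_experiment(e)
    prepared = [prepare_experiment(e, geometry) for e in experiments]
    pooled = pd.concat(prepared, ignore_index=True)

    srange = build_search_range(pooled["T_C"], pooled["mu_bar"], pooled["q_ph"])
    clusters = reorganize_datasets(prepared)

    rows = []
    for c in clusters:
        for T, mu in zip(c.temperatures, c.mu_bar):
            rows.append(
                {"cluster": c.cluster_index, "q_ph": c.q_ph, "T_C": T, "mu_bar": mu}
            )
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "cluster_datasets.csv", index=False)

    print(f"pooled {len(pooled)} growth-rate observations from "
          f"{len(experiments)} experiments")
    print(f"observed T {pooled['T_C'].min():.1f}..{pooled['T_C'].max():.1f} degC, "
          f"q_ph {pooled['q_ph'].min():.2f}..{pooled['q_ph'].max():.2f} mol/(g d)")
    print("search range:", srange.as_dict())
    print(f"{len(clusters)} cluster datasets selected:")
    for c in clusters:
        print(f"  cluster {c.cluster_index:2d}: q_ph={c.q_ph:.3f}, "
              f"{len(c.temperatures)} temperatures spanning {c.t_span:.1f} K")


if __name__ == "__main__":
    main()
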