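"""Penetrance parameter recovery from simulated cohorts.

Simulates 20 replicate cohorts of 200 informative (unascertained,
founder-boosted) families under the digenic model with male penetrance 0.95
and phenocopy rate 0.01, refits the digenic model to each, and tabulates
the recovered penetrance estimates.

Expected outcome: the fitted male penetrance lands within +/-0.05 of 0.95
in at least 90% of replicates, centred on the truth.
"""

import argparse
import statistics
from pathlib import Path

from digenic.inference import FitOptions, fit_model
from digenic.likelihood import ModelFamily
from digenic.simulate import SimConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-replicates", type=int, default=20)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    rows = []
    for k in range(args.n_replicates):
        sim_seed = (args.seed * 100_003 + k) % 2**31
        cohort = simulate_cohort(
            SimConfig(seed=sim_seed, n_families=200, ascertainment="none")
        )
        fit = fit_model(cohort.pedigrees, ModelFamily.DIGENIC_AND, options=FitOptions(seed=k))
        rows.append((sim_seed, fit.mle_params["f_m"], fit.mle_params["eps"]))
        print(f"replicate {k:2d}: fitted f_m = {fit.mle_params['f_m']:.3f}, "
              f"eps = {fit.mle_params['eps']:.4f}")

    with open(OUT / "penetrance_recovery.tsv", "wt") as fh:
        fh.write("sim_seed\tfitted_f_m\tfitted_eps\n")
        for seed, fm, eps in rows:
            fh.write(f"{seed}\t{fm:.6f}\t{eps:.6f}\n")

    fms = [r[1] for r in rows]
    hits = sum(abs(f - 0.95) <= 0.05 for f in fms)
    print(f"\nmedian fitted f_m = {statistics.median(fms):.3f} (truth 0.95); "
          f"{hits}/{len(fms)} replicates within +/-0.05")
    print(f"wrote {OUT / 'penetrance_recovery.tsv'}")


if __name__ == "__main__":
    main()
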