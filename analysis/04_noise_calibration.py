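"""Calibrate the propagated-noise significance framework by simulation.

A double-transformation cycle combines four independent measurements, so
per-measurement noise of sigma log units inflates the ddpAct statistic to a
null standard deviation of 2*sigma. This driver verifies the propagation by
Monte Carlo for both canonical noise levels (0.3 homogeneous, 0.5
heterogeneous), and tabulates the fraction of pure-noise cycles that exceed
the significance threshold 2*sigma (the irreducible false-positive rate of
the thresholding framework) against the closed-form normal tail.

Outputs under results/04_noise/.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from nadd.cycles import simulate_noise_cycles

OUT = Path(__file__).resolve().parents[1] / "results" / "04_noise"
SEED = 7
N_CYCLES = 100_000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    rows = []
    for sigma in (0.3, 0.5):
        na = simulate_noise_cycles(N_CYCLES, sigma, rng)
        t_sig = 2 * sigma
        rows.append({
            "sigma_exp": sigma,
            "n_cycles": N_CYCLES,
            "na_std_empirical": float(na.std()),
            "na_std_theory": 2 * sigma,
            "significant_fraction_pct": float(100 * np.mean(np.abs(na) > t_sig)),
            "normal_tail_pct": float(100 * 2 * (1 - norm.cdf(1.0))),
            "strong_fraction_pct": float(100 * np.mean(np.abs(na) > 2.0)),
            "strong_tail_pct": float(100 * 2 * (1 - norm.cdf(2.0 / (2 * sigma)))),
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "noise_calibration.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print("\nA pure-noise cycle exceeds the 2-sigma significance threshold in"
          " ~31.7% of draws regardless of sigma; 'strong' calls (>2.0 log"
          " units) are rare unless sigma is large.")


if __name__ == "__main__":
    main()
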