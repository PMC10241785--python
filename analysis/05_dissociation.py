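"""The central dissociation: matched mean slopes, diverging pattern codes.

Two noiseless populations with the same mean combination coefficient (0.5)
but different per-unit spreads — tight (SD 0.005, every unit a near-perfect
averager) and wide (SD 0.3, most units far from averaging).  Both produce a
population slope near 0.5, but only the tight population preserves
averaging at the pattern level: with wide coefficients the pair pattern can
no longer be predicted by averaging the single-object patterns, and the
near-unit fraction collapses.  Writes results/dissociation.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pairavg import (
    GeneratorConfig,
    classify_units,
    condition_means,
    generate_dataset,
    noiseless_pattern_averaging,
    normal_coefficient,
    population_slope,
    responsive_unit_mask,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0
N_SUBJECTS = 50


def condition_summary(coeff_sd: float, seed: int) -> dict:
    config = GeneratorConfig(
        n_units=500, n_runs=0, noise_sd=0.0,
        coefficient=normal_coefficient(0.5, coeff_sd), seed=seed,
    )
    slopes, props, rs = [], [], []
    for i in range(N_SUBJECTS):
        ds = generate_dataset(config, i)
        means = condition_means(ds)
        mask = responsive_unit_mask(means, ds.table)
        res = population_slope(means, ds.table, mask)
        slopes.append(res.population_slope)
        props.append(classify_units(res.per_unit_slope).proportion_near)
        rs.append(noiseless_pattern_averaging(means, ds.table, unit_mask=mask).mean_averaged_r)
    return {
        "coefficient_sd": coeff_sd,
        "mean_slope": float(np.mean(slopes)),
        "proportion_near": float(np.mean(props)),
        "pattern_correlation": float(np.mean(rs)),
    }


def main() -> None:
    tight = condition_summary(0.005, SEED)
    wide = condition_summary(0.3, SEED + 1)
    df = pd.DataFrame([tight, wide])
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "dissociation.csv", index=False)

    print(df.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print("\nBoth populations put the mean slope near 0.5, but the wide-"
          "coefficient population hides a broad slope distribution:")
    print(f"  near-unit fraction {wide['proportion_near']:.2f} vs "
          f"{tight['proportion_near']:.2f}, pattern correlation "
          f"{wide['pattern_correlation']:.3f} vs {tight['pattern_correlation']:.4f}")
    print(f"wrote {RESULTS / 'dissociation.csv'}")


if __name__ == "__main__":
    main()
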