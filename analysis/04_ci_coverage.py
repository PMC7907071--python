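"""Calibration of the delta-method RERI interval under a null generator.

Simulates 1,000 case-control tables from a generator whose stratum odds
ratios satisfy exact additivity (OR11 = OR10 + OR01 - 1, true RERI = 0) at
2,000 subjects per arm and reports how often the 95% delta-method interval
covers zero; a calibrated interval should land near 95%.

Writes results/ci_coverage.tsv.
"""

import argparse
from pathlib import Path

import numpy as np

from addinter import SyntheticCohortSpec, delta_ci, sample_joint_table


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--reps", type=int, default=1000)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    spec = SyntheticCohortSpec(
        control_joint_distribution={(0, 0): 0.40, (0, 1): 0.25, (1, 0): 0.25, (1, 1): 0.10},
        stratum_ors=(2.0, 2.0, 3.0),  # true RERI = 0
        n_cases=2000,
        n_controls=2000,
        matching="none",
        seed=args.seed,
    )
    rng = np.random.default_rng(args.seed)
    covered = 0
    for _ in range(args.reps):
        lo, hi = delta_ci(sample_joint_table(spec, rng=rng)).reri
        covered += lo <= 0.0 <= hi
    pct = 100.0 * covered / args.reps

    out = args.outdir / "ci_coverage.tsv"
    out.write_text(
        "quantity\tvalue\n"
        f"reps\t{args.reps}\n"
        f"n_per_arm\t{spec.n_cases}\n"
        f"coverage_pct\t{pct:.1f}\n",
        encoding="utf-8",
    )
    print(f"delta-method 95% RERI interval: {pct:.1f}% coverage "
          f"({covered}/{args.reps} replicates, n={spec.n_cases}/arm)")


if __name__ == "__main__":
    main()
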