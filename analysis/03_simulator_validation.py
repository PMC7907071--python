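"""Validate the synthetic-cohort generator against its analytic truth.

Three checks: (1) the analytic expected tables return the specified stratum
odds ratios exactly; (2) a full generated cohort at 100,000 per arm, using
the published family-history x diabetes control distribution and stratum
ORs as truth, recovers the joint OR and RERI within 2%; (3) the estimation
error shrinks with sample size (median over 20 replicate seeds along
n = 1e3, 1e4, 1e5).

Writes results/simulator_validation.tsv.
"""

import argparse
from pathlib import Path

import numpy as np

from addinter import (
    SyntheticCohortSpec,
    expected_tables,
    generate_cohort,
    joint_odds_ratios,
    run_interaction_analysis,
    sample_joint_table,
    table2_control_distribution,
    true_measures,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    spec = SyntheticCohortSpec(
        control_joint_distribution=table2_control_distribution(),
        stratum_ors=(4.354, 4.505, 16.537),
        n_cases=100_000,
        n_controls=100_000,
        matching="none",
        seed=args.seed,
    )
    truth = true_measures(spec)
    rows = []

    or01, or10, or11 = (e.point for e in joint_odds_ratios(expected_tables(spec)))
    rows.append(["expected_table_identity",
                 f"max_abs_error={max(abs(or01 - 4.354), abs(or10 - 4.505), abs(or11 - 16.537)):.2e}"])

    records = generate_cohort(spec)
    m = run_interaction_analysis(records, "family_history", "diabetes", ci_method=None)
    rows.append(["recovered_or11", f"{m.or11.point:.3f} (truth 16.537)"])
    rows.append(["recovered_reri", f"{m.reri:.3f} (truth {truth['reri']:.3f})"])
    rows.append(["rel_error_reri", f"{abs(m.reri - truth['reri']) / truth['reri']:.4f}"])

    for n in (1_000, 10_000, 100_000):
        errors = []
        for rep in range(20):
            rng = np.random.default_rng(args.seed * 1000 + rep)
            joint = sample_joint_table(spec, rng=rng, n_cases=n, n_controls=n)
            o01, o10, o11 = (e.point for e in joint_odds_ratios(joint))
            errors.append(abs((o11 - o10 - o01 + 1) - truth["reri"]))
        rows.append([f"median_abs_reri_error_n{n}", f"{np.median(errors):.4f}"])

    out = args.outdir / "simulator_validation.tsv"
    out.write_text("\n".join("\t".join(r) for r in rows) + "\n", encoding="utf-8")
    for r in rows:
        print("\t".join(r))


if __name__ == "__main__":
    main()
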