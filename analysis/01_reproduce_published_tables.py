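"""Recompute every published stratum odds ratio from its printed counts.

Runs the reproduction pipeline over the six packaged cross-classifications
(family history against diabetes and five lifestyle exposures), compares
each computed odds ratio with the printed one at the printed precision, and
writes the full side-by-side report.  Thirteen of the eighteen printed odds
ratios reproduce exactly; the five known-inconsistent cells are flagged.

Writes results/published_tables_report.tsv and .txt.
"""

import argparse
from pathlib import Path

from addinter import render_report, reproduce_paper, write_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    bundle = reproduce_paper()
    write_report(bundle, args.outdir / "published_tables_report.tsv", "tsv")
    write_report(bundle, args.outdir / "published_tables_report.txt", "text")

    n_match = sum(c.matches for t in bundle.tables for c in t.cells)
    n_flagged = sum(c.known_inconsistent for t in bundle.tables for c in t.cells)
    print(render_report(bundle, "text"))
    print(f"matched printed ORs: {n_match}/18; flagged inconsistent cells: {n_flagged}")
    assert all(t.all_consistent_match for t in bundle.tables)


if __name__ == "__main__":
    main()
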