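#!/usr/bin/env python
"""Cohort summary table: group sizes and missing/removed-data statistics.

The outcome partition (normal / NCU / VEND / FSB, perinatal = VEND ∪ FSB,
unlabeled excluded) with per-group mean ± sd of per-episode missing-data
and removed-data percentages. Writes results/summary.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import default_cohort, make_parser

from fhrtrend.cohort import summary_table


def main() -> None:
    args = make_parser(__doc__).parse_args()
    _, _, cleaneds, partition = default_cohort(args.seed)
    table = summary_table(cleaneds, partition)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "summary.csv", index=False)
    print(table.to_string(index=False))
    print(f"wrote {args.out / 'summary.csv'}")


if __name__ == "__main__":
    main()
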