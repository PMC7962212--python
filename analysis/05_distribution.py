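#!/usr/bin/env python
"""Windowed FHR probability densities: 30-min snapshots and 10-min surface.

Estimates the normalized-histogram pdf (1-bpm bins, 50-200 bpm) of each
outcome group in 30-min windows over the last 90 min — where the spread
grows and the perinatal-mortality peak shifts down — and the 10-min
pdf-over-time surface with its falling episode-support curve. Writes
results/pdf_long.csv and results/pdf_windows.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import default_cohort, group_members, make_parser

from fhrtrend.distribution import pdf_surface, surface_long_table
from fhrtrend.trend import window_partition

GROUPS = [
    ("normal", "s1_normal"),
    ("ncu", "s2_ncu"),
    ("perinatal", "s3_perinatal"),
]


def main() -> None:
    args = make_parser(__doc__).parse_args()
    _, _, cleaneds, partition = default_cohort(args.seed)
    args.out.mkdir(parents=True, exist_ok=True)

    longs, sides = [], []
    for delta in (600.0, 1800.0):
        windows = window_partition(9000.0, delta)
        for label, key in GROUPS:
            members = group_members(cleaneds, partition, key)
            if not members:
                continue
            pdfs, counts = pdf_surface(members, windows, group=label)
            long_df, side_df = surface_long_table(pdfs, counts)
            long_df.insert(1, "delta_s", delta)
            side_df.insert(1, "delta_s", delta)
            longs.append(long_df)
            sides.append(side_df)
    pd.concat(longs, ignore_index=True).to_csv(
        args.out / "pdf_long.csv", index=False
    )
    side = pd.concat(sides, ignore_index=True)
    side.to_csv(args.out / "pdf_windows.csv", index=False)

    for label, key in GROUPS:
        members = group_members(cleaneds, partition, key)
        if not members:
            continue
        pdfs, _ = pdf_surface(members, window_partition(9000.0, 1800.0), label)
        msg = ", ".join(
            f"{int(-p.window.start_s / 60)}-{int(-p.window.end_s / 60)} min: "
            f"peak {p.peak_bin()} bpm, sigma2 {p.variance:.0f}"
            for p in pdfs[-3:] if p is not None
        )
        print(f"{label}: {msg}")
    print(f"wrote {args.out / 'pdf_long.csv'} and pdf_windows.csv")


if __name__ == "__main__":
    main()
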