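#!/usr/bin/env python
"""Estimate the leukaemia-donor cell fraction from marker reads.

Builds a 24-marker two-donor panel with 10 informative markers, simulates
marker-specific read counts for a 90% leukaemia-donor mixture at depth
1,000 per marker, and estimates the donor fraction as the mean of
per-marker donor-specific read proportions.
"""

import argparse
from pathlib import Path

from shieldseq.chimerism import estimate_donor_fraction, select_informative_markers
from shieldseq.io import write_table
from shieldseq.simulate import demo_marker_panel, simulate_chimerism_reads


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--fraction", type=float, default=0.9)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    panel = select_informative_markers(demo_marker_panel(24, 10, seed=args.seed))
    n_inf = int(panel["informative"].sum())
    print(f"panel: {len(panel)} markers, {n_inf} informative for this donor pair")

    counts = simulate_chimerism_reads(args.fraction, n_markers=n_inf, depth=1000, seed=args.seed)
    est = estimate_donor_fraction(counts)
    write_table(est.per_marker, str(args.outdir / "chimerism_per_marker.csv"))
    print(f"true fraction {args.fraction:.3f}, estimate {est.fraction:.3f} "
          f"(per-marker s.d. {est.sd:.3f}, {est.n_markers} markers)")
    print(f"wrote {args.outdir / 'chimerism_per_marker.csv'}")


if __name__ == "__main__":
    main()
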