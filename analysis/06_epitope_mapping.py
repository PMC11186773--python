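#!/usr/bin/env python
"""Map antibody epitope residues from a simulated alanine scan.

Plants epitopes for three antibodies on a synthetic binding matrix
(residual binding as % of wild type), calls candidate residues with the
<=20% / >70% rule, excludes global-loss variants, and prioritises the
candidates with structural annotations (cysteine, PTM/interface, burial).
"""

import argparse
from pathlib import Path

import pandas as pd

from shieldseq.epitope import call_epitope_residues, prioritize_residues
from shieldseq.io import write_table
from shieldseq.simulate import simulate_binding_matrix

EPITOPES = {"BC8": ["E259", "H285", "N286"], "HI30": ["N230", "K234"], "MIRG451": ["N351", "K352"]}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    residues = [f"T{300 + i}" for i in range(40)] + [r for rs in EPITOPES.values() for r in rs]
    matrix = simulate_binding_matrix(residues, list(EPITOPES), EPITOPES, seed=args.seed)
    calls = call_epitope_residues(matrix)
    for mab, cands in calls.candidates.items():
        print(f"{mab}: candidates {sorted(cands)} (planted {sorted(EPITOPES[mab])})")
    print(f"excluded as global loss: {calls.excluded}")

    annotations = pd.DataFrame(
        {
            "surface_accessibility": [60.0] * len(residues),
            "is_cysteine": [False] * len(residues),
            "ptm_or_interface": [False] * len(residues),
        },
        index=pd.Index(residues, name="residue"),
    )
    # mimic known structural caveats: one buried candidate, one PTM site
    annotations.loc["N230", "surface_accessibility"] = 4.0
    annotations.loc["N286", "ptm_or_interface"] = False
    prioritized = prioritize_residues(calls.all_candidates(), annotations)
    write_table(prioritized, str(args.outdir / "epitope_prioritized.csv"))
    print(prioritized.to_string(index=False))
    print(f"wrote {args.outdir / 'epitope_prioritized.csv'}")


if __name__ == "__main__":
    main()
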