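#!/usr/bin/env python
"""Quantify window alleles from the simulated reads.

Aligns the reads from 01_simulate_reads.py to the reference amplicon,
extracts the quantification window (centre -10, size 15 relative to the
protospacer 3' end) and writes the allele frequency table, pooling
alleles below 0.8% into 'other'.
"""

import argparse
from pathlib import Path

from shieldseq.allele_quant import build_allele_table, read_fastq, write_allele_table
from shieldseq.geometry import WindowSpec, resolve_window
from shieldseq.simulate import demo_geometry


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/simulated"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    amplicon, proto, _ = demo_geometry("K352")
    window = resolve_window(WindowSpec(center_offset=-10, size=15), proto, amplicon)
    reads = read_fastq(str(args.indir / "reads.fastq"))
    table = build_allele_table(reads, amplicon, proto, window)
    write_allele_table(table, str(args.outdir / "alleles.tsv"), sample="sim_k352")

    print(f"window {window[0]}-{window[1]} (amplicon coords), {table.total_reads} reads kept")
    print(f"filters: {table.filter_log.as_dict()}")
    print(table.df.to_string(index=False))
    print(f"wrote {args.outdir / 'alleles.tsv'}")


if __name__ == "__main__":
    main()
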