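#!/usr/bin/env python
"""Optional: re-run the full analysis on the original deposited arrays.

The study's data-dependent numbers — 62.7% / 59.1% present rates, the 87
shared probe sets (49 down / 38 up), per-gene fold changes and the GSEA
p-values — can only be recomputed from the original MAS5 exports of GEO
series GSE9545 (samples GSM241642-GSM241660; Mouse Genome 430A for
Experiment 1 and 430 2.0 for Experiment 2) together with the two curated
gene-set collections. None of that material ships with this package, so
this script is NOT part of the test suite; it documents how a user holding
the data would reproduce those numbers.

Expected layout under --data-dir (the package's standard TSV formats; a
MAS5 export or GEO series matrix converts with a few lines of pandas —
probe x sample signal and detection-call matrices plus a sample->group
table):

    exp1/signals.tsv  exp1/calls.tsv  exp1/samples.tsv
    exp2/signals.tsv  exp2/calls.tsv  exp2/samples.tsv
    early_dev.gmt     stem_cell.gmt   (optional, enables GSEA)

Usage:
    python scripts/reproduce_gse9545.py --data-dir DIR [--out DIR]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path


def main() -> int:
    parser = argparse.ArgumentParser(
        description=__doc__,
        formatter_class=argparse.RawDescriptionHelpFormatter,
    )
    parser.add_argument("--data-dir", type=Path, required=True,
                        help="directory with the converted GSE9545 matrices")
    parser.add_argument("--out", type=Path, default=Path("gse9545_results"))
    parser.add_argument("--seed", type=int, default=7, help="GSEA permutation seed")
    args = parser.parse_args()

    required = [
        args.data_dir / "exp1" / "signals.tsv",
        args.data_dir / "exp1" / "calls.tsv",
        args.data_dir / "exp1" / "samples.tsv",
        args.data_dir / "exp2" / "signals.tsv",
        args.data_dir / "exp2" / "calls.tsv",
        args.data_dir / "exp2" / "samples.tsv",
    ]
    missing = [p for p in required if not p.is_file()]
    if missing:
        print(
            "error: deposited-array files not found under "
            f"{args.data_dir} (missing e.g. {missing[0]}).\n"
            "Convert the GSE9545 MAS5 exports to the layout in --help first.",
            file=sys.stderr,
        )
        return 3

    from replicaseq.pipeline import PipelineConfig, run_all

    gmts = [p for p in (args.data_dir / "early_dev.gmt",
                        args.data_dir / "stem_cell.gmt") if p.is_file()]
    config = PipelineConfig(
        exp1_dir=str(args.data_dir / "exp1"),
        exp2_dir=str(args.data_dir / "exp2"),
        out_dir=str(args.out),
        gmt_paths=[str(p) for p in gmts],
        seed=args.seed,
    )
    manifest = run_all(config)

    rep = manifest["stages"]["replication"]
    filt = manifest["stages"]["filter"]
    print("present-filtered probes:", filt)
    print("directional intersection:", rep)
    print(f"full tables under {args.out}/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
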