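"""Run the full analysis pipeline on the bundles from 01_generate_data.py.

Writes correlation maps, delay traces, threshold/accumulation tables, and
report.json under results/run/.
"""

import argparse
import json
from pathlib import Path

from scmotor.pipeline import RunConfig, run_full_analysis


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="in_dir", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/run"))
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--variant", default="projected", choices=["projected", "raw"])
    args = ap.parse_args()

    bundles = sorted(p for p in args.in_dir.iterdir() if (p / "trials.csv").exists())
    if not bundles:
        raise SystemExit(f"no session bundles under {args.in_dir}; run 01_generate_data.py first")
    cfg = RunConfig(
        seed=args.seed,
        variant=args.variant,
        out_dir=str(args.out),
        input_dirs=[str(p) for p in bundles],
    )
    report = run_full_analysis(cfg)
    print(json.dumps(report["motor_potential"], indent=2, default=str))
    print(f"tables and report.json written to {args.out}")


if __name__ == "__main__":
    main()
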