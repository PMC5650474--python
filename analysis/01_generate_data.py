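"""Generate the synthetic session bundles used by the downstream drivers.

Writes one bundle directory per neuron/session under results/data/.
"""

import argparse
from pathlib import Path

from scmotor.config import GeneratorConfig
from scmotor.io import write_session
from scmotor.synth import generate_population


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    ap.add_argument("--n-neurons", type=int, default=20)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--config", type=Path, default=None, help="generator config YAML")
    args = ap.parse_args()

    cfg = GeneratorConfig.from_yaml(args.config) if args.config else GeneratorConfig()
    sessions = generate_population(cfg, args.n_neurons, base_seed=args.seed)
    for session in sessions:
        write_session(session, args.out, config=cfg)
    print(f"wrote {len(sessions)} session bundles to {args.out}")


if __name__ == "__main__":
    main()
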