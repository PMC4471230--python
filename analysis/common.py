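"""Shared plumbing for the numbered analysis drivers: one run directory,
one seed, genomes rebuilt deterministically from that seed."""

import argparse
from pathlib import Path


def driver_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--dir", type=Path, default=Path("results/study"))
    args = ap.parse_args()
    args.dir.mkdir(parents=True, exist_ok=True)
    return args
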