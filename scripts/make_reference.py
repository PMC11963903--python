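"""Rebuild the shipped reference fixture (data/reference.json).

Usage:  python scripts/make_reference.py [--out PATH]

Runs the homeostatic pressure-flow-control calibration of the healthy
reference parameterization to steady state and freezes parameters plus
state.  Deterministic: no randomness is involved.
"""
import argparse
from pathlib import Path

from cardioloop.reference import calibrate_reference, write_fixture


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="src/cardioloop/data/reference.json")
    args = ap.parse_args()
    params, state = calibrate_reference()
    write_fixture(args.out, params, state)
    cal = state["calibration"]
    print(f"calibrated in {cal['beats']} beats: "
          f"MAP {cal['p_art_mean_mmHg']:.3f} mmHg, "
          f"VR {cal['q_venous_return_Lmin']:.4f} L/min")
    print(f"wrote {Path(args.out).resolve()}")


if __name__ == "__main__":
    main()
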