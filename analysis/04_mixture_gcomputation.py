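#!/usr/bin/env python
"""Summarize the six-element mixture analysis from the pipeline run.

Reads the quantile-g-computation outputs written by 02_fit_trajectories.py:
per-class risk ratios for a simultaneous one-quartile increase in all six
elements, with bootstrap CIs, and the signed per-element weights.
"""

from pathlib import Path

import pandas as pd

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    if not RUN.exists():
        raise SystemExit("run 02_fit_trajectories.py first")
    for sex in ("male", "female"):
        sdir = RUN / sex
        ep = sdir / "mixture_effects.csv"
        if not ep.exists():
            print(f"{sex}: no mixture results")
            continue
        eff = pd.read_csv(ep)
        w = pd.read_csv(sdir / "mixture_weights.csv")
        print(f"\n=== {sex}: RR per simultaneous one-quartile increase ===")
        cols = [c for c in ("label", "class", "rr", "lo95", "hi95") if c in eff]
        print(eff[cols].round(2).to_string(index=False))
        for cls, grp in w.groupby("label" if "label" in w else "class"):
            top = grp.sort_values("weight", ascending=False).iloc[0]
            print(f"  {cls}: dominant {top['direction']} contributor "
                  f"{top['element']} (weight {top['weight']:.2f})")


if __name__ == "__main__":
    main()
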