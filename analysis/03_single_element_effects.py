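#!/usr/bin/env python
"""Summarize single-element exposure effects from the pipeline run.

Reads the per-sex effect tables written by 02_fit_trajectories.py
(one-step RRRs from within the mixture model, two-stage multinomial
comparators, tertile contrasts, 18-month z-score regressions, and BMI
cross-product screens) and prints the notable associations.
"""

from pathlib import Path

import pandas as pd

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main() -> None:
    if not RUN.exists():
        raise SystemExit("run 02_fit_trajectories.py first")
    for sex in ("male", "female"):
        sdir = RUN / sex
        if not (sdir / "effects.csv").exists():
            print(f"{sex}: no effect tables (model selection failed?)")
            continue
        eff = pd.read_csv(sdir / "effects.csv")
        print(f"\n=== {sex} ===")
        ok = eff.dropna(subset=["estimate"])
        sig = ok[(ok["lo95"] > 1) | (ok["hi95"] < 1)]
        print(f"{len(ok)} estimated contrasts, {len(sig)} excluding 1:")
        cols = ["element", "contrast", "label", "method", "estimate",
                "lo95", "hi95"]
        have = [c for c in cols if c in sig.columns]
        with pd.option_context("display.width", 120):
            print(sig[have].round(2).to_string(index=False) if len(sig)
                  else "  none")
        nc = eff[~eff["converged"]]
        if len(nc):
            print(f"non-converged rows: "
                  f"{sorted(set(zip(nc['element'], nc['method'])))}")
        zp = sdir / "zscore_effects.csv"
        if zp.exists():
            z = pd.read_csv(zp)
            print("18-month z-score slopes per doubling:")
            print(z[["term", "estimate", "lo95", "hi95"]].round(3)
                  .to_string(index=False))
        ip = sdir / "interactions.csv"
        if ip.exists():
            inter = pd.read_csv(ip)
            n_sig = int((inter["p"] < 0.05).sum())
            print(f"BMI cross-product terms with p<0.05: {n_sig} of {len(inter)}")


if __name__ == "__main__":
    main()
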