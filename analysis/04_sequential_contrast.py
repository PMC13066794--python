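#!/usr/bin/env python
"""History-dependent contrast enhancement between sequential odors.

Compares Pearson correlations between a reference odor's ON response and
each context odor's ON response when both are solitary versus when the
reference follows the context odor by half a second (so the context odor's
inverted OFF response overlaps it).  Finding to reproduce: sequential
correlations are systematically lower than solitary ones (paired t-test),
and the effect disappears when the OFF carryover is disabled in the
generator.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from afterimage import synthetic
from afterimage.sequential import sequential_contrast

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

ODORS = ("iaa", "bza", "cit", "oct", "ger")


def run(seed: int, carryover: bool):
    cfg = synthetic.locust_like(
        odors=ODORS, paradigm="sequential_pairs", reference_odor="ger",
        iti_s=12.0, sequential_carryover=carryover, seed=seed)
    sess, _ = synthetic.generate_session(cfg)
    return sequential_contrast(sess, "ger")


def main() -> None:
    comp = run(SEED, carryover=True)
    rows = [{"reference": "ger", "context": c, "corr_solitary": s,
             "corr_sequential": q, "delta": q - s, "condition": "carryover"}
            for c, s, q in comp.pairs]
    null = run(SEED, carryover=False)
    rows += [{"reference": "ger", "context": c, "corr_solitary": s,
              "corr_sequential": q, "delta": q - s, "condition": "no_carryover"}
             for c, s, q in null.pairs]
    RESULTS.mkdir(exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "04_sequential.csv", index=False, float_format="%.4g")

    frac = float(np.mean([(run(SEED + s, True).delta < 0).all()
                          for s in range(10)]))

    print("solitary vs sequential ON-response correlations "
          f"(reference ger, {len(comp.pairs)} context odors):")
    for c, s, q in comp.pairs:
        print(f"  ({c})ger: solitary {s:+.3f} -> sequential {q:+.3f}")
    print(f"paired t-test (one-sided, solitary > sequential): "
          f"p = {comp.test.p_value:.3g}")
    print(f"mean delta with OFF carryover disabled: "
          f"{null.delta.mean():+.3f} (control)")
    print(f"all-pairs suppression reproduced in {frac:.0%} of 10 seeds")
    print(f"table: {RESULTS}/04_sequential.csv")


if __name__ == "__main__":
    main()
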