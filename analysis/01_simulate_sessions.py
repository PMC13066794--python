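#!/usr/bin/env python
"""Generate the synthetic sessions the downstream analyses run on.

Builds one locust-like spike session (solitary blocks), one mouse-like
calcium session, one sequential-pair session and one random-order session,
validates them, writes a dataset summary table to results/, and dumps a
small example session in the text dialect under scratch/sessions/ for
inspection with any CSV/YAML tooling.
"""

import sys
from pathlib import Path

import pandas as pd

from afterimage import synthetic
from afterimage.session import write_session

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

CONFIGS = {
    "locust_solitary": synthetic.locust_like(
        odors=tuple(f"o{i}" for i in range(11)), iti_s=24.0, seed=SEED),
    "mouse_solitary": synthetic.mouse_like(
        n_units=120, iti_s=57.0, seed=SEED + 1),
    "locust_sequential": synthetic.locust_like(
        odors=("iaa", "bza", "cit", "oct", "ger"),
        paradigm="sequential_pairs", reference_odor="ger", iti_s=12.0,
        seed=SEED + 2),
    "mouse_random_order": synthetic.mouse_like(
        n_units=80, odors=tuple(f"o{i}" for i in range(11)),
        paradigm="random_order", on_s=1.0, iti_s=19.0,
        n_random_trials=120, seed=SEED + 3),
}


def main() -> None:
    rows = []
    for name, cfg in CONFIGS.items():
        sess, truth = synthetic.generate_session(cfg)
        sess.validate()
        rows.append({
            "session": name,
            "modality": sess.modality,
            "n_units": sess.n_units(),
            "n_odors": len(sess.odors),
            "n_trials": len(sess.trials),
            "paradigm": cfg.paradigm,
            "on_s": cfg.on_s,
            "iti_s": cfg.iti_s,
            "inversion_gamma": cfg.inversion_gamma,
        })
        print(f"{name}: {sess.modality}, {sess.n_units()} units, "
              f"{len(sess.trials)} trials ({cfg.paradigm})")

    RESULTS.mkdir(exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "01_sessions.csv", index=False)

    demo = synthetic.locust_like(odors=("bza", "nen"), n_units=12,
                                 trials_per_block=3, iti_s=10.0, seed=SEED)
    sess, _ = synthetic.generate_session(demo)
    out = SCRATCH / "sessions" / "locust_demo"
    write_session(sess, out)
    print(f"\nwrote demo session to {out} (session.yaml + activity.csv)")
    print(f"summary table: {RESULTS / '01_sessions.csv'}")


if __name__ == "__main__":
    main()
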