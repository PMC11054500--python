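"""Fit the packaged standardization statistics for the reference
logistic models on a seeded simulated cohort.

The published models report coefficients on standardized inputs but not
the (mean, sd) pairs used to standardize them; this script computes
those pairs on a fixed simulator cohort and writes them to
src/walk6mwt/data/reference_standardization.json. Re-running is fully
deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from walk6mwt.features import extract_features
from walk6mwt.filters import apply_filters
from walk6mwt.models import ERROR_BASED_BINDINGS, USER_BASED_BINDINGS
from walk6mwt.simulate import NoiseConfig, simulate_cohort

COHORT_SEED = 20240408
N_PARTICIPANTS = 8
TESTS_PER_PARTICIPANT = 8

OUT = Path(__file__).resolve().parents[1] / "src" / "walk6mwt" / "data" / (
    "reference_standardization.json"
)


def main() -> None:
    walks = simulate_cohort(
        N_PARTICIPANTS,
        TESTS_PER_PARTICIPANT,
        noise=NoiseConfig(),
        seed=COHORT_SEED,
    )
    needed = sorted(
        {f for b in (ERROR_BASED_BINDINGS, USER_BASED_BINDINGS) for c in b.values() for f in c}
    )
    rows = []
    for w in walks:
        kept = apply_filters(w.trace).kept
        fv = extract_features(kept, w.trace)
        rows.append([fv[f] for f in needed])
    arr = np.asarray(rows)
    doc = {
        "cohort": {
            "seed": COHORT_SEED,
            "n_participants": N_PARTICIPANTS,
            "tests_per_participant": TESTS_PER_PARTICIPANT,
            "n_traces": len(walks),
        },
        "features": {
            f: {"mean": float(arr[:, i].mean()), "sd": float(arr[:, i].std(ddof=1))}
            for i, f in enumerate(needed)
        },
    }
    OUT.write_text(json.dumps(doc, indent=1))
    print(f"wrote {OUT} ({len(needed)} features over {len(walks)} traces)")


if __name__ == "__main__":
    main()
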