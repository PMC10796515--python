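#!/usr/bin/env python
"""Generate the synthetic study cohort.

Draws 40 training patients plus 4 held-out validation patients (one per
response class) from the first-level box prior under the standard six-week
weekday regime, adds measurement noise with (α₁, α₂) = (0.05, 0.10), and
writes the patient/schedule CSVs and a manifest with the ground truth to
results/cohort/.
"""

from pathlib import Path

import gtvpredict as gp
from gtvpredict.io import write_cohort

SEED = 2024
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    prior = gp.PriorSpec()
    noise = gp.NoiseParams(0.05, 0.10)

    training = gp.generate_cohort(40, prior, noise=noise, seed=SEED)
    write_cohort(training, OUT / "training", noise=noise, seed=SEED)

    validation = []
    for k, label in enumerate(gp.CLASS_LABELS):
        pat = gp.generate_patient(
            prior,
            noise=noise,
            seed=SEED + 100 + k,
            target_class=label,
            patient_id=f"holdout_{label.value}",
        )
        validation.append(pat)
    write_cohort(validation, OUT / "validation", noise=noise, seed=SEED + 100)

    counts = {}
    for p in training:
        counts[p.true_class.value] = counts.get(p.true_class.value, 0) + 1
    print(f"wrote {len(training)} training patients to {OUT/'training'}")
    print(f"training true-class counts: {counts}")
    print(f"wrote {len(validation)} class-conditional validation patients")


if __name__ == "__main__":
    main()
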