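#!/usr/bin/env python
"""Simulate the synthetic cohort and write the trial container.

34 individuals, 10 laser pulses at each of 12-15 energy levels (1 J upward
in 0.25 J steps to a per-individual maximum in [3.75, 4.5] J), simulated at
250 Hz. The raw sample arrays go under scratch/ (they are bulky,
regenerable intermediates); the ground-truth profiles and trial metadata are
what the later stages and parameter-recovery checks consume.
"""

from pathlib import Path

from lepnorm import CohortConfig, simulate_cohort
from lepnorm.io import write_trial_container

ROOT = Path(__file__).resolve().parents[1]
CONFIG = CohortConfig(sampling_rate=250.0, seed=42)


def main() -> None:
    trials, profiles = simulate_cohort(CONFIG)
    out = write_trial_container(trials, ROOT / "scratch" / "trials", profiles)
    per_ind = {}
    for t in trials:
        per_ind[t.individual_id] = per_ind.get(t.individual_id, 0) + 1
    counts = sorted(per_ind.values())
    print(f"simulated {len(trials)} trials from {len(profiles)} individuals -> {out}")
    print(f"trials per individual: min {counts[0]}, max {counts[-1]} (expected 120-150)")
    ratings = [t.rating for t in trials]
    print(f"rating range {min(ratings)}-{max(ratings)}; "
          f"high-pain share {sum(r > 4 for r in ratings) / len(ratings):.2f}")


if __name__ == "__main__":
    main()
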