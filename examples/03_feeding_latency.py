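"""Feeding metrics: intake mass and latency to the five-pellet threshold.

Simulates a small Fed vs Fasted48 cohort, prints each animal's intake and
latency to consume five 20 mg pellets (0.1 g), and the fraction of each
group reaching the threshold by trial end.
"""

from ethoseq import (
    cumulative_threshold_curve,
    intake_mass,
    latency_to_threshold,
    simulate_cohort,
)

cohort = simulate_cohort(
    "no_intruder", n_subjects=8, duration_s=1200, seed=3,
    conditions=["Fed", "Fasted48"],
)

for cond in ("Fed", "Fasted48"):
    results = []
    for (subject, c), (etho, log) in sorted(cohort.items()):
        if c != cond:
            continue
        lat = latency_to_threshold(log, subject, threshold_pellets=5, censor_time_s=1200)
        results.append(lat)
        if subject in ("sub00", "sub01"):
            print(
                f"{cond:>9s} {subject}: intake {intake_mass(log, subject):.2f} g, "
                f"latency {lat.latency_s:6.1f} s ({'reached' if lat.reached else 'censored'})"
            )
    times, fracs = cumulative_threshold_curve(results)
    print(f"{cond:>9s}: fraction past threshold at trial end = {fracs[-1]:.2f}\n")
print(
    "Fasted animals reach the 0.1 g homeostatic threshold within minutes;\n"
    "sated animals hover near five pellets and reach it late, if at all."
)
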