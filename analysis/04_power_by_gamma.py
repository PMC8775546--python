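"""Power of the left/right ApEn contrast as the side asymmetry strengthens.

Sweeps the affected-side noise multiplier gamma (1 = symmetric, smaller =
more regular left side), simulating Parkinson's-like cohorts at each value
and recording how often the knee-flexion contrast detects the asymmetry.
"""

from pathlib import Path

import pandas as pd

from kinentropy.calibration import asymmetry_recovery

N_COHORTS = 25
rows = []
for gamma in (0.25, 0.5, 0.75, 1.0):
    res = asymmetry_recovery(n_cohorts=N_COHORTS, base_seed=3000, gamma=gamma)
    rows.append(
        {
            "gamma": gamma,
            "n_cohorts": res.n_cohorts,
            "left_lower_fraction": res.left_lower_fraction,
            "rejection_rate": res.rejection_rate,
        }
    )
    print(
        f"gamma={gamma:.2f}: left more regular in "
        f"{res.left_lower_fraction:.0%} of cohorts, "
        f"significant contrast in {res.rejection_rate:.0%}"
    )

out = Path(__file__).resolve().parents[1] / "results" / "power_by_gamma.csv"
out.parent.mkdir(parents=True, exist_ok=True)
pd.DataFrame(rows).to_csv(out, index=False)
print(f"-> {out}")
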