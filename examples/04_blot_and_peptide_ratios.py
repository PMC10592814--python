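"""Loading-control-normalized blot intensities and peptide abundance ratios.

Normalizes band volumes to their loading control, expresses each lane
relative to the untreated mean, and computes a treated/untreated mean
abundance ratio for a quantified peptide.
"""

import pandas as pd

from fociquant import abundance_ratio, relative_intensity
from fociquant.model import IntensityTable

lanes = pd.DataFrame({
    "lane_id": ["u1", "u2", "u3", "t1", "t2", "t3"],
    "condition": ["untreated"] * 3 + ["cGAMP"] * 3,
    "target_band_volume": [900.0, 1100.0, 1000.0, 3300.0, 2900.0, 3100.0],
    "loading_control_volume": [1000.0, 1020.0, 980.0, 1010.0, 990.0, 1000.0],
})
folds = relative_intensity(IntensityTable(lanes))
print(folds.per_sample.round(3).to_string(index=False))
print(folds.per_condition.round(3).to_string(index=False))
print()

treated = [8.2, 7.5, 8.6]
untreated = [1.0, 1.1, 0.95]
ratio = abundance_ratio(treated, untreated)
print(f"Peptide abundance ratio (treated/untreated means): {ratio:.2f}")
print()
print("Relative intensities divide each loading-control-normalized lane by")
print("the untreated mean, so the untreated condition averages exactly 1;")
print("the abundance ratio is the mean treated signal over the mean")
print("untreated signal for one quantified peptide.")
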