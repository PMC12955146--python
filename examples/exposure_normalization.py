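"""Exposure-normalized comparison of two drugs' raw ADR counts.

Raw report counts mislead when drug usage differs: a drug with 100 reports
from 1000 doses sold is safer per use than one with 50 reports from 100
doses.  Normalizing by an exposure proxy turns counts into per-use rates.
"""

import numpy as np
import pandas as pd

from adrtrend import normalize_by_exposure
from adrtrend.series import ADRSeries

test_drug = ADRSeries("Test", np.array([2020]), np.array([100.0]))
ref_drug = ADRSeries("Reference", np.array([2020]), np.array([50.0]))
exposure = pd.DataFrame(
    {
        "drug": ["Test", "Reference"],
        "year": [2020, 2020],
        "exposure_units": [1000.0, 100.0],  # doses sold
    }
)

for s in (test_drug, ref_drug):
    rate = normalize_by_exposure(s, exposure).annual_counts[0]
    print(f"{s.drug_id:>9}: {s.annual_counts[0]:>5.0f} reports, "
          f"{exposure.set_index('drug').loc[s.drug_id, 'exposure_units']:>6.0f} doses "
          f"-> rate {rate:.2f} reports/dose")

print()
print("Test reports one ADR per ten doses, Reference one per two doses:")
print("despite its higher raw count, Test is the safer per-use profile.")
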