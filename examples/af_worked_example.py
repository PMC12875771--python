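"""Hand-checkable Alkire-Foster worked example on a 4 x 3 toy matrix.

Rows (participants) x columns (indicators): 110, 100, 111, 000.  With equal
weights and cutoff d = 2, participants 1 and 3 are poor (2 and 3
deprivations), so H = 2/4, A = (2/3 + 3/3)/2 = 5/6 and M0 = H*A = 5/12.
"""

import pandas as pd

from sdohmpi import AFConfig, WeightScheme, af_measures, contributions
from sdohmpi.indicators import DeprivationMatrix

matrix = DeprivationMatrix(
    pd.DataFrame(
        [[1, 1, 0], [1, 0, 0], [1, 1, 1], [0, 0, 0]], columns=["i1", "i2", "i3"]
    )
)
scheme = WeightScheme("EIW", pd.Series(1.0, index=["i1", "i2", "i3"]), "count")
config = AFConfig(d=2, weight_scheme=scheme)

result = af_measures(matrix, config)
print(f"H  = {result.H:.4f}   (fraction identified as poor)")
print(f"A  = {result.A:.4f}   (average deprivation share among the poor)")
print(f"M0 = {result.M0:.4f}   (adjusted headcount ratio = H * A)")

table = contributions(matrix, config)
ind = table[table.level == "indicator"]
print("\nindicator contributions to M0 (sum to 1):")
for _, row in ind.iterrows():
    print(f"  {row['name']}: {row['contribution']:.2f}")
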