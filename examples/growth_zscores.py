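"""Growth z-scores (LMS method) and ΔWLZ growth intervals.

Computes weight-for-length z-scores against the packaged (synthetic)
reference table, then the ΔWLZ change across an interval — the growth
exposure used to predict 24-month functional connectivity.
"""

import pandas as pd

from infantfc import LmsTable, delta_wlz, enumerate_intervals, lms_zscore

table = LmsTable.synthetic_fixture()

# one infant measured at birth and 5 months
records = pd.DataFrame([
    {"subject": "sub-001", "visit_label": "birth", "sex": "F",
     "length_cm": 50.0, "weight_kg": 3.20},
    {"subject": "sub-001", "visit_label": "5mo", "sex": "F",
     "length_cm": 64.0, "weight_kg": 6.10},
])
records["wlz"] = [
    table.zscore("weight-for-length", r.sex, r.length_cm, r.weight_kg)
    for r in records.itertuples()]
print(records[["visit_label", "length_cm", "weight_kg", "wlz"]].to_string(index=False))

dw = delta_wlz(records, "birth", "5mo")
print(f"\ndelta WLZ (birth -> 5 mo) = {dw['sub-001']:+.2f}")
print("(later minus earlier: positive = relative growth gain over the interval)")

intervals = enumerate_intervals()
print(f"\n{len(intervals)} ΔWLZ intervals over the 7 canonical visits, e.g. "
      f"{intervals[:3]} ...")

# the LMS transform itself: z=0 at the reference median
print(f"\nLMS check: z at the median = {lms_zscore(10.0, -0.35, 10.0, 0.09):.3f}")
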