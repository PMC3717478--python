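"""Clean a labeled day: non-wear consolidation, wake window, valid-day rule.

Constructs an epoch sequence with a long device-off block containing a
short spurious activity burst, plus a short non-wear episode, and shows
how each rule transforms it.
"""

import numpy as np
import pandas as pd

import actiflux as af
from actiflux.kinds import ActivityKind

EPM = 24  # 2.5 s epochs per minute
SIT, WALK, NW = (ActivityKind.sitting.value, ActivityKind.walk_slow.value,
                 ActivityKind.non_wear.value)

labels = np.concatenate([
    np.full(120 * EPM, SIT),    # 06:00-08:00 sitting
    np.full(40 * EPM, NW),      # device off ...
    np.full(4 * EPM, WALK),     # ... 4 min spurious activity ...
    np.full(40 * EPM, NW),      # ... device off again (84 min block)
    np.full(60 * EPM, WALK),
    np.full(20 * EPM, NW),      # isolated 20 min of "non-wear"
    np.full(8 * 60 * EPM, SIT),
]).astype(np.int8)
epochs = af.LabeledEpochs("c1", "2013-04-08 06:00:00", labels)

window = af.DayWindow("c1", pd.Timestamp("2013-04-08").date(),
                      pd.Timestamp("2013-04-08 07:00:00"),
                      pd.Timestamp("2013-04-08 21:00:00"))
cleaned, wear = af.clean_day(epochs, window)

flags = pd.Series([af.EpochFlag(f).name for f in cleaned.flags]).value_counts()
print("epoch provenance after cleaning:")
print(flags.to_string())
print(f"\nwear time inside wake window: {wear.wear_hours:.2f} h "
      f"-> valid day: {wear.is_valid_day}")
print("\nThe 4 min burst inside the 84 min device-off block was re-classified")
print("as non-wear; the isolated 20 min non-wear run became sedentary time;")
print("epochs before 07:00 fall outside the diary wake window.")
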