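"""Build the five cognitive outcomes from raw test scores.

Generates plausible raw CANTAB-style measures (with some missingness and a
failed accuracy criterion), then applies score reversal, sample z-scoring,
the inclusion rules and composite averaging.
"""

import numpy as np

from timeuse_coda import composites_from_raw
from timeuse_coda.synthetic import generate_cognitive_scores

raw = generate_cognitive_scores(n=12, seed=9, missing_fraction=0.05)
raw.loc[3, "rti_accuracy"] = 0.42  # fails the <50% accuracy criterion

composites = composites_from_raw(raw)
print(composites.round(2).to_string())
print()
print("participant 3 speed composite:",
      "masked (accuracy < 50%)" if np.isnan(composites.loc[3, "speed"]) else "present")
# global_cognition is the raw ACE-III total (0-100); the four domain scores
# are means of component z-scores, blank wherever a component is missing or
# an accuracy rule removed the participant from that composite.
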