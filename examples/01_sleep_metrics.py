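"""Score a simulated full-sleep night and split it at 03:30.

Generates one full-night hypnogram (in bed 23:00-08:00, 30-s epochs),
scores the standard sleep parameters, and compares REM percentage between
the early (23:00-03:30) and late (03:30-08:00) halves of the night.
"""

import numpy as np

from remcpm import generate_hypnogram, rem_metrics, score_sleep_parameters, segment

h = generate_hypnogram("FS", rng=np.random.default_rng(0))
p = score_sleep_parameters(h)
print(f"TST {p.tst_min:.1f} min  SL {p.sl_min:.1f}  WASO {p.waso_min:.1f}  "
      f"SE {p.se_frac:.2f}")
print(f"stage %: N1 {p.pct_n1:.1f}  N2 {p.pct_n2:.1f}  N3 {p.pct_n3:.1f}  "
      f"REM {p.pct_rem:.1f}")

early, late = segment(h, "03:30")
_, pct_early = rem_metrics(early)
_, pct_late = rem_metrics(late)
print(f"REM% early half {pct_early:.1f}  vs late half {pct_late:.1f}")
# The late half should carry clearly more REM: REM pressure rises across
# the night, which is what makes late-night sleep restriction REM-depriving.
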