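"""Why does the fed-batch rate collapse?

Decomposes the instantaneous rate of the heuristic protocol into its
multiplicative factors -- salt-driven promoter occupancy, the pH response,
catalyst dilution, and NTP saturation -- each normalized to t = 0.  Their
product reproduces the normalized rate identically, so the smallest factor
names the dominant cause at any moment.
"""

import numpy as np

from ivtkit.reactor import decompose_rate_decline
from ivtkit.scenarios import make_scenarios

bundle = make_scenarios(seed=0)
res = bundle.simulate("heuristic_fedbatch")
df = decompose_rate_decline(res)

print(f"{'t (min)':>8} {'rate':>6} {'salt/occ':>9} {'pH':>6} "
      f"{'dilution':>9} {'NTP sat':>8}")
for t_min in (0, 30, 60, 90, 120, 150, 180):
    i = int(np.searchsorted(df["time_s"], t_min * 60.0))
    i = min(i, len(df) - 1)
    r = df.iloc[i]
    print(f"{t_min:>8} {r['normalized_rate']:>6.2f} {r['salt_occupancy']:>9.2f} "
          f"{r['pH_response']:>6.2f} {r['catalyst_dilution']:>9.2f} "
          f"{r['ntp_saturation']:>8.2f}")
# Salt-driven occupancy loss is the smallest factor from mid-run onward:
# accumulated counterions, not NTP exhaustion, kill this protocol.
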