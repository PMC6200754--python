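"""Coherence lifetime versus number of collectively coupled nuclei.

Runs the collective model for N = 1..4 identical spin-1/2 nuclei per
radical (hyperfine constant 10 MHz, 47 uT, 300 K) and prints the
degeneracy-weighted coherence lifetime of the singlet-triplet oscillation.
Even N admits a j = 0 nuclear sector whose electrons see no hyperfine
coupling; that sector decoheres only through the slow 1.3 MHz Zeeman
channel, so even-N ensembles keep a long-lived fraction and outlive their
odd-N neighbours.
"""

import numpy as np

from radicalpair import SystemSpec, coherence_lifetime, run_collective

times = np.concatenate([[0.0], np.geomspace(4e-4, 400.0, 400)])

print("N (per radical)   lifetime (s)")
for n in range(1, 5):
    spec = SystemSpec(mode="collective", n1=n, n2=n, lambda_h_hz=1e7)
    tr = run_collective(spec, times)
    print(f"      {n}            {coherence_lifetime(tr):8.3f}")

print("\n(lifetimes fall with N as more transitions open dissipation "
      "channels, but even N -- integer collective spin, including j = 0 -- "
      "decays more slowly than adjacent odd N)")
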