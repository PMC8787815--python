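"""Simulate bulk expression kinetics across a DNA titration.

Runs the full resource-limited model at the bulk-fit parameters for four
plasmid concentrations and prints when each channel plateaus and peaks.
The mRNA signal should level off around ~3 h (transcription resources
exhaust first), protein around ~5 h, and endpoint protein should saturate
near the 3.75 nM template level.
"""

import numpy as np

from cfekit import BULK_MLE, max_rates, simulate

t_grid = np.linspace(0.0, 8.0, 97)
print(f"{'DNA (nM)':>9} {'RNA@8h (nM)':>12} {'protein@8h (nM)':>16} "
      f"{'peak v_tl (nM/h)':>17} {'at (h)':>7}")
for dna in (0.94, 1.875, 3.75, 7.5):
    traj = simulate(BULK_MLE.replace(tau_l=0.0), "V1", dna0=dna, t_grid=t_grid)
    (vtx, t_tx), (vtl, t_tl) = max_rates(traj)
    print(f"{dna:>9.3g} {traj.rna[-1]:>12.0f} {traj.protein_mat[-1]:>16.0f} "
          f"{vtl:>17.0f} {t_tl:>7.2f}")

print("\nTranscription flux always peaks at t = 0 (resources and template")
print("saturation are maximal at the start); translation peaks after enough")
print("transcript has accumulated, and endpoint protein saturates with DNA.")
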