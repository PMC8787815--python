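"""Generate and summarize monodisperse synthetic-cell populations.

Emulates three microfluidic liposome populations (different DNA doses, one
batch) with per-cell radius CV ~0.06 and expression CV ~0.022, summarizes
endpoint distributions, and estimates batch-to-batch variability from a
separate ten-batch run. Population CVs of a few percent are the signature
of uniform encapsulation; batch CVs are typically several-fold larger.
"""

import numpy as np

from cfekit import GeneratorConfig, generate_population, summarize_population
from cfekit.population import batch_cv, max_translation_rate

cfg = GeneratorConfig.population_default(
    dna_levels_nM=(1.75, 3.5, 7.0), n_cells=85, noise_cv=0.0, seed=85,
)
traces = generate_population(cfg)
by_pop: dict[str, list] = {}
for t in traces:
    by_pop.setdefault(t.population_id, []).append(t)

print(f"{'population':>10} {'n':>4} {'radius μm (CV)':>18} "
      f"{'RNA nM (CV)':>18} {'protein nM (CV)':>18}")
for pid, cells in sorted(by_pop.items()):
    s = summarize_population(cells)
    print(f"{pid:>10} {s.n_cells:>4} "
          f"{s.radius_mean:>9.1f} ({s.radius_cv:.3f}) "
          f"{s.rna_mean:>10.0f} ({s.rna_cv:.3f}) "
          f"{s.protein_mean:>10.0f} ({s.protein_cv:.3f})")

batch_cfg = GeneratorConfig.population_default(
    dna_levels_nM=(3.5,), n_cells=40, n_batches=10, batch_cv=0.10,
    noise_cv=0.0, seed=77,
)
by_batch: dict[str, list] = {}
for t in generate_population(batch_cfg):
    by_batch.setdefault(t.batch_id, []).append(t)
means = [np.mean([t.protein_nM[-1] for t in v]) for _, v in sorted(by_batch.items())]
rates = [np.mean([max_translation_rate(t) for t in v])
         for _, v in sorted(by_batch.items())]
cv_ep, cv_mr = batch_cv(means, rates)
print(f"\nbatch-to-batch CV over 10 batches: endpoint protein {cv_ep:.3f}, "
      f"peak translation rate {cv_mr:.3f}")
print("(the generator's batch factor was configured at CV 0.10)")
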