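"""Correlate fecal miRNA abundance with predicted target taxa.

Plants a monotone coupling between one miRNA and one taxon, then tests every
predicted (miRNA, taxon) pair with Spearman correlation (exact permutation p
for small n) the way a Table-2-style report is built.
"""

import numpy as np
import pandas as pd

from gutmir.correlate import correlate_targets
from gutmir.simulate import simulate_mirna
from gutmir.targets import CorrelationTarget

rng = np.random.default_rng(7)
samples = [f"mouse{i}" for i in range(12)]
rel = pd.DataFrame(rng.dirichlet(np.ones(4) * 2.0, size=12), index=samples,
                   columns=["Akkermansia_OTU", "Parabacteroides_OTU",
                            "Clostridium_OTU", "Bacteroides_OTU"])

mc, truth = simulate_mirna(
    n_probes=6, groups={s: "all" for s in samples},
    coupling={("miR-000", "Akkermansia_OTU"): 1,
              ("miR-001", "Parabacteroides_OTU"): -1},
    relabund=rel, seed=7)
counts = pd.DataFrame(mc.counts[:6], index=mc.probe_ids[:6], columns=samples)

targets = [CorrelationTarget(f"miR-{j:03d}", c, "otu", f"gene{j}", 30.2, 4.6)
           for j, c in enumerate(rel.columns)] + [
    CorrelationTarget("miR-001", "Parabacteroides_OTU", "otu", "geneX",
                      32.2, 1.9)]
report = correlate_targets(counts, rel.copy(), rel, targets)
cols = ["mirna_id", "taxon_key", "spearman_rho", "p", "significant"]
print(report[cols].round(3).to_string(index=False))
print(f"\nsignificant pairs: {report.attrs['n_significant']} "
      f"of {len(report)} (n={report.attrs['n_samples']} matched samples)")
# The two planted couplings surface with |rho| near 1; uncoupled pairs do not.
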