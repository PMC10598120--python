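"""Per-window clinical interleaving: the covariates enter every kernel window.

With stride equal to kernel size, each convolution position reads one gene
window plus the full clinical block, so age/sex/etc. participate in every
local feature instead of being appended once at the end.
"""

import numpy as np

import tripletgene as tg
from tripletgene.datasets import ClinicalTable

genes = np.arange(1, 7, dtype=float)      # g1..g6
table = ClinicalTable(["s1"], {"age": ["71"], "marital": ["widowed"]})
clinical, names = tg.encode_clinical(table)
print(f"encoded clinical {names}: {clinical[0]}  (widowed -> +1 by convention)")

row = tg.interleave_clinical(genes, clinical[0], k=3)
print(f"interleaved row (k=3): {row}")
print("layout: [g1 g2 g3 | age marital | g4 g5 g6 | age marital]")

spec = tg.EmbeddingModelSpec(n_genes=6, n_clinical=2, kernel_size=3,
                             embedding_dim=30, init_seed=0)
print(f"conv window = stride = {spec.effective_window} "
      f"(kernel {spec.kernel_size} genes + {spec.n_clinical} clinical)")
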