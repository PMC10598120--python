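"""Online triplet categorization and the strict semi-hard (switching) filter.

Every triplet is easy, semi-hard or hard from its squared distances; the
strict filter additionally requires the triplet to stay semi-hard when anchor
and positive swap roles, discarding triplets whose category is an artifact of
the anchor choice.
"""

import numpy as np

import tripletgene as tg
from tripletgene.triplets import semi_hard_filter

rng = np.random.default_rng(0)
labels = rng.integers(0, 2, 100)
labels[:4] = [0, 0, 1, 1]
ts = tg.build_triplets(labels, n_triplets=10_000, seed=1)
E = rng.standard_normal((100, 30)) * 0.4  # an untrained, diffuse embedding

cats, counts = tg.categorize_all(E, ts, m=0.5)
print(f"easy {counts.easy}, semi-hard {counts.semi_hard}, hard {counts.hard} "
      f"(sum {counts.total})")

semi = semi_hard_filter(E, ts, m=0.5)
strict = tg.strict_semi_hard_filter(E, ts, m=0.5)
print(f"semi-hard {len(semi)} -> strict semi-hard {len(strict)} "
      f"({100 * len(strict) / len(semi):.1f}% survive the switching check)")

swapped = tg.strict_semi_hard_filter(E, ts.swapped(), m=0.5)
print(f"strict set invariant under anchor<->positive swap: "
      f"{np.array_equal(strict, swapped)}")
# The discarded triplets are exactly those whose category flips with the anchor.
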