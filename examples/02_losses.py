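"""Evaluate the triplet, switching, angular and joint losses on toy triplets.

The switching loss is the triplet loss after exchanging anchor and positive:
a triplet whose negative sits close to the *positive* is penalized even when
the plain triplet loss is small.
"""

import numpy as np

import tripletgene as tg

cfg = tg.LossConfig(margin=0.5, alpha=45.0)

# negative close to the positive: mild forward loss, large switched loss
t = tg.EmbeddedTriplet(np.array([0.0, 0.0]), np.array([1.0, 0.0]),
                       np.array([1.1, 0.0]))
print(f"triplet loss   = {tg.triplet_loss(t, cfg):.4f}   (dp2=1, dn2=1.21, m=0.5)")
print(f"switching loss = {tg.switching_loss(t, cfg):.4f}   (from the positive, "
      "the negative is at distance^2 0.01)")

tri = tg.EmbeddedTriplet(np.array([0.0, 0.0]), np.array([2.0, 0.0]),
                         np.array([1.0, 1.0]))
for alpha in (30.0, 45.0):
    a_cfg = tg.LossConfig(margin=0.5, alpha=alpha)
    print(f"angular loss (alpha={alpha:.0f}) = {tg.angular_loss(tri, a_cfg):.4f}")

x = np.array([0.2, -0.7])
collapsed = tg.EmbeddedTriplet(x, x.copy(), x.copy())
print(f"joint loss on a collapsed embedding = {tg.joint_loss(collapsed, cfg):.4f} "
      "(= m + m + 0: both hinges open by exactly the margin)")
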