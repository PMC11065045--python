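"""Anatomy of the self-cross similarity loss and its PU adjustment.

Walks through the loss on a hand-built feature set: tight exemplar
cluster, mostly-dissimilar background features, and one background
feature that is secretly a particle — the situation the
positive-unlabeled (PU) adjustment exists for.
"""

import numpy as np

from maepick import (LossConfig, adjusted_similarities, cross_similarity,
                     scs_loss, self_similarity, similarity_sums, total_loss)

rng = np.random.default_rng(0)
particle_axis = np.array([1.0, 0.2, 0.1, 0.0])
background_axis = np.array([-0.2, 1.0, -0.5, 0.3])

exemplars = particle_axis + 0.05 * rng.normal(size=(5, 4))
background = background_axis + 0.3 * rng.normal(size=(9, 4))
unlabeled = np.vstack([background, particle_axis + 0.05 * rng.normal(size=4)])

s_self = self_similarity(exemplars)
s_cross = cross_similarity(exemplars, unlabeled)
print(f"s_self  (exemplar cohesion)          = {s_self:.3f}")
print(f"s_cross (exemplar vs unlabeled)      = {s_cross:.3f}")

cfg = LossConfig(alpha=0.5, tau=0.05, pi_hat=0.1)
print(f"unadjusted SCS loss                  = {scs_loss(s_cross, s_self, cfg):.3f}")

sums = similarity_sums(exemplars, unlabeled)
s_self_hat, s_cross_hat = adjusted_similarities(sums, cfg.pi_hat)
print(f"PU-adjusted s_self / s_cross         = {s_self_hat:.3f} / {s_cross_hat:.3f}")
print(f"adjusted SCS loss                    = {scs_loss(s_cross_hat, s_self_hat, cfg):.3f}")
print(f"total loss with l_mse=0.20, beta=1   = "
      f"{total_loss(0.20, scs_loss(s_cross_hat, s_self_hat, cfg), 1.0):.3f}")
print("\nThe adjustment discounts the unlabeled set by the assumed particle")
print("fraction pi_hat, so the hidden particle in it is not pushed away as")
print("hard as genuine background.")
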