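"""Explain a trained classifier with integrated gradients.

Attributions are path integrals of the logit gradient from a zero
baseline to each input; their per-site sum must match the logit change
(the completeness axiom), which the completeness gap audits.  The
generator plants the class signal on the first four coordinates, so a
faithful attribution ranks those features on top.
"""

import numpy as np

from ubisite import (attribute_sites, feature_importance_ranking,
                     rank_agreement)
from ubisite.heads import HeadConfig, fit_head
from ubisite.synthetic import SynthSpec, gen_embeddings

spec = SynthSpec(n_pos=100, n_neg=500, dim=32, effect_size=4.0,
                 n_informative=4, noise_flip_rate=0.0, seed=1)
data = gen_embeddings(spec)
head = fit_head(data.table.features, data.labels,
                HeadConfig(architecture="res_dnn", input_dim=32,
                           layer_dims=[16], epochs=30, learning_rate=1e-3,
                           seed=7))

table = attribute_sites(head, data.table.features[:100],
                        data.table.sites[:100], n_steps=64)
print(f"attributed {len(table.sites)} sites; "
      f"max completeness gap {table.completeness_gap.max():.3g}")

print("top 5 features by mean |attribution|:")
for rank, feat in enumerate(feature_importance_ranking(table, top_k=5), 1):
    print(f"  {rank}. {feat.feature_name}  "
          f"mean|IG|={feat.mean_abs_attribution:.3f}  "
          f"sign consistency={feat.sign_consistency:.2f}")

# agreement between the IG ranking and plain input-gradient importance
ig_importance = np.abs(table.attributions).mean(axis=0)
grad = head.input_gradient(data.table.features[:100])
grad_importance = np.abs(grad).mean(axis=0)
rho, p = rank_agreement(ig_importance, grad_importance)
print(f"Spearman agreement IG vs plain-gradient importance: "
      f"rho={rho:.3f} (p={p:.2g})")
# The informative coordinates (features 1-4) dominate the ranking, and
# two attribution flavours agree strongly on which features matter.
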