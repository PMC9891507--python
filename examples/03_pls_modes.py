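"""Two-block PLS correlation: paired latent modes of risk traits and social
indicators.

Two data blocks that share planted latent factors (cross-correlations 0.7 and
0.3) are decomposed by an SVD of their cross-covariance; the fitted mode
correlations recover the planted values and the covariance-explained profile
shows how dominant the first mode is.
"""

import numpy as np

from isorisk import fit_pls, simulate_two_block

X, Y, truth = simulate_two_block(
    n=20000, p=12, q=6, n_latent=2, latent_corrs=[0.7, 0.3], noise_sd=0.1, seed=1
)
res = fit_pls(X, Y, n_modes=6)

print(f"planted latent correlations: {truth['latent_corrs']}")
print(f"fitted mode correlations:    {res.mode_correlations.round(3)}")
print(f"covariance explained:        {res.covariance_explained.round(3)}")
cos = abs(truth["x_weights"][:, 0] @ res.x_weights[:, 0])
print(f"|cos| between planted and fitted mode-1 X weights: {cos:.3f}")
print("\nThe first two modes recover the planted cross-block structure "
      "(residual modes stay near zero); weights align with the planted "
      "directions up to sign.")
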