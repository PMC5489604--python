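"""CSP simultaneous diagonalization and the variance-ratio feature f.

Two-class epochs with strong contralateral ERD are projected by the CSP
filter K = R^T P.  The complementary eigenvalue pairs (D1 + D2 = I) show
which spatial directions favor which class, and the scalar feature
f = var(Z1)/(var(Z1) + var(Z2)) separates the classes along [0, 1].
"""

import numpy as np

import sccsp

epochs = sccsp.generate_mi_epochs(
    sccsp.MIGenConfig(n_trials_per_class=30, erd_depth=0.8, seed=1)
)
fitted = sccsp.fit_csp_baseline(epochs)

print("CSP eigenvalues (class 1):", np.round(np.diag(fitted.csp_model.D1), 3))
f = fitted.train_features
for c in (1, 2):
    vals = f[fitted.train_labels == c]
    print(f"class {c}: mean f = {vals.mean():.3f} (sd {vals.std():.3f})")
lam = sccsp.separability_ratio(f[fitted.train_labels == 1], f[fitted.train_labels == 2])
print(f"separability ratio lambda = {lam:.3f} (lower = better separated)")
print()
print("Eigenvalues far from 0.5 mark discriminative directions; the two "
      "f clusters sit on opposite sides of 0.5 and a small lambda confirms "
      "the classes are compact and far apart in feature space.")
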