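"""Spectral ICA isolates the μ-suppression into one component.

Infomax ICA is fitted on the amplitude spectra of the 6-channel simulation
(channels as variables, frequency bins as observations).  One of the two
components absorbs the μ-band content shared by all channels; the other —
the μ-deficit component, ranked first by the μ/flank contrast — reads the
suppressed channels: its demixing filter concentrates its energy on
channels 5-6.
"""

import numpy as np

import sccsp

epochs = sccsp.generate_fig2_simulation(sccsp.SimConfig(seed=0))
spectrum = sccsp.amplitude_spectrum(epochs.data[0], epochs.fs)
model = sccsp.fit_infomax(spectrum, seed=0, lr=0.005, max_iter=5000, tol=1e-10)

print("component  mu/flank contrast  filter energy on ch 5-6")
for c in range(2):
    w = model.W[c] ** 2
    frac = w[4:].sum() / w.sum()
    print(f"    {c + 1}        {model.mu_contrast[c]:10.3f}        {100 * frac:5.1f}%")
print()
print("Component 1 (contrast ~0: no mu relative to its flanks) is the "
      "mu-deficit component; its spatial filter reads almost exclusively "
      "the two suppressed channels, i.e. the suppression information was "
      "integrated into a single component.")
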