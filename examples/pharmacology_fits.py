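"""Dose-response, competition binding and kinetic-trace processing.

Fits the four-parameter Hill equation to a synthetic replicated
dose-response (the 'fig4c-wt' preset: EC50 = 10 nM, slope 1, 5% noise),
converts a competition IC50 to Ki with Cheng-Prusoff, and processes a
luciferase complementation kinetic trace.
"""

import numpy as np

from icl3kit.pharmacology import (
    cheng_prusoff,
    fit_competition,
    fit_hill,
    process_kinetic_trace,
)
from icl3kit.synthetic_data import gen_dose_response, gen_kinetic_trace

# --- Hill dose-response ---------------------------------------------------
df, meta = gen_dose_response(preset="fig4c-wt", replicates=4,
                             noise_sd_fraction=0.05, seed=11)
mean = df.groupby("concentration")["response"].mean()
hill = fit_hill(mean.index.to_numpy(), mean.to_numpy())
print(f"Hill fit: EC50 = {hill.ec50 * 1e9:.2f} nM (preset 10 nM), "
      f"slope = {hill.hill:.2f}, efficacy log10(Emax/EC50) = {hill.efficacy:.2f}")

# --- competition binding with Cheng-Prusoff -------------------------------
A = np.linspace(-10, -4, 13)  # log10 molar isoproterenol
# noiseless one-site displacement: Y = (Bmax - Bmin)/(1 + 10^(A - log IC50)) + Bmin
y = 100.0 / (1.0 + 10.0 ** (A - np.log10(300e-9)))
comp = fit_competition(A, y, sites=1, tracer_L=50e-12, tracer_KD=25e-12)
print(f"competition: IC50 = {comp.ic50 * 1e9:.0f} nM -> "
      f"Ki = {comp.Ki * 1e9:.0f} nM (tracer 50 pM, KD 25 pM)")
# Ki = IC50 / (1 + L/KD) corrects for tracer occupancy of the binding site.
print(f"Cheng-Prusoff check at L = KD: {cheng_prusoff(1.0, 1.0, 1.0):.2f} x IC50")

# --- luciferase kinetic trace ---------------------------------------------
t, lum, drug_idx, _ = gen_kinetic_trace(fold_change=2.4, noise_sd=0.02, seed=3)
res = process_kinetic_trace(t, lum, drug_idx, control_value=1.0)
print(f"kinetic trace: plateau {res.plateau:.2f}x baseline, "
      f"specific signal {res.specific_signal:.2f} "
      f"(smoothing windows {res.windows})")
# The specific signal is the stabilized post-drug plateau minus the matched
# no-peptide control, after normalizing to the pre-drug equilibration.
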