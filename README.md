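# icl3kit

Analysis toolkit for the biology of the third intracellular loop (ICL3) of
G-protein-coupled receptors: how a conformationally dynamic loop between
transmembrane helices 5 and 6 gates access to the receptor's G-protein-binding
cavity, autoregulates activation, and filters coupling to competing G-protein
subtypes.

The package is aimed at structural bioinformaticians and receptor
pharmacologists who need the quantitative half of such a study as reusable,
tested code: every analysis runs on synthetic inputs generated in-package, so
the full pipeline is exercisable without downloading trajectories, coupling
databases or instrument files.

## What it computes

**Receptor topology** (`icl3kit.receptor_topology`). ICL3 segments are
extracted from annotated receptor records (explicit ICL3 interval, or the gap
between TM5 and TM6; 1-based inclusive numbering throughout). Because loop
lengths vary ~10–240 aa, mutation effects are compared in a symmetric N/C
coordinate frame — positions N1..Nn counted from the TM5 side, Cn..C1 back
from the TM6 side, with n = ⌈L/2⌉ — then rescaled onto a 22-aa normalization
frame. Effect sizes Δ = (mutant − wild type) on the pK_d/pEC50/E_max scale
are aggregated per normalized position.

**Selectivity landscape** (`icl3kit.selectivity_landscape`). Receptors split
into two regimes at an ICL3 length of 46 aa: *interface specificity* (short
loop — selectivity carried by the amino-acid composition of the G-protein
interface) and *gated by ICL3* (long loop). Per receptor the package computes
interface conservation within its primary-coupling group (mean pairwise
diagonal-normalized BLOSUM62 similarity over interface positions, in [0, 1]),
Venn-region coupling overlap and a promiscuity index per regime, and the
cognate/secondary gap max − second-max of log10(E_max/EC50) coupling profiles.

**FRET lifetime** (`icl3kit.fret_lifetime`). TCSPC decay histograms are fit
as Decay(t) = Σ αᵢ e^(−t/τᵢ) (n ≤ 3, Poisson-weighted least squares with
multi-start, optional IRF convolution); the amplitude-weighted lifetime is
τ_avg = Σαᵢτᵢ / Σαᵢ and FRET efficiency E = 1 − τ_FRET/τ_donor. Condition
contrasts call the three loop states — closed/inactive (~37 Å probe
separation, low FRET), agonist-stimulated intermediate (~29 Å, high FRET),
effector-bound open (~43 Å, low FRET) — via the Förster relation
E = 1/(1 + (r/R₀)⁶).

**Ensemble analysis** (`icl3kit.ensemble_analysis`). Backbone φ/ψ dihedrals
are embedded as (sin, cos) pairs, projected on the slowest time-correlated
independent components (tICA: symmetrized time-lagged covariance, generalized
eigenproblem, ridge-regularized), binned into a free-energy surface
F = −kT ln(ρ/ρ_max), and decomposed into metastable states with mini-batch
k-means (including the 4-basins-then-split-one workflow for a five-state
decomposition). Centre-of-mass distances between ICL3 (or slash-delimited
three-residue subsegments, e.g. `"241-HVQ/NLS/QVE/QDG/RT-254"`) and the
ICL1/ICL2 reference loops quantify loop packing.

**Pharmacology** (`icl3kit.pharmacology`). Saturation binding
(B = B_max·L/(K_d+L)), one-/two-site competition displacement on log10
concentration with Cheng–Prusoff K_i = IC50/(1 + L/K_D), the four-parameter
Hill equation E = (E_max−E_min)/(1 + 10^((logEC50−logL)·N_H)) + E_min with
efficacy log10(E_max/EC50), ratiometric difference metrics, pulldown
percent-bound, luciferase kinetic-trace smoothing/normalization, and the
|Z| > 3 leave-one-out outlier rule applied to flagged replicates only.

**Synthetic data** (`icl3kit.synthetic_data`). Seeded generators emulate
every input above with the statistical structure the analyses assume; each
embeds its configuration in output metadata so datasets regenerate
byte-identically.

## Worked example

```sh
python examples/pharmacology_fits.py
```

```
Hill fit: EC50 = 9.42 nM (preset 10 nM), slope = 1.07, efficacy log10(Emax/EC50) = 8.02
competition: IC50 = 300 nM -> Ki = 100 nM (tracer 50 pM, KD 25 pM)
Cheng-Prusoff check at L = KD: 0.50 x IC50
kinetic trace: plateau 2.36x baseline, specific signal 1.36 (smoothing windows (3, 8))
```

The Hill fit recovers the generating EC50 (10 nM) from four replicate curves
with 5% noise; the competition fit's IC50 of 300 nM corrects to K_i = 100 nM
because the 50 pM tracer sits at twice its 25 pM K_D (divisor 1 + L/K_D = 3);
the kinetic trace plateaus near the planted 2.4-fold induction after
smoothing and baseline normalization.

The other scripts in `examples/` walk the remaining capabilities: loop
numbering and mutation meta-analysis, the selectivity regimes, three-state
FRET classification from raw decays, and the tICA/free-energy/cluster
pipeline with planted-state recovery (e.g. median ICL3–ICL1 centre-of-mass
distances of 37.0/29.0/43.0 Å against planted 37/29/43 Å).

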