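# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `icl3kit`, in the order of the analysis pipeline.

## Loop coordinates and mutation meta-analysis

Residue intervals are 1-based and inclusive everywhere, matching biological
numbering conventions (an ICL3 annotated 236–257 has 22 residues). ICL3 is
taken from an explicit annotation when present, otherwise inferred as the gap
between the TM5 and TM6 intervals; adjacent helices yield a length-0 segment
with the convention start = end + 1, never a negative width.

The N/C coordinate scheme assigns loop position p to N_p if p ≤ ⌈L/2⌉ and to
C_(L−p+1) otherwise. For even L the two halves are equal; for odd L the
middle residue must go somewhere, and we assign it to the N side
(deterministic, and the round-trip map stays a bijection for every length —
property-tested for L = 1..60).

Rescaling onto the 22-aa normalization frame maps bin centres
proportionally, p → round_half_up((p − 0.5)·22/L + 0.5), clamped to [1, 22].
This is monotone, maps endpoints to endpoints, and distributes the L source
positions over the 22 slots in groups of ⌊L/22⌋ or ⌈L/22⌉ (verified
exhaustively for L = 22..60). Positions are integer bins, not fractions: the
aggregation is a per-bin effect list, and fractional placement would create
empty bins for L < 44.

Multi-residue mutants contribute their single effect size to every mutated
position; aggregation therefore conserves Σ|positions| over records.
Chimera/insertion records have no meaningful per-position coordinates in the
host loop and are excluded from aggregation by default (opt-in flag).

## Interface conservation and regimes

Conservation of a receptor's G-protein-binding interface is the mean, over
interface positions, of the mean pairwise similarity between that receptor
and every other member of its primary-coupling group at that position.
Groups are scored independently (one alignment per transducer family).

Residue similarity uses diagonal-normalized BLOSUM62 log-odds,
s(a,b) = max(M[a,b], 0)/√(M[a,a]·M[b,b]), so s ∈ [0, 1] and s(a,a) = 1 for
every residue — a conservation score of exactly 1 then means "all group
members identical at all interface positions", which is the natural reading
of the statistic. A plain min-max rescaling of the matrix would score
self-matches of weakly self-similar residues (e.g. A/A) well below 1 and
break that calibration. Identity similarity (1 if equal else 0) is available
as an option; gap–residue and gap–gap pairs score 0 and are counted by
default (configurable to excluded).

The regime threshold defaults to 46 aa, with length ≥ 46 classed as long
("gated by ICL3"); it is a parameter because the demarcation is approximate
(values near 45–46 are equally defensible). Classification is monotone by
construction. Coupling overlap is summarized as Venn-region counts over
{Gs, Gq, Gi} subsets plus a promiscuity index (fraction coupling to ≥ 2
families). The cognate/secondary analysis ranks log10(Emax/EC50) profiles,
excludes single-family profiles (no secondary exists), and breaks exact ties
by the fixed order Gs > Gi > Gq > G12 with the gap reported as 0. Regime
contrasts are descriptive (mean, sd, IQR, mean difference, IQR ratio); no
hypothesis testing is attached.

## TCSPC decay fitting and FRET

The decay model is Decay(t) = Σᵢ αᵢ e^(−t/τᵢ) with n ≤ 3 components. The
objective is Poisson-weighted least squares, residual (model − counts)/√max(counts, 1),
which approximates the Poisson likelihood well at the counts where these
fits operate. The model predicts the *integral* of the decay over each
histogram bin rather than a point evaluation — for lifetimes comparable to
the bin width the point form biases short lifetimes by several percent.
Amplitudes are bounded ≥ 0 and lifetimes > 0; starting lifetimes are
log-spaced over the window with equal amplitudes, and five seeded restarts
with log-normal jitter keep the best reduced χ². IRF handling is an optional
discrete convolution with a supplied histogram, off by default.

Components are reported in descending τ. A component with fractional
amplitude < 1% or a lifetime within 1% of another is counted as degenerate:
the requested n is retained in the output but the effective component count
is reduced and a warning raised. Reduced χ² near 1 indicates
Poisson-consistent residuals; values ~1.2–1.4 are typical of real instrument
data with imperfect IRF treatment and are treated as a plausibility band,
not a target.

τ_avg = Σαᵢτᵢ/Σαᵢ (amplitude weighting, not intensity weighting) and
E = 1 − τ_FRET/τ_donor. Negative efficiencies are reported with a warning
rather than clamped — they are informative about noise or absent transfer.
The per-condition donor-only reference is preferred, but nothing in the API
prevents a single global τ_donor.

State calls compare conditions: agonist efficiency above buffer by more than
the ΔE cutoff → intermediate; an agonist+effector condition at or below the
buffer margin *and* quenched relative to the agonist condition → open. The
quench-versus-agonist requirement makes the all-conditions-equal case
resolve to "no transitions" (all closed) instead of spuriously calling an
open state. The default cutoff of 0.02 is half the ~4% agonist-induced
efficiency swing characteristic of this sensor class; it is a parameter.

The Förster relation E = 1/(1 + (r/R₀)⁶) links the three state distances
(37/29/43 Å) to the low/high/low FRET signature; this ordering holds for any
R₀, and the pipeline round-trip (distance → decay → fit → efficiency →
state call) is tested over R₀ ∈ [30, 70] Å. No default Förster radius is
assumed in analysis: it is required configuration, because it depends on the
dye pair. The synthetic generator documents its chosen value in metadata.

## Trajectory analysis

Dihedral channels are embedded as (sin θ, cos θ) pairs to remove the ±π
discontinuity, then mean-centred. tICA solves C(τ)v = λC(0)v with the
lagged covariance symmetrized, (C + Cᵀ)/2, and C(0) ridge-regularized
(1e-6 on the diagonal) so duplicated or constant feature columns do not make
the problem singular. Eigenvalues are reported in descending order; under
symmetrized estimation |λ| ≤ 1 up to sampling noise, and λ of the leading
component estimates the autocorrelation of the slowest process at the lag.
For a hidden 2-state chain with stay probabilities p₁₁, p₂₂ the slow
eigenvalue is analytically (p₁₁ + p₂₂ − 1)^lag, which the implementation
recovers within 0.05 at 10⁴ frames — the main oracle test.

The free-energy surface is F(bin) = −kT·ln(count/max count) on a 2-D
histogram (default 100×100 over the data range): the most populated bin sits
at exactly 0, empty bins are masked rather than given a number, and F
differences are invariant to total sample count. kT defaults to 1
(dimensionless); multiply by 0.616 kcal/mol for 310 K.

State decomposition uses scikit-learn's MiniBatchKMeans followed by one
exact full-data refinement pass (centers become exact cluster means, frames
are reassigned once, inertia is the true within-cluster sum of squares);
this keeps mini-batch speed while making k = 1 return the data mean exactly
and results bit-reproducible for a fixed seed. The two-pass workflow —
k basins, then split one basin into two subclusters — reproduces the
four-basins-plus-two-subclusters decomposition as `subcluster_basin`. k is
always a user choice; no automatic model selection is attempted.

Centre-of-mass distances are Euclidean distances between mass-weighted
centroids of residue selections (masses default to 1 when not supplied, as
for Cα-like synthetic frames). Segment specs like
`"241-HVQ/NLS/QVE/QDG/RT-254"` are parsed by anchoring the flanking residue
numbers and partitioning the span by the slash-delimited residue strings,
validating that the letters sum to the anchor span (and, when frames carry
residue names, that they match; `X` matches anything).

## Pharmacology fits

All binding/dose-response fits are nonlinear least squares on log10
concentration (concentrations molar internally). Two-site competition nests
the one-site model at F₁ ∈ {0, 1} (tested to 1e-10); fits with F₁ pinned near
0 or 1 are flagged with a recommendation to refit one-site. The two-site
summary IC50 is the linear weighted average F₁·IC50₁ + (1−F₁)·IC50₂,
matching the plain reading of a "weighted average of the IC50 values";
log-scale weighting is an option since the choice of scale is ambiguous.
Cheng–Prusoff is the closed form K_i = IC50/(1 + L/K_D).

Kinetic traces are smoothed with a 3-point moving average before drug
addition and an 8-point one after, normalized to the last smoothed pre-drug
point. The "stable maximum" plateau is defined as the largest smoothed
post-drug value whose next three smoothed points deviate by < 5% — the
qualitative criterion ("maximum value that appeared stable") needs a formal
realization and this is one; both windows and the tolerance are parameters.
EC50/K_d estimates falling outside the tested concentration range ×100 are
flagged as extrapolation, and negative specific signals are flagged, never
clamped.

The outlier rule removes only replicates *flagged* on independent grounds
(e.g. mismatched cell density or expression) whose leave-one-out Z-score
exceeds 3; unflagged values are never removed regardless of Z. The
comparator set excludes the candidate so a gross outlier cannot inflate the
spread used to judge itself.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic under a fixed seed and embed their full
configuration in metadata. Defaults encode the study conditions the analyses
assume:

- **Receptor panel**: ICL3 lengths from a two-component discretized normal
  mixture, modes 20 and 80 aa (sd 6 and 15, weights 0.75/0.25 — roughly the
  3:1 short:long split of real class A panels); second-family coupling
  probability 0.5 (short) vs 0.1 (long); a β2AR-like fixture with ICL3
  236–257.
- **Interface alignments**: per-group consensus with per-position mutation
  probability (1 − conservation level).
- **Decays**: exact per-bin integrals of the multi-exponential model scaled
  to the photon budget, Poisson-sampled; state presets derive a
  mono-exponential lifetime from the 37/29/43 Å distances via the Förster
  relation against a 4.0 ns donor (typical of the green dye class used on
  such sensors; recorded in metadata, configurable).
- **Trajectories**: hidden Markov chain with per-state stay probabilities
  (leave mass spread uniformly), von Mises dihedral emissions
  (concentration 8, i.e. ~0.36 rad circular sd — a test-harness choice, not
  a claim about real dihedral distributions), optional paired coordinate
  frames placing an ICL3-like segment at state-specific distances from an
  ICL1-like reference.
- **Dose-response**: Hill responses plus Gaussian noise proportional to
  Emax; the `fig4c-wt` preset is EC50 = 10 nM, slope 1, Emax 1 (arbitrary
  units) on a 10 pM–100 µM grid with 4 replicates and 5% noise.
- **Kinetic traces**: flat baseline, exponential approach to
  baseline×fold_change (default 2.4, rise constant 30 s) after drug addition
  at 330 s.

What passing tests on these inputs shows: the estimators are unbiased and
correctly calibrated when their model assumptions hold, and the pipeline
recovers planted structure (states, lifetimes, EC50s, conservation
orderings) at realistic noise. What they do not show: robustness to the
features real data add — instrument response functions and afterpulsing in
TCSPC, anharmonic/correlated dihedral fluctuations and slow solvent degrees
of freedom in MD, receptor reserve and system bias in cell-based
dose-response, or database-version effects in coupling panels. Published
panel counts (e.g. n = 249/187/62) depend on coupling-evidence and sequence
database versions and are deliberately not reproduction targets.

## Problem sizes in the test suite

Tests run the decay recovery at 10⁷ photons (512 bins), tICA oracles at
10⁴ frames, the free-energy closed form at 10⁵ samples, and classification
round-trips at 10⁵ photons with single-component fits — sizes at which the
statistical tolerances in the tests (5%/10% on τ/α, 0.05 on eigenvalues,
0.1 kT on basin gaps) hold with margin across seeds while the whole suite
stays fast on one CPU.

## Known limitations

- The lifetime fitter assumes a clean decay origin (no time-shift parameter)
  and treats the IRF, when given, as noise-free.
- tICA is linear; genuinely nonlinear slow coordinates need a kernel or
  deep variant out of scope here.
- Markov-state-model machinery beyond tICA + clustering (transition-matrix
  estimation, spectral analysis) is not included; the landscape and state
  decomposition do not require it.
- Interface residue sets are inputs, not computed from structure; no
  alignment-based generic-numbering engine is included.
- The competition fitter assumes equilibrium displacement; kinetic binding
  artifacts are out of scope.
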