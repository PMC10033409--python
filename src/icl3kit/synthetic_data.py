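"""Seeded generators emulating every input the analysis pipeline consumes.

Each generator draws from a ``numpy.random.default_rng`` seeded explicitly,
returns plain containers the analysis modules accept directly, and embeds
its full configuration in the result metadata so any dataset can be
regenerated byte-identically. The statistical structure mirrors the study
conditions the analyses assume:

* a receptor panel with a bimodal ICL3-length distribution (modes near 20
  and 80 aa, echoing the short/long regime split) whose coupling promiscuity
  depends on the regime;
* group-structured interface alignments with a tunable per-group
  conservation level;
* Poisson-noise multi-exponential TCSPC decays, with presets deriving state
  lifetimes from the three characteristic probe distances (~37/29/43 A)
  through the Foerster relation against a mono-exponential donor;
* metastable hidden-Markov dihedral trajectories with von Mises emissions
  (a planted slow coordinate) and paired coordinate frames that place an
  ICL3-like segment at state-specific distances from an ICL1-like reference;
* Hill dose-response tables (including the 'fig4c-wt' preset: EC50 = 10 nM,
  Hill slope 1) and luciferase kinetic traces with stated noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble_analysis import CoordinateFrame, DihedralTrajectory
from .fret_lifetime import (
    ConformationalState,
    DecayTrace,
    THREE_STATE_DISTANCES,
    distance_to_efficiency,
)
from .receptor_topology import ReceptorRecord

__all__ = [
    "DEFAULT_DONOR_LIFETIME_NS",
    "DOSE_RESPONSE_PRESETS",
    "gen_receptor_panel",
    "gen_interface_alignment",
    "gen_decay",
    "gen_metastable_trajectory",
    "gen_dose_response",
    "gen_kinetic_trace",
]

_AA = "ARNDCQEGHILKMFPSTWYV"

#: Mono-exponential donor lifetime used when deriving state lifetimes from
#: probe distances (typical for the green dye class used on such sensors).
DEFAULT_DONOR_LIFETIME_NS = 4.0

#: Printed dose-response fits usable as generator presets.
DOSE_RESPONSE_PRESETS: dict[str, dict[str, float]] = {
    # wild-type beta2AR(dICL3) isoproterenol dose -> InsP1 accumulation fit
    "fig4c-wt": {"Emax": 1.0, "Emin": 0.0, "ec50": 10e-9, "hill": 1.0},
}


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA), size=n))


def gen_receptor_panel(
    n: int = 200,
    length_modes: tuple[float, float] = (20.0, 80.0),
    length_sds: tuple[float, float] = (6.0, 15.0),
    weights: tuple[float, float] = (0.75, 0.25),
    p_second: tuple[float, float] = (0.5, 0.1),
    threshold: int = 46,
    seed: int = 0,
    include_b2ar_fixture: bool = True,
) -> tuple[list[ReceptorRecord], dict]:
    """Generate an annotated receptor panel with a bimodal ICL3-length mixture.

    ICL3 lengths are drawn from a two-component discretized normal mixture
    (defaults centred on the short/long regime modes). Each receptor gets a
    primary transducer family uniformly from {Gs, Gi, Gq}; a second family is
    added with probability ``p_second[0]`` below the length ``threshold`` and
    ``p_second[1]`` at or above it. A beta2AR-like fixture with ICL3
    annotated 236-257 (and TM5/TM6 flanks) is appended unless disabled.
    """
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    if not all(0.0 <= p <= 1.0 for p in p_second):
        raise ValueError("p_second probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    families = ("Gs", "Gi", "Gq")
    records: list[ReceptorRecord] = []
    for i in range(n):
        comp = rng.choice(2, p=weights)
        length = max(int(round(rng.normal(length_modes[comp], length_sds[comp]))), 4)
        tm5 = (31, 60)  # 30-residue helices flanking the loop
        icl3 = (61, 60 + length)
        tm6 = (61 + length, 90 + length)
        seq_len = tm6[1] + 30
        p2 = p_second[0] if length < threshold else p_second[1]
        primary = families[rng.choice(3)]
        coupling = {primary}
        if rng.random() < p2:
            coupling.add(rng.choice([f for f in families if f != primary]))
        records.append(
            ReceptorRecord(
                receptor_id=f"SYN{i:04d}",
                sequence=_random_sequence(rng, seq_len),
                segments={"TM5": tm5, "ICL3": icl3, "TM6": tm6},
                coupling=frozenset(coupling),
            )
        )
    if include_b2ar_fixture:
        records.append(
            ReceptorRecord(
                receptor_id="B2AR_LIKE",
                sequence=_random_sequence(rng, 413),
                segments={"TM5": (206, 235), "ICL3": (236, 257), "TM6": (258, 290)},
                coupling=frozenset({"Gs"}),
            )
        )
    meta = {
        "generator": "gen_receptor_panel",
        "seed": seed,
        "n": n,
        "length_modes": length_modes,
        "length_sds": length_sds,
        "weights": weights,
        "p_second": p_second,
        "threshold": threshold,
    }
    return records, meta


def gen_interface_alignment(
    group_sizes: Mapping[str, int],
    conservation_levels: Mapping[str, float],
    n_positions: int = 30,
    seed: int = 0,
):
    """Generate a group-structured interface alignment.

    Each group gets a random consensus row; every cell of a member row is
    mutated to a different random residue with probability
    ``1 - conservation_level`` of its group.
    """
    from .selectivity_landscape import InterfaceAlignment

    for fam, level in conservation_levels.items():
        if not 0.0 <= level <= 1.0:
            raise ValueError(f"conservation level for {fam} outside [0, 1]")
    rng = np.random.default_rng(seed)
    ids, rows, group = [], [], {}
    for fam, size in group_sizes.items():
        level = conservation_levels[fam]
        consensus = rng.choice(list(_AA), size=n_positions)
        for k in range(size):
            rid = f"{fam}_{k:03d}"
            row = consensus.copy()
            mutate = rng.random(n_positions) > level
            for j in np.flatnonzero(mutate):
                choices = [a for a in _AA if a != consensus[j]]
                row[j] = rng.choice(choices)
            ids.append(rid)
            rows.append(row)
            group[rid] = fam
    aln = InterfaceAlignment(
        receptor_ids=ids,
        positions=[f"P{j}" for j in range(n_positions)],
        residues=np.array(rows),
        group=group,
    )
    meta = {
        "generator": "gen_interface_alignment",
        "seed": seed,
        "group_sizes": dict(group_sizes),
        "conservation_levels": dict(conservation_levels),
        "n_positions": n_positions,
    }
    return aln, meta


def gen_decay(
    lifetimes: Sequence[float] | None = None,
    amplitudes: Sequence[float] | None = None,
    state: ConformationalState | str | None = None,
    forster_radius: float | None = None,
    donor_lifetime: float = DEFAULT_DONOR_LIFETIME_NS,
    photons: int = 1_000_000,
    n_bins: int = 512,
    window: float | None = None,
    irf_sigma: float | None = None,
    poisson_noise: bool = True,
    seed: int = 0,
) -> tuple[DecayTrace, dict]:
    """Generate a TCSPC decay histogram with Poisson counting noise.

    Either give explicit multi-exponential ``(amplitudes, lifetimes)`` or a
    three-state ``state`` preset plus ``forster_radius``: the state's probe
    distance converts to a FRET efficiency E through the Foerster relation
    and the (mono-exponential) decay lifetime is donor_lifetime * (1 - E).
    Expected bin contents are the exact integrals of the decay over each bin,
    scaled to ``photons`` total, then Poisson-sampled (disable with
    ``poisson_noise=False`` for noiseless expectation histograms). A Gaussian
    IRF of width ``irf_sigma`` ns can be convolved in and is attached to the
    trace.
    """
    if state is not None:
        if lifetimes is not None:
            raise ValueError("give either a state preset or explicit lifetimes")
        if forster_radius is None:
            raise ValueError("a state preset needs a forster_radius")
        state = ConformationalState(state)
        distance = THREE_STATE_DISTANCES[state]
        eff = distance_to_efficiency(distance, forster_radius)
        lifetimes = [donor_lifetime * (1.0 - eff)]
        amplitudes = [1.0]
    if lifetimes is None:
        raise ValueError("lifetimes required")
    taus = np.asarray(lifetimes, dtype=float)
    amps = np.asarray(
        amplitudes if amplitudes is not None else np.ones_like(taus), dtype=float
    )
    if np.any(taus <= 0) or np.any(amps < 0):
        raise ValueError("lifetimes must be positive and amplitudes non-negative")
    if photons < 1:
        raise ValueError("photons must be >= 1")
    if window is None:
        window = 5.0 * taus.max()
    if window < 5.0 * taus.max():
        raise ValueError("window must cover >= 5x the longest lifetime")

    edges = np.linspace(0.0, window, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    expected = np.zeros(n_bins)
    for a, tau in zip(amps, taus):
        expected += a * tau * (np.exp(-edges[:-1] / tau) - np.exp(-edges[1:] / tau))
    irf_hist = None
    if irf_sigma is not None:
        kernel_t = centers - centers[0]
        irf_hist = np.exp(-0.5 * ((kernel_t - 3 * irf_sigma) / irf_sigma) ** 2)
        expected = np.convolve(expected, irf_hist / irf_hist.sum())[:n_bins]
    expected *= photons / expected.sum()
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected) if poisson_noise else expected
    meta = {
        "generator": "gen_decay",
        "seed": seed,
        "lifetimes_ns": taus.tolist(),
        "amplitudes": amps.tolist(),
        "state": state.value if state is not None else None,
        "forster_radius_A": forster_radius,
        "donor_lifetime_ns": donor_lifetime,
        "photons": photons,
        "n_bins": n_bins,
        "window_ns": window,
        "irf_sigma_ns": irf_sigma,
        "poisson_noise": poisson_noise,
    }
    return DecayTrace(bin_centers=centers, counts=counts, irf=irf_hist, meta=meta), meta


def _markov_chain(
    rng: np.random.Generator, transition: np.ndarray, n_steps: int
) -> np.ndarray:
    k = transition.shape[0]
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.choice(k)
    for t in range(1, n_steps):
        states[t] = rng.choice(k, p=transition[states[t - 1]])
    return states


def gen_metastable_trajectory(
    k_states: int = 3,
    stay_probabilities: Sequence[float] = (0.99, 0.98, 0.99),
    n_channels: int = 4,
    emission_means: np.ndarray | None = None,
    emission_concentration: float = 8.0,
    frames: int = 10_000,
    frame_interval_ns: float = 0.02,
    state_distances: Sequence[float] | None = None,
    seed: int = 0,
    make_frames: bool = False,
):
    """Generate a metastable dihedral trajectory with a planted slow coordinate.

    A hidden Markov chain with the given per-state stay probabilities (the
    leave mass is spread uniformly over the other states) emits
    von Mises-distributed dihedrals around state-specific mean angles.
    With ``make_frames`` the generator also builds one coordinate frame per
    time step placing an ICL3-like segment (resid 236-257) at the current
    state's distance from an ICL1-like reference (resid 61-66); default
    distances are the three-state presets 37/29/43 A.

    Returns ``(DihedralTrajectory, true_labels, frames_or_None, meta)``.
    """
    if k_states < 2:
        raise ValueError("k_states must be >= 2")
    stay = np.asarray(stay_probabilities, dtype=float)
    if stay.size != k_states or np.any(stay <= 0) or np.any(stay >= 1):
        raise ValueError("need one stay probability in (0, 1) per state")
    transition = np.full((k_states, k_states), 0.0)
    for i in range(k_states):
        transition[i] = (1.0 - stay[i]) / (k_states - 1)
        transition[i, i] = stay[i]
    rng = np.random.default_rng(seed)
    labels = _markov_chain(rng, transition, frames)

    if emission_means is None:
        # spread state means around the circle, one offset per channel
        base = np.linspace(-np.pi / 2, np.pi / 2, k_states)
        offsets = np.linspace(0.0, np.pi / 4, n_channels)
        emission_means = base[:, None] + offsets[None, :]
    emission_means = np.asarray(emission_means, dtype=float)
    if emission_means.shape != (k_states, n_channels):
        raise ValueError(
            f"emission_means must be ({k_states}, {n_channels}), got {emission_means.shape}"
        )
    angles = rng.vonmises(emission_means[labels], emission_concentration)
    angles = np.mod(angles + np.pi, 2 * np.pi) - np.pi
    traj = DihedralTrajectory(
        angles=angles,
        frame_interval_ns=frame_interval_ns,
        channel_labels=[f"res{i // 2}_{'phi' if i % 2 == 0 else 'psi'}"
                        for i in range(n_channels)],
    )

    coord_frames = None
    if make_frames:
        if state_distances is None:
            state_distances = list(THREE_STATE_DISTANCES.values())[:k_states]
        dists = np.asarray(state_distances, dtype=float)
        if dists.size != k_states:
            raise ValueError("need one state distance per state")
        ref_resid = np.arange(61, 67)  # ICL1-like reference, F61-T66
        loop_resid = np.arange(236, 258)  # ICL3-like segment, S236-G257
        coord_frames = []
        for lbl in labels:
            ref_pos = rng.normal(0.0, 0.3, size=(ref_resid.size, 3))
            ref_pos -= ref_pos.mean(axis=0)
            loop_pos = rng.normal(0.0, 0.5, size=(loop_resid.size, 3))
            loop_pos -= loop_pos.mean(axis=0)
            loop_pos[:, 0] += dists[lbl]
            coord_frames.append(
                CoordinateFrame(
                    positions=np.vstack([ref_pos, loop_pos]),
                    resid=np.concatenate([ref_resid, loop_resid]),
                )
            )
    meta = {
        "generator": "gen_metastable_trajectory",
        "seed": seed,
        "k_states": k_states,
        "stay_probabilities": stay.tolist(),
        "transition_matrix": transition.tolist(),
        "n_channels": n_channels,
        "emission_concentration": emission_concentration,
        "frames": frames,
        "frame_interval_ns": frame_interval_ns,
        "state_distances_A": list(state_distances) if make_frames else None,
    }
    return traj, labels, coord_frames, meta


def gen_dose_response(
    preset: str | None = "fig4c-wt",
    Emax: float | None = None,
    Emin: float | None = None,
    ec50: float | None = None,
    hill: float | None = None,
    concentrations: Sequence[float] | None = None,
    replicates: int = 4,
    noise_sd_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Generate a replicated Hill dose-response table.

    The default 'fig4c-wt' preset reproduces the wild-type receptor
    isoproterenol dose-InsP1 fit (EC50 = 10 nM, Hill slope 1) on a
    10 pM - 100 uM grid. Gaussian noise with sd ``noise_sd_fraction * Emax``
    is added per well. Returns a tidy frame (concentration, replicate,
    response) plus metadata with the generating parameters.
    """
    if preset is not None:
        params = dict(DOSE_RESPONSE_PRESETS[preset])
    else:
        params = {"Emax": Emax, "Emin": Emin, "ec50": ec50, "hill": hill}
        if any(v is None for v in params.values()):
            raise ValueError("without a preset, give Emax, Emin, ec50 and hill")
    if concentrations is None:
        concentrations = np.logspace(-11, -4, 15)  # 10 pM .. 100 uM
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("empty concentration grid")
    rng = np.random.default_rng(seed)
    log_ec50 = np.log10(params["ec50"])
    truth = (params["Emax"] - params["Emin"]) / (
        1.0 + 10.0 ** ((log_ec50 - np.log10(conc)) * params["hill"])
    ) + params["Emin"]
    rows = []
    for rep in range(replicates):
        noise = rng.normal(0.0, noise_sd_fraction * params["Emax"], size=conc.size)
        for c, r in zip(conc, truth + noise):
            rows.append({"concentration": c, "replicate": rep, "response": r})
    meta = {
        "generator": "gen_dose_response",
        "seed": seed,
        "preset": preset,
        "params": params,
        "replicates": replicates,
        "noise_sd_fraction": noise_sd_fraction,
    }
    return pd.DataFrame(rows), meta


def gen_kinetic_trace(
    baseline: float = 1.0,
    fold_change: float = 2.4,
    rise_constant_s: float = 30.0,
    drug_time_s: float = 330.0,
    total_time_s: float = 900.0,
    dt_s: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, int, dict]:
    """Generate a luciferase kinetic trace: flat pre-drug baseline, then an
    exponential approach to baseline * fold_change after drug addition.

    Returns ``(time, luminescence, drug_addition_index, meta)``.
    """
    if fold_change < 0:
        raise ValueError("fold_change must be non-negative")
    if not 0 < drug_time_s < total_time_s:
        raise ValueError("drug_time_s must lie inside the trace")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, total_time_s, dt_s)
    drug_idx = int(np.searchsorted(t, drug_time_s))
    y = np.full(t.size, baseline)
    post_t = t[drug_idx:] - t[drug_idx]
    y[drug_idx:] = baseline + baseline * (fold_change - 1.0) * (
        1.0 - np.exp(-post_t / rise_constant_s)
    )
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    meta = {
        "generator": "gen_kinetic_trace",
        "seed": seed,
        "baseline": baseline,
        "fold_change": fold_change,
        "rise_constant_s": rise_constant_s,
        "drug_time_s": drug_time_s,
        "total_time_s": total_time_s,
        "dt_s": dt_s,
        "noise_sd": noise_sd,
    }
    return t, y, drug_idx, meta
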