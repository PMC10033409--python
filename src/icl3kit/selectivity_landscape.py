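"""G-protein coupling selectivity versus ICL3 length.

Receptors fall into two regimes demarcated by ICL3 length (default 46 aa):
short-ICL3 receptors whose G-protein selectivity is carried by the amino-acid
composition of the structurally resolved receptor-G-protein interface, and
long-ICL3 receptors whose selectivity is gated by the loop itself. This
module computes, per receptor:

* interface conservation — the mean pairwise residue similarity of a
  receptor's G-protein-binding interface against the other members of its
  primary-coupling group, normalized to [0, 1];
* the regime classification and per-regime coupling-overlap (Venn) summaries
  with a promiscuity index (fraction of receptors coupling to >= 2 families);
* the cognate/secondary gap from quantitative coupling profiles, where the
  cognate family is the one with the highest log(Emax/EC50) and the secondary
  the second-highest (single-family profiles are excluded);
* descriptive contrasts of the conservation distributions between regimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

__all__ = [
    "GAP",
    "FAMILY_ORDER",
    "Regime",
    "InterfaceAlignment",
    "ConservationScore",
    "CouplingProfile",
    "RegimeSummary",
    "interface_conservation",
    "classify_regime",
    "coupling_overlap",
    "cognate_secondary_gap",
    "regime_contrast",
    "read_interface_alignment",
]

GAP = "-"
DEFAULT_THRESHOLD = 46
#: Fixed family priority used to break ties in cognate/secondary ordering.
FAMILY_ORDER = ("Gs", "Gi", "Gq", "G12")

_AA = "ARNDCQEGHILKMFPSTWYV"


class Regime(str, Enum):
    #: short ICL3 — selectivity carried by the G-protein interface
    interface_specificity = "interface_specificity"
    #: long ICL3 — selectivity gated by the loop
    gated_by_ICL3 = "gated_by_ICL3"


@dataclass
class InterfaceAlignment:
    """Gapped alignment of G-protein-interface residues across receptors."""

    receptor_ids: list[str]
    positions: list[str]
    residues: np.ndarray  # (n_receptors, n_positions) of single characters
    group: dict[str, str]  # receptor_id -> primary transducer family

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype="<U1")
        if self.residues.shape != (len(self.receptor_ids), len(self.positions)):
            raise ValueError(
                f"residue matrix shape {self.residues.shape} inconsistent with "
                f"{len(self.receptor_ids)} receptors x {len(self.positions)} positions"
            )
        missing = [r for r in self.receptor_ids if r not in self.group]
        if missing:
            raise ValueError(f"receptors without a group: {missing}")


@dataclass(frozen=True)
class ConservationScore:
    receptor_id: str
    score: float
    group: str
    degenerate: bool = False  # singleton group: score undefined


@dataclass(frozen=True)
class CouplingProfile:
    """Per-receptor quantitative coupling: transducer family -> log(Emax/EC50)."""

    receptor_id: str
    values: Mapping[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError(f"{self.receptor_id}: empty coupling profile")


@dataclass
class RegimeSummary:
    regime: Regime
    n: int
    overlap_counts: dict[frozenset, int] = field(default_factory=dict)
    promiscuity_index: float = float("nan")
    conservation_mean: float = float("nan")
    conservation_sd: float = float("nan")


def _normalized_blosum62() -> dict[tuple[str, str], float]:
    # diagonal-normalized log-odds: s(a,b) = max(M[a,b], 0)/sqrt(M[a,a]*M[b,b]),
    # so s(a,a) = 1 for every residue and dissimilar pairs floor at 0
    mat = substitution_matrices.load("BLOSUM62")
    scores = np.array([[mat[a, b] for b in _AA] for a in _AA], dtype=float)
    diag = np.diag(scores)
    table = {}
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            table[(a, b)] = max(scores[i, j], 0.0) / np.sqrt(diag[i] * diag[j])
    return table


_BLOSUM_CACHE: dict[tuple[str, str], float] | None = None


def _similarity_table(metric: str) -> dict[tuple[str, str], float] | None:
    global _BLOSUM_CACHE
    if metric == "blosum62":
        if _BLOSUM_CACHE is None:
            _BLOSUM_CACHE = _normalized_blosum62()
        return _BLOSUM_CACHE
    if metric == "identity":
        return None
    raise ValueError(f"unknown similarity metric {metric!r}")


def _pair_similarity(a: str, b: str, table) -> float:
    if table is None:
        return 1.0 if a == b else 0.0
    return table.get((a, b), 0.0)


def interface_conservation(
    aln: InterfaceAlignment,
    metric: str = "blosum62",
    gap_mode: str = "count",
) -> list[ConservationScore]:
    """Score each receptor's interface conservation within its coupling group.

    For receptor r, score = mean over interface positions of the mean pairwise
    similarity between r and every other member of r's group at that position.
    Similarity is a diagonal-normalized BLOSUM62 log-odds score in [0, 1] with
    identical residues scoring 1 (``metric="identity"`` uses 1 if equal else
    0). Gap pairs contribute 0 and are counted under ``gap_mode="count"``
    (default) or dropped under ``"exclude"``.
    """
    if gap_mode not in ("count", "exclude"):
        raise ValueError("gap_mode must be 'count' or 'exclude'")
    if not aln.receptor_ids:
        raise ValueError("empty alignment")
    table = _similarity_table(metric)
    by_group: dict[str, list[int]] = {}
    for i, rid in enumerate(aln.receptor_ids):
        by_group.setdefault(aln.group[rid], []).append(i)

    scores: list[ConservationScore] = []
    for i, rid in enumerate(aln.receptor_ids):
        fam = aln.group[rid]
        others = [j for j in by_group[fam] if j != i]
        if not others:
            warnings.warn(f"{rid}: singleton group {fam}, conservation undefined")
            scores.append(ConservationScore(rid, float("nan"), fam, degenerate=True))
            continue
        sims = []
        for p in range(len(aln.positions)):
            a = aln.residues[i, p]
            for j in others:
                b = aln.residues[j, p]
                if a == GAP or b == GAP:
                    if gap_mode == "count":
                        sims.append(0.0)
                    continue
                sims.append(_pair_similarity(a, b, table))
        score = float(np.mean(sims)) if sims else 0.0
        scores.append(ConservationScore(rid, score, fam))
    return scores


def classify_regime(icl3_length: int, threshold: int = DEFAULT_THRESHOLD) -> Regime:
    """Classify a receptor by ICL3 length: < threshold -> short (interface
    specificity), >= threshold -> long (gated by ICL3)."""
    if icl3_length < 0:
        raise ValueError("icl3_length must be >= 0")
    if icl3_length < threshold:
        return Regime.interface_specificity
    return Regime.gated_by_ICL3


def coupling_overlap(
    lengths: Mapping[str, int],
    couplings: Mapping[str, frozenset],
    threshold: int = DEFAULT_THRESHOLD,
    families: Sequence[str] = ("Gs", "Gq", "Gi"),
) -> dict[Regime, RegimeSummary]:
    """Per-regime Venn-region counts of G-protein coupling sets.

    Receptors with an empty coupling set (after restriction to ``families``)
    are excluded with a warning. The promiscuity index is the fraction of a
    regime's receptors coupling to two or more families.
    """
    fam_set = frozenset(families)
    summaries = {r: RegimeSummary(regime=r, n=0) for r in Regime}
    for rid, length in lengths.items():
        cset = frozenset(couplings.get(rid, frozenset())) & fam_set
        if not cset:
            warnings.warn(f"{rid}: empty coupling set, excluded from overlap counts")
            continue
        s = summaries[classify_regime(length, threshold)]
        s.n += 1
        s.overlap_counts[cset] = s.overlap_counts.get(cset, 0) + 1
    for s in summaries.values():
        if s.n:
            multi = sum(c for k, c in s.overlap_counts.items() if len(k) >= 2)
            s.promiscuity_index = multi / s.n
    return summaries


def cognate_secondary_gap(profiles: Iterable[CouplingProfile]) -> pd.DataFrame:
    """Cognate (highest log(Emax/EC50)) vs secondary (second-highest) coupling.

    Receptors whose profile covers a single family are excluded. Ties are
    broken by the fixed family order Gs > Gi > Gq > G12; a tied cognate and
    secondary report gap 0.
    """
    prio = {f: i for i, f in enumerate(FAMILY_ORDER)}
    rows = []
    for prof in profiles:
        if len(prof.values) < 2:
            continue
        ordered = sorted(
            prof.values.items(),
            key=lambda kv: (-kv[1], prio.get(kv[0], len(prio))),
        )
        (cog_f, cog_v), (sec_f, sec_v) = ordered[0], ordered[1]
        rows.append(
            {
                "receptor_id": prof.receptor_id,
                "cognate_family": cog_f,
                "cognate_value": cog_v,
                "secondary_family": sec_f,
                "secondary_value": sec_v,
                "gap": cog_v - sec_v,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "receptor_id",
            "cognate_family",
            "cognate_value",
            "secondary_family",
            "secondary_value",
            "gap",
        ],
    )


def regime_contrast(
    scores: Iterable[ConservationScore],
    lengths: Mapping[str, int],
    threshold: int = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Descriptive contrast of conservation distributions between regimes.

    Returns per-regime mean, sd and IQR plus the short-minus-long mean
    difference and the short/long IQR ratio (no hypothesis test). A regime
    with fewer than two scored receptors is flagged degenerate.
    """
    buckets: dict[Regime, list[float]] = {r: [] for r in Regime}
    for sc in scores:
        if sc.degenerate or np.isnan(sc.score):
            continue
        buckets[classify_regime(lengths[sc.receptor_id], threshold)].append(sc.score)

    rows = []
    stats = {}
    for regime, vals in buckets.items():
        arr = np.asarray(vals, dtype=float)
        degenerate = arr.size < 2
        mean = float(arr.mean()) if arr.size else float("nan")
        sd = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
        iqr = (
            float(np.percentile(arr, 75) - np.percentile(arr, 25))
            if arr.size >= 2
            else float("nan")
        )
        stats[regime] = (mean, iqr)
        rows.append(
            {
                "regime": regime.value,
                "n": int(arr.size),
                "mean": mean,
                "sd": sd,
                "iqr": iqr,
                "degenerate": degenerate,
            }
        )
    df = pd.DataFrame(rows)
    short_mean, short_iqr = stats[Regime.interface_specificity]
    long_mean, long_iqr = stats[Regime.gated_by_ICL3]
    df.attrs["mean_difference"] = short_mean - long_mean
    df.attrs["spread_ratio"] = (
        short_iqr / long_iqr if long_iqr and not np.isnan(long_iqr) else float("nan")
    )
    return df


def read_interface_alignment(path) -> InterfaceAlignment:
    """Read an interface alignment TSV: rows = receptors, a ``group`` column,
    remaining columns = interface-position labels holding residues/gaps."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "group" not in df.columns:
        raise ValueError("alignment table needs a 'group' column")
    group = df["group"].to_dict()
    res = df.drop(columns=["group"])
    return InterfaceAlignment(
        receptor_ids=[str(r) for r in res.index],
        positions=[str(c) for c in res.columns],
        residues=res.to_numpy(dtype="<U1"),
        group={str(k): str(v) for k, v in group.items()},
    )
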