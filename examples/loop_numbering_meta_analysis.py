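"""Extract an ICL3 segment and aggregate mutation effects in N/C coordinates.

ICL3 lengths vary ~10-240 aa across receptors, so mutation effects are
compared on a common frame: positions are numbered N1..Nn from the TM5 side
and Cn..C1 from the TM6 side, then rescaled onto the shortest loop in the
corpus (22 aa).
"""

from icl3kit.receptor_topology import (
    EffectMetric,
    MutationKind,
    MutationRecord,
    ReceptorRecord,
    aggregate_mutation_effects,
    extract_icl3,
    map_to_nc_coordinate,
)

# A beta2AR-like record: ICL3 annotated as residues 236-257 (22 aa).
receptor = ReceptorRecord(
    "B2AR", "A" * 235 + "SDEAKRQLQKIDKSEGRFHVQN" + "A" * 156,
    segments={"TM5": (206, 235), "ICL3": (236, 257), "TM6": (258, 290)},
)
segment = extract_icl3(receptor)
print(f"ICL3 interval {segment.start}-{segment.end}, length {segment.length}")
print(f"loop position 15 in N/C numbering: {map_to_nc_coordinate(15, segment.length)}")

# Three mutation reports: a triple-alanine mutant spans three loop positions
# and contributes its effect size (mut - wt) to each of them.
records = [
    MutationRecord("B2AR", (15, 16, 17), MutationKind.substitution,
                   EffectMetric.Emax, wt_value=1.0, mut_value=1.6),
    MutationRecord("B2AR", (6,), MutationKind.substitution,
                   EffectMetric.Emax, wt_value=1.0, mut_value=0.9),
    MutationRecord("LONG_R", (40,), MutationKind.substitution,
                   EffectMetric.Emax, wt_value=1.0, mut_value=1.2),
]
table = aggregate_mutation_effects(records, {"B2AR": 22, "LONG_R": 44})
print("\nPer-position effect table (positions on the 22-aa frame):")
print(table[["position", "metric", "count", "mean_delta"]].to_string(index=False))
# mean_delta > 0 means the mutation increased the metric relative to wild type;
# the LONG_R position 40 of a 44-aa loop lands on normalized position 20.
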