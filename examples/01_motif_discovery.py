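"""Discriminative motif discovery on a simulated binder/non-binder family.

Plants a five-residue motif in six positive sequences, a one-substitution
decoy in one negative, and searches for substrings present in every
positive and absent from every negative.
"""

from palmkit import MotifFamilySpec, find_discriminative_motifs, simulate_motif_family

spec = MotifFamilySpec(motif="WQHKD", length=300, seed=42)
family, truth = simulate_motif_family(spec)
report = find_discriminative_motifs(family)

print(f"planted motif: {truth['motif']} (decoy {truth['decoy']} in {truth['decoy_ids']})")
print(f"discriminative motifs found: {len(report.motifs)}")
print(f"maximal motifs: {[m.string for m in report.maximal]}")
for motif in report.maximal:
    first = next(iter(motif.occurrences.items()))
    print(f"  {motif.string}: e.g. {first[0]} at position {first[1][0]}")
# The maximal motif contains the plant; shorter discriminative substrings
# of it are suppressed so the family's shared signature is reported once.
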