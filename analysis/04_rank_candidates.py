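"""Rank substitution candidates at the focal gate position.

Classifies residues at position 200 as favored/avoided against the pooled
background and ranks the favored non-reference residues by observed
frequency — the substitutions evolution has oversampled at this site.

Reads results/profile.tsv, writes results/candidates.tsv.
"""

from pathlib import Path

from orthomut.design import candidate_substitutions
from orthomut.profile import classify_preferences, read_profile_table
from orthomut.simulate import default_annotation

base = Path(__file__).resolve().parent.parent / "results"
annotation = default_annotation()
profile = read_profile_table(base / "profile.tsv")
focal = annotation.focal_position

preference = classify_preferences(profile, focal, min_count=5)
candidates = candidate_substitutions(profile, preference, annotation, k=5)

with open(base / "candidates.tsv", "w") as fh:
    fh.write("rank\tmutation\talt_residue\tfrequency\tlog_odds\n")
    for c in candidates:
        fh.write(f"{c.rank}\t{c.label}\t{c.alt_residue}\t"
                 f"{c.frequency:.4f}\t{c.log_odds:.3f}\n")

print(f"favored residues at position {focal}: {sorted(preference.favored)}")
print("top substitution candidates:")
for c in candidates:
    print(f"  {c.rank}. {c.label}  freq={c.frequency:.3f}  "
          f"log2(obs/bg)={c.log_odds:+.2f}")
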