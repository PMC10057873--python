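"""Digest the two rice storage proteins with the gastrointestinal protease
cocktail and summarise the released fragments by length class.

The 2–5-residue class is the window assumed passively absorbable across the
epithelial barrier; it is the pool from which docking candidates are drawn.
"""

from oryzapep import classify_lengths, default_rules, digest, study_proteins

rules = default_rules()
print("enzymes:", ", ".join(r.enzyme_name for r in rules))

for protein in study_proteins():
    result = digest(protein, rules)
    dist = classify_lengths(result)
    print(f"\n{protein.id} ({len(protein)} residues) -> {dist.n_total} fragments")
    print(f"  length 1   : {dist.n_len1:4d}  ({dist.pct_len1:.2f} %)")
    print(f"  length 2-5 : {dist.n_len2to5:4d}  ({dist.pct_len2to5:.2f} %)")
    print(f"  length >5  : {dist.n_gt5:4d}  ({dist.pct_gt5:.2f} %)")

print("\nprolamin digest, hyphen-delimited:")
prolamin = study_proteins()[1]
print(digest(prolamin, rules).hyphenated())
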