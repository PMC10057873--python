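"""Synthetic-sequence sanity checks of the digestion engine.

For i.i.d. random sequences in which the combined cut-after residues have
frequency p, every internal bond is cut independently with probability p,
so the expected fragment count is 1 + (N-1)p.  A correct engine must land
within sampling error of that law.
"""

from oryzapep import default_rules, digest, random_protein
from oryzapep.synthdata import storage_protein_composition, uniform_composition

rules = default_rules()
n = 100_000

protein = random_protein(uniform_composition(length=n, seed=7))
p = 9 / 20  # 9 of 20 residues are in the combined cut-after set
count = digest(protein, rules).n_fragments
expected = 1 + (n - 1) * p
se = ((n - 1) * p * (1 - p)) ** 0.5
print(f"uniform composition, N={n}: {count} fragments "
      f"(expected {expected:.0f} +/- {se:.0f})")

rich = random_protein(storage_protein_composition(length=n, seed=7, gln=0.18))
print(f"glutamine-rich draw: Gln frequency = {rich.sequence.count('Q') / n:.3f} "
      "(target 0.18, emulating cereal storage proteins)")
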