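"""Sequence-derived physicochemistry and rule-of-five verdicts for the five
high-affinity candidate peptides and the small-molecule control antagonist.

Molecular weight comes from summed residue formulas plus one water; donor
and acceptor counts from neutral-form contribution tables; the partition
coefficients here are injected external predictor values (the shipped
additive estimate is used when none is available).
"""

from oryzapep import lipinski, peptide_properties
from oryzapep.pepchem import GW9662_FORMULA, average_mw
from oryzapep.screening import packaged_logp_table

logp = packaged_logp_table()

print(f"{'peptide':8s} {'MW':>8s} {'logP':>6s} {'HBD':>4s} {'HBA':>4s}  verdict")
for peptide in ["IVPQH", "PIVF", "IIQGR", "QPY", "QSPVF"]:
    props = peptide_properties(peptide, logp_override=logp.get(peptide))
    verdict = lipinski(props)
    call = "orally absorbable" if verdict.orally_absorbable else f"{verdict.violation_count} violations"
    print(f"{peptide:8s} {props.mw_average:8.2f} {props.logp_estimate:6.2f} "
          f"{props.hbd:4d} {props.hba:4d}  {call}")

print(f"\ncontrol antagonist (from formula): MW = {average_mw(GW9662_FORMULA):.2f} g/mol")
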