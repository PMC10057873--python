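"""Run the full screening pipeline on the packaged study inputs.

Digest both storage proteins, keep the absorbable 2–5-mers, join them with
the packaged docking-server scores, apply the −160 high-affinity threshold,
and screen the survivors with the Lipinski rule of five.  The final list is
the peptides predicted to be both high-affinity PPARγ binders and orally
absorbable.
"""

from oryzapep import run_pipeline

report = run_pipeline()
print(report.summary())

print("\nhigh-affinity candidates:")
cols = ["fraction", "peptide", "length", "affinity_score", "mw", "logp", "hbd",
        "hba", "lipinski_violations", "orally_absorbable"]
print(report.high_affinity[cols].to_string(index=False))

print("\nprovenance:", dict(report.provenance))
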