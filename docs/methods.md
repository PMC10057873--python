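# Methods

## Digestion model

Proteolysis is simulated as an idealised, complete digestion: every bond
that satisfies any enzyme's specificity is cleaved, and no other bond is.
A rule is a P1 cut-after residue set plus an optional P1′ exception set
(`not_before`); position *i* is cut iff some rule has `seq[i-1]` in its
cut-after set and `seq[i]` outside its exception set.  Multi-enzyme
digestion unions the cut sites of all enzymes before splitting once
("simultaneous" semantics), which models prolonged simultaneous exposure
to the cocktail; a sequential mode exists and coincides with it whenever
no rule carries exceptions.  There is no kinetic or missed-cleavage
modelling and no pH-dependent switching: the gastric/duodenal phases are
collapsed into one rule set.

The default cocktail is pepsin (pH 1.3) {F, L}, trypsin {K, R} and
chymotrypsin {W, Y, F, M, L, N, H}, all exception-free, loaded from
`data/enzymes.yaml`.  The combined set {F, L, W, Y, M, K, R, N, H} with no
P1′ exceptions is the validated core: it reproduces the published
hydrolysis fragment lists of both rice storage proteins exactly, including
Tyr|Pro cleavage (which rules out a "not before proline" exception for
chymotrypsin in this convention).  The attribution of {M, N, H} to
individual enzymes follows BIOPEP-style conventions and is configuration,
not a validated claim — only the union is exercised by the reference data.

Fragment counting is positional: repeated occurrences of the same peptide
are distinct digestion events.  Under occurrence counting the prolamin
digest gives 42 fragments split 18/14/10 over the {1, 2–5, >5} length
classes (42.86/33.33/23.81 %, two decimals, half-up rounding).  The
published per-class summary for glutelin (85 total, 66/16/3) is *not*
consistent with digesting the published glutelin fragment list under any
counting convention we tried — the same list concatenates to 499 residues
and re-digests into 185 fragments (66/106/13; the singleton count is the
only agreeing entry).  The package reproduces the fragment list exactly
and leaves the summary-table discrepancy unresolved; glutelin class counts
are therefore not used as reference values anywhere.

A related bookkeeping note: the published tables attribute the tripeptide
QPY to the prolamin fraction, but in the published fragment lists QPY is a
glutelin product (prolamin yields QY).  The pipeline joins docking scores
to digest products by sequence and reports the actual parent, so QPY
appears under glutelin in our reports.

## Peptide physicochemistry

All properties are computed on the neutral, non-zwitterionic form of the
linear peptide with free termini; there is no pKa or charge-state model,
and no 3D structure is ever built.

* **Formula / mass.** Elemental formula = Σ residue formulas + one water;
  average molecular weight is the dot product with IUPAC standard average
  atomic masses (C 12.011, H 1.008, N 14.007, O 15.999, S 32.06,
  Cl 35.45), reported to two decimals.  Agreement with the study's ADME
  table is within ±0.05 g/mol for every candidate.  The control
  antagonist GW9662 is a small molecule, not a peptide: its mass comes
  from its formula C13H9ClN2O3 and its donor/acceptor counts are fixture
  values.
* **Donors/acceptors.** Atom-count contribution tables.  Donors: the
  N-terminal amine (proline's secondary amine included), one per
  non-proline backbone amide NH, the C-terminal carboxylic OH, and side
  chains (S/T/Y/N/Q/K/W/H +1, R +3).  Acceptors: n−1 backbone carbonyl
  oxygens, two carboxyl oxygens, the N-terminal amine nitrogen, and side
  chains (N/Q +1 — amide oxygen only, amide nitrogens never accept,
  D/E +2, S/T/Y +1, H +1 pyridine-type nitrogen, R +1, K +1).  This
  neutral-form convention reproduces the published counts for QPY, IIQGR,
  IVPQH and QSPVF; the published donor count for PIVF (7) is not
  reproducible by any atom count on that sequence (the maximum is 5:
  proline N-terminus, three backbone NHs, carboxyl OH) and is treated as
  an error in the source table.
* **Lipophilicity.** A residue-additive estimate (hydrophobic/aromatic
  residues positive, polar/ionisable negative, one free-termini
  correction).  It is a deterministic ranking device and is *not*
  numerically comparable to GB/SA-based predictors such as iLOGP; where
  external predictor values exist they are injected via
  `logp_override` / an external TSV, and the packaged pipeline fixture
  does exactly that.  Both routes classify the same two candidates as
  absorbable.
* **Rule of five.** MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10; a molecule
  fails at two or more violations.  The acceptor cutoff is the integer 10
  (the value 10.6 that circulates in some secondary sources appears to be
  a typographical artifact); the threshold object is configurable so 10.6
  can be restored.

## Screening pipeline

Digest → 2–5-residue window → sequence join with affinity scores →
score ≤ −160 threshold → properties → verdict.  Scores and binding
energies are always inputs (TSV or the packaged fixture of published
values); the docking engines themselves are outside the package's scope.
Window peptides without scores are reported as `unscored` rather than
dropped, so the output table is a complete audit of the absorbable window;
in strict join mode a score for a peptide absent from the window is an
error, in lenient mode it is logged.  Reports are deterministic for a
given configuration and carry a provenance block (proteins, enzymes,
window, threshold, input hash).

The digestibility/bioaccessibility ratios are direct percentage forms:
IVPD = 100·FP/IP (protein percentage after the duodenal phase over time
zero) and IVPB = 100·Ptd/Pti (dialyzed over initial protein
concentration).  Physically implausible inputs (FP > IP, Ptd > Pti) warn
rather than fail, since transient measurement artifacts can produce them.

## Docking-adjacent geometry

* **Grid box.** The search box over the receptor's antiadipogenic region
  defaults to center (7.745, 50.606, 57.552) Å, 70×40×40 grid points,
  0.375 Å spacing (edge lengths 26.25 × 15 × 15 Å as points × spacing).
  Whether a tool consumes dimensions as points or Å differs between
  programs; both the points and the computed Å extents are emitted, and
  the config text round-trips.
* **Hydrogen bonds.** Donor–acceptor heavy-atom distance ≤ 3.5 Å; when
  the donor molecule carries explicit hydrogens, additionally the best
  D–H···A angle ≥ 120° (hydrogens are assigned to their heavy atom within
  1.25 Å).  Structures without hydrogens are judged on distance alone.
  These are standard geometric values, fully configurable; detection is
  invariant under rigid motions and symmetric under role swap.  Donor and
  acceptor typing uses a neutral residue template table for the 20
  protein residues and an N/O element heuristic for ligands and unknown
  residues; no bond-perception engine is involved.  Only hydrogen bonds
  are detected — no π-stacking or hydrophobic-contact model.
* **Contacts.** A pose's contacted receptor residues are intersected with
  the antiadipogenic hotspot set; contacts outside the set (e.g. the
  activation-helix Tyr473 reported for QPY, which the hotspot definition
  omits) are flagged separately, never dropped.

## Synthetic data

`synthdata` makes every stage testable without downloads.  Random proteins
are i.i.d. draws from a residue-composition vector (uniform, or a
glutamine-rich preset with P(Q)=0.18 emulating cereal storage proteins);
they reproduce neither residue autocorrelation nor domain structure of
real proteins, so passing digestion tests on them validates the splitting
arithmetic and the i.i.d. fragment-count law E[#fragments] = 1 + (N−1)p,
not biological realism.  Planted geometries put ligand amine donors (with
explicit hydrogen, placed by the law of sines to hit the target D–H···A
angle exactly) against receptor backbone carbonyl acceptors at exact
distance, with bond sites spaced ≥ 4× the cutoff apart and decoy
heteroatoms beyond 2× the cutoff, so recovery tests are exact rather than
statistical; a seed-deterministic rigid motion randomises the frame
without disturbing the geometry.  These fixtures contain no realistic
fold or pose physics.

## Problem sizes and determinism

All reference computations run on the packaged study inputs (149- and
499-residue proteins, five scored peptides) in well under a second.  The
statistical suites use one length-10⁵ i.i.d. draw (fragment-count law,
composition convergence, 3-standard-error bands) and a few hundred random
sequences ≤ 500 residues for oracle equivalence.  Every stochastic
component takes an explicit integer seed; property tests are
derandomised.

## Known limitations

Complete-digestion assumption (no partial proteolysis); neutral-form
counting (no pH 7.4 charge states, which real absorption chemistry has);
the lipophilicity estimate is a ranking device, not a calibrated logP;
hydrogen-bond detection ignores donor hybridisation and secondary
geometric criteria; the packaged substrate sequences are reconstructions
from the published fragment lists and may differ from database entries
(e.g. by signal peptides), which cannot be checked offline and is
recorded in each record's `source` field.
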