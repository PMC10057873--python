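"""Peptide physicochemical properties from sequence, and Lipinski screening.

Everything here is computed on the neutral (non-zwitterionic) form of a
linear peptide with free termini: elemental formula, average molecular
weight, hydrogen-bond donor/acceptor atom counts from residue contribution
tables, and an additive lipophilicity estimate.

The donor/acceptor tables count atoms, not hydrogens, following the usual
drug-likeness convention: a donor is an N or O bearing at least one
hydrogen; an acceptor is an N or O able to accept a hydrogen bond (amide
nitrogens are excluded as acceptors, amide carbonyl oxygens included).

The lipophilicity estimate is a simple residue-additive scale shipped with
the package.  It is deterministic and suitable for ranking hydrophobic
against polar peptides, but it is NOT numerically comparable to the
GB/SA-based iLOGP values printed by SwissADME; when such external values
exist they can be injected (see :func:`load_external_logp` and the
``logp_override`` argument of :func:`peptide_properties`).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from pathlib import Path
from typing import Mapping

from .sequences import SequenceError, validate_residues

__all__ = [
    "ElementalFormula",
    "PeptideProperties",
    "LipinskiThresholds",
    "LipinskiVerdict",
    "peptide_formula",
    "parse_formula",
    "average_mw",
    "count_hbd",
    "count_hba",
    "estimate_logp",
    "peptide_properties",
    "lipinski",
    "load_external_logp",
    "GW9662_FORMULA",
]

# Standard IUPAC average atomic masses (g/mol).
ATOMIC_MASS = {
    "C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06,
    "Cl": 35.45,
}

# Residue formulas (amino acid minus one water): C, H, N, O, S.
_RESIDUE_FORMULA: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}

# Side-chain donor atoms (N/O with >=1 H), neutral form.
_HBD_SIDE = {"S": 1, "T": 1, "Y": 1, "N": 1, "Q": 1, "K": 1, "W": 1, "H": 1, "R": 3}
# Side-chain acceptor atoms; amide N of Asn/Gln excluded, carbonyl O included;
# His contributes its pyridine-type nitrogen.
_HBA_SIDE = {"N": 1, "Q": 1, "D": 2, "E": 2, "S": 1, "T": 1, "Y": 1, "H": 1, "R": 1, "K": 1}

# Residue-additive lipophilicity contributions (octanol-water tendency,
# loosely Crippen-flavoured: aromatics and branched aliphatics positive,
# charged/polar side chains negative).  One free-termini correction applies
# per peptide so the scale is additive over bond formation.
_LOGP_RESIDUE = {
    "A": 0.12, "R": -1.80, "N": -1.05, "D": -1.20, "C": 0.29,
    "Q": -0.95, "E": -1.10, "G": -0.07, "H": -0.70, "I": 0.98,
    "L": 0.98, "K": -1.35, "M": 0.56, "F": 1.25, "P": 0.10,
    "S": -0.62, "T": -0.38, "W": 1.10, "Y": 0.55, "V": 0.72,
}
_LOGP_TERMINI = -1.30  # free amine + carboxylic acid, once per chain

# Positive-control antagonist (a chloro-nitro-benzamide), handled at the
# formula level: it is not a peptide and its donor/acceptor counts come from
# its published structure rather than the residue tables.
GW9662_FORMULA: Mapping[str, int] = {"C": 13, "H": 9, "Cl": 1, "N": 2, "O": 3}


@dataclass(frozen=True)
class ElementalFormula:
    """Element → atom-count map for a molecule (non-negative counts)."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n}
        if any(n < 0 for n in clean.values()):
            raise ValueError("negative atom count")
        unknown = set(clean) - set(ATOMIC_MASS)
        if unknown:
            raise ValueError(f"elements without a mass entry: {sorted(unknown)}")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(Counter(self.counts) + Counter(other.counts))

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = ["C", "H"] + sorted(set(self.counts) - {"C", "H"})
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] != 1 else ''}"
            for el in order if el in self.counts
        )


@dataclass(frozen=True)
class LipinskiThresholds:
    """Rule-of-five cutoffs; a molecule fails the screen at
    ``max_violations_exclusive`` or more violations (default 2)."""

    mw_max: float = 500.0
    logp_max: float = 5.0
    hbd_max: float = 5
    hba_max: float = 10
    max_violations_exclusive: int = 2

    def __post_init__(self) -> None:
        if min(self.mw_max, self.logp_max, self.hbd_max, self.hba_max) <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_violations_exclusive <= 0:
            raise ValueError("max_violations_exclusive must be positive")


@dataclass(frozen=True)
class LipinskiVerdict:
    """Per-criterion pass flags and the oral-absorbability call."""

    mw_ok: bool
    logp_ok: bool
    hbd_ok: bool
    hba_ok: bool
    violation_count: int
    orally_absorbable: bool

    def __post_init__(self) -> None:
        n = sum(1 for ok in (self.mw_ok, self.logp_ok, self.hbd_ok, self.hba_ok) if not ok)
        if n != self.violation_count:
            raise ValueError("violation_count inconsistent with flags")


@dataclass(frozen=True)
class PeptideProperties:
    """Sequence-derived physicochemistry of one peptide."""

    sequence: str
    formula: ElementalFormula
    mw_average: float
    hbd: int
    hba: int
    logp_estimate: float
    logp_source: str = "additive-estimate"


def peptide_formula(sequence: str) -> ElementalFormula:
    """Elemental formula of the neutral linear peptide (residues + one water).

    Additive over concatenation minus one water per peptide bond formed.
    """
    seq = validate_residues(sequence)
    if not seq:
        raise SequenceError("empty sequence")
    totals = Counter({"H": 2, "O": 1})  # terminal water
    for r in seq:
        c, h, n, o, s = _RESIDUE_FORMULA[r]
        totals.update({"C": c, "H": h, "N": n, "O": o, "S": s})
    return ElementalFormula(totals)


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-style formula string like ``"C13H9ClN2O3"``."""
    import re

    counts: Counter[str] = Counter()
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
        counts[m.group(1)] += int(m.group(2) or 1)
        pos = m.end()
    if pos != len(text) or not counts:
        raise ValueError(f"cannot parse formula {text!r}")
    return ElementalFormula(counts)


def average_mw(formula: ElementalFormula | Mapping[str, int]) -> float:
    """Average molecular weight (g/mol) from standard atomic masses,
    reported to 2 decimals."""
    if not isinstance(formula, ElementalFormula):
        formula = ElementalFormula(formula)
    mw = sum(ATOMIC_MASS[el] * n for el, n in formula.counts.items())
    return round(mw, 2)


def count_hbd(sequence: str) -> int:
    """Hydrogen-bond donor atoms (N/O bearing ≥1 H), neutral peptide.

    N-terminal amine (including proline's secondary amine) +1; each
    non-proline backbone amide NH +1; C-terminal carboxylic OH +1; plus
    side-chain contributions (Arg guanidine counts all three nitrogens).
    """
    seq = validate_residues(sequence)
    if not seq:
        raise SequenceError("empty sequence")
    n = 1                                        # N-terminal amine
    n += sum(1 for r in seq[1:] if r != "P")     # backbone amide NHs
    n += 1                                       # C-terminal COOH
    n += sum(_HBD_SIDE.get(r, 0) for r in seq)
    return n


def count_hba(sequence: str) -> int:
    """Hydrogen-bond acceptor atoms (accepting N/O), neutral peptide.

    Backbone carbonyl oxygens (n−1 for an n-mer) plus the two C-terminal
    carboxyl oxygens and the N-terminal amine nitrogen; amide nitrogens are
    never acceptors.
    """
    seq = validate_residues(sequence)
    if not seq:
        raise SequenceError("empty sequence")
    n = (len(seq) - 1) + 2 + 1
    n += sum(_HBA_SIDE.get(r, 0) for r in seq)
    return n


def estimate_logp(sequence: str) -> float:
    """Additive residue-contribution lipophilicity estimate (unitless).

    Deterministic ranking score: hydrophobic/aromatic residues raise it,
    polar and ionisable residues lower it, with a single free-termini
    correction.  Not comparable to GB/SA-based octanol-water predictors;
    inject external values where they exist.
    """
    seq = validate_residues(sequence)
    if not seq:
        raise SequenceError("empty sequence")
    return round(sum(_LOGP_RESIDUE[r] for r in seq) + _LOGP_TERMINI, 2)


def peptide_properties(
    sequence: str, *, logp_override: float | None = None
) -> PeptideProperties:
    """All sequence-derived properties of one peptide in one record.

    ``logp_override`` injects an externally computed partition coefficient
    (e.g. from a structure-based predictor) in place of the shipped
    additive estimate; the provenance is recorded in ``logp_source``.
    """
    formula = peptide_formula(sequence)
    return PeptideProperties(
        sequence=validate_residues(sequence),
        formula=formula,
        mw_average=average_mw(formula),
        hbd=count_hbd(sequence),
        hba=count_hba(sequence),
        logp_estimate=logp_override if logp_override is not None else estimate_logp(sequence),
        logp_source="external" if logp_override is not None else "additive-estimate",
    )


def lipinski(
    props: PeptideProperties,
    thresholds: LipinskiThresholds = LipinskiThresholds(),
) -> LipinskiVerdict:
    """Rule-of-five verdict: orally absorbable iff fewer than
    ``max_violations_exclusive`` criteria are violated."""
    mw_ok = props.mw_average <= thresholds.mw_max
    logp_ok = props.logp_estimate <= thresholds.logp_max
    hbd_ok = props.hbd <= thresholds.hbd_max
    hba_ok = props.hba <= thresholds.hba_max
    violations = sum(1 for ok in (mw_ok, logp_ok, hbd_ok, hba_ok) if not ok)
    return LipinskiVerdict(
        mw_ok=mw_ok,
        logp_ok=logp_ok,
        hbd_ok=hbd_ok,
        hba_ok=hba_ok,
        violation_count=violations,
        orally_absorbable=violations < thresholds.max_violations_exclusive,
    )


def load_external_logp(path: str | Path) -> dict[str, float]:
    """Read an external lipophilicity table: TSV with columns
    ``peptide`` and ``logp`` (header required)."""
    import csv

    out: dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"peptide", "logp"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected 'peptide' and 'logp' columns")
        for row in reader:
            out[row["peptide"].strip().upper()] = float(row["logp"])
    return out
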