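"""Rule-based simulation of simultaneous multi-enzyme proteolysis.

Each protease is described by its P1 specificity — the residues it cleaves
C-terminal to — plus an optional P1' exception set (residues that block
cleavage when they immediately follow the scissile bond).  Multi-enzyme
digestion is simultaneous: the cut sites of all enzymes are unioned and the
substrate is split once, which models prolonged exposure of the substrate to
the full gastrointestinal protease cocktail.  A sequential mode (one enzyme
after another) is available but is equivalent for exception-free rules.

The default rule set (pepsin at gastric pH, trypsin, chymotrypsin) has a
combined cut-after set {F, L, W, Y, M, K, R, N, H} with no P1' exceptions.

Fragment counting is positional: repeated occurrences of the same peptide
are distinct fragments, so counts and length-class percentages refer to
digestion events, not unique sequences.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .sequences import (
    CANONICAL_RESIDUES,
    PeptideFragment,
    ProteinRecord,
    SequenceError,
    validate_residues,
)

__all__ = [
    "CleavageRule",
    "DigestResult",
    "LengthDistribution",
    "load_rules",
    "default_rules",
    "find_cut_sites",
    "digest",
    "digest_sequential",
    "classify_lengths",
    "select_by_length",
]


@dataclass(frozen=True)
class CleavageRule:
    """Protease cleavage specificity.

    ``cut_after`` is the P1 set (cleavage C-terminal to these residues);
    ``not_before`` is the P1' exception set — a cut is suppressed when the
    residue after the scissile bond is in it.
    """

    enzyme_name: str
    ec_number: str
    cut_after: frozenset[str]
    not_before: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        cut = frozenset(str(r).upper() for r in self.cut_after)
        blk = frozenset(str(r).upper() for r in self.not_before)
        if not cut:
            raise ValueError(f"{self.enzyme_name}: cut_after must be non-empty")
        bad = (cut | blk) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"{self.enzyme_name}: non-canonical residues {sorted(bad)}")
        object.__setattr__(self, "cut_after", cut)
        object.__setattr__(self, "not_before", blk)


@dataclass(frozen=True)
class DigestResult:
    """Outcome of digesting one protein: cut sites and the tiling fragments.

    A cut at position ``i`` separates ``sequence[:i]`` from ``sequence[i:]``.
    Fragments tile the parent: consecutive half-open intervals starting at 0
    and ending at the parent length, whose concatenation is the parent.
    """

    parent_id: str
    cut_sites: tuple[int, ...]
    fragments: tuple[PeptideFragment, ...]
    enzymes: tuple[str, ...]

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def sequences(self) -> list[str]:
        """Fragment sequences in positional order."""
        return [f.sequence for f in self.fragments]

    def hyphenated(self) -> str:
        """The digest in the hyphen-delimited style of published tables."""
        return "-".join(self.sequences())

    def to_tsv(self) -> str:
        """Fragments as TSV: parent_id, start, end, length, sequence."""
        lines = ["parent_id\tstart\tend\tlength\tsequence"]
        lines += [
            f"{f.parent_id}\t{f.start}\t{f.end}\t{len(f)}\t{f.sequence}"
            for f in self.fragments
        ]
        return "\n".join(lines) + "\n"


def _round2(x: float) -> float:
    # Table-style 2-decimal, half-up rounding (not banker's).
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LengthDistribution:
    """Fragment counts and percentages by bioaccessibility length class.

    Classes follow the passive-absorption convention: single residues,
    the absorbable 2–5-residue window, and longer peptides.
    Percentages are reported to 2 decimals (half-up) and sum to 100
    within rounding.
    """

    n_total: int
    n_len1: int
    n_len2to5: int
    n_gt5: int

    def __post_init__(self) -> None:
        if self.n_len1 + self.n_len2to5 + self.n_gt5 != self.n_total:
            raise ValueError("length-class counts do not sum to the total")

    @property
    def pct_len1(self) -> float:
        return _round2(100.0 * self.n_len1 / self.n_total)

    @property
    def pct_len2to5(self) -> float:
        return _round2(100.0 * self.n_len2to5 / self.n_total)

    @property
    def pct_gt5(self) -> float:
        return _round2(100.0 * self.n_gt5 / self.n_total)


def load_rules(path: str | Path | None = None) -> list[CleavageRule]:
    """Load a protease rule set from a YAML config.

    With no argument, loads the packaged default (pepsin/trypsin/
    chymotrypsin).  The config must define every enzyme it names fully;
    unknown or incomplete entries are a config error, never a silent no-op.
    """
    if path is None:
        text = importlib.resources.files("oryzapep.data").joinpath("enzymes.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "enzymes" not in doc or not doc["enzymes"]:
        raise ValueError("rule config must contain a non-empty 'enzymes' list")
    rules = []
    for entry in doc["enzymes"]:
        missing = {"name", "ec", "cut_after"} - set(entry)
        if missing:
            raise ValueError(f"enzyme entry {entry!r} missing fields {sorted(missing)}")
        rules.append(
            CleavageRule(
                enzyme_name=str(entry["name"]),
                ec_number=str(entry["ec"]),
                cut_after=frozenset(entry["cut_after"]),
                not_before=frozenset(entry.get("not_before") or ()),
            )
        )
    return rules


def default_rules() -> list[CleavageRule]:
    """The gastrointestinal cocktail: pepsin (pH 1.3), trypsin, chymotrypsin."""
    return load_rules(None)


def find_cut_sites(sequence: str, rules: Sequence[CleavageRule]) -> list[int]:
    """Union of cut positions over all rules (simultaneous digestion).

    Position ``i`` (0 < i < len) is a cut iff some rule has
    ``sequence[i-1]`` in its ``cut_after`` and ``sequence[i]`` not in its
    ``not_before``.  The position after the terminal residue is never a
    cut — the C-terminal fragment simply ends there.
    """
    if not sequence:
        raise SequenceError("cannot digest an empty sequence")
    seq = validate_residues(sequence)
    if not rules:
        raise ValueError("at least one cleavage rule is required")
    sites: set[int] = set()
    for rule in rules:
        for i in range(1, len(seq)):
            if seq[i - 1] in rule.cut_after and seq[i] not in rule.not_before:
                sites.add(i)
    return sorted(sites)


def digest(protein: ProteinRecord, rules: Sequence[CleavageRule]) -> DigestResult:
    """Digest *protein*, returning cut sites and the tiling fragment list.

    Fragments are the maximal substrings between consecutive cut sites;
    positional duplicates are retained as distinct fragments.
    """
    seq = protein.sequence
    sites = find_cut_sites(seq, rules)
    bounds = [0, *sites, len(seq)]
    fragments = tuple(
        PeptideFragment(
            sequence=seq[a:b], parent_id=protein.id, start=a, end=b
        )
        for a, b in zip(bounds, bounds[1:])
    )
    return DigestResult(
        parent_id=protein.id,
        cut_sites=tuple(sites),
        fragments=fragments,
        enzymes=tuple(r.enzyme_name for r in rules),
    )


def digest_sequential(protein: ProteinRecord, rules: Sequence[CleavageRule]) -> DigestResult:
    """Apply enzymes one after another, re-digesting the released fragments.

    For exception-free rules this coincides with :func:`digest`; it differs
    only when a P1' exception spans a cut made by an earlier enzyme.
    """
    pieces: list[tuple[int, str]] = [(0, protein.sequence)]
    for rule in rules:
        nxt: list[tuple[int, str]] = []
        for off, piece in pieces:
            bounds = [0, *find_cut_sites(piece, [rule]), len(piece)]
            nxt += [(off + a, piece[a:b]) for a, b in zip(bounds, bounds[1:])]
        pieces = nxt
    fragments = tuple(
        PeptideFragment(sequence=s, parent_id=protein.id, start=off, end=off + len(s))
        for off, s in pieces
    )
    return DigestResult(
        parent_id=protein.id,
        cut_sites=tuple(f.start for f in fragments[1:]),
        fragments=fragments,
        enzymes=tuple(r.enzyme_name for r in rules),
    )


def classify_lengths(result: DigestResult) -> LengthDistribution:
    """Histogram the digest into the {1, 2–5, >5} length classes."""
    if not result.fragments:
        raise ValueError("digest has no fragments")
    lengths = [len(f) for f in result.fragments]
    return LengthDistribution(
        n_total=len(lengths),
        n_len1=sum(1 for n in lengths if n == 1),
        n_len2to5=sum(1 for n in lengths if 2 <= n <= 5),
        n_gt5=sum(1 for n in lengths if n > 5),
    )


def select_by_length(
    result: DigestResult, min_len: int = 2, max_len: int = 5
) -> list[PeptideFragment]:
    """Fragments whose length falls in [min_len, max_len], positional order.

    The default 2–5 window is the passive-absorption (bioaccessibility)
    filter applied before docking triage.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError(f"invalid length window [{min_len}, {max_len}]")
    return [f for f in result.fragments if min_len <= len(f) <= max_len]
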