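"""End-to-end candidate screening pipeline and digestibility ratios.

The pipeline chains the steps of the in silico workflow: digest the
substrate proteins with the gastrointestinal protease cocktail, keep the
2–5-residue (passively absorbable) fragments, join them with docking-server
affinity scores, apply the high-affinity threshold, compute sequence-derived
physicochemistry and deliver a Lipinski verdict per candidate.

Docking scores are always consumed as input (from a TSV file or the
packaged fixture of published values), never computed: the scoring engines
are web servers / external binaries outside this package's scope.  Peptides
in the absorbable window that lack a score are reported as unscored rather
than dropped, so the report is a complete audit of the window.

Also implemented here are the two wet-lab companion ratios of the study:
in vitro protein digestibility (IVPD) and bioaccessibility (IVPB), simple
percentage ratios of protein measured after/before digestion and dialysis.
"""

from __future__ import annotations

import csv
import hashlib
import importlib.resources
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .pepchem import (
    LipinskiThresholds,
    lipinski,
    load_external_logp,
    peptide_properties,
)
from .proteolysis import (
    CleavageRule,
    default_rules,
    digest,
    select_by_length,
)
from .sequences import ProteinRecord, study_proteins, validate_residues

logger = logging.getLogger(__name__)

__all__ = [
    "AffinityRecord",
    "DigestibilityInputs",
    "PipelineConfig",
    "CandidateReport",
    "read_affinity_table",
    "packaged_affinity_table",
    "packaged_logp_table",
    "apply_affinity_threshold",
    "ivpd",
    "ivpb",
    "run_pipeline",
]

DEFAULT_AFFINITY_THRESHOLD = -160.0


@dataclass(frozen=True)
class AffinityRecord:
    """One docking-server score for one peptide (more negative = stronger)."""

    peptide: str
    score: float
    source: str = ""
    binding_energy: float | None = None
    interactions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptide", validate_residues(self.peptide, context="peptide"))


@dataclass(frozen=True)
class DigestibilityInputs:
    """Measured protein quantities for the IVPD / IVPB ratios.

    fp/ip: protein percentage at the end of the duodenal phase and at time
    zero; ptd/pti: dialyzed and initial protein concentrations (mg/mL).
    """

    fp: float
    ip: float
    ptd: float
    pti: float

    def __post_init__(self) -> None:
        if min(self.fp, self.ip, self.ptd, self.pti) < 0:
            raise ValueError("digestibility inputs must be non-negative")
        if self.fp > self.ip:
            warnings.warn("FP exceeds IP: digestibility above 100%", stacklevel=2)
        if self.ptd > self.pti:
            warnings.warn("Ptd exceeds Pti: bioaccessibility above 100%", stacklevel=2)


def ivpd(inputs: DigestibilityInputs) -> float:
    """In vitro protein digestibility: 100·FP/IP, to 2 decimals."""
    if inputs.ip == 0:
        raise ZeroDivisionError("IP (initial protein percentage) is zero")
    return round(100.0 * inputs.fp / inputs.ip, 2)


def ivpb(inputs: DigestibilityInputs) -> float:
    """In vitro protein bioaccessibility: 100·Ptd/Pti, to 2 decimals."""
    if inputs.pti == 0:
        raise ZeroDivisionError("Pti (initial protein concentration) is zero")
    return round(100.0 * inputs.ptd / inputs.pti, 2)


def read_affinity_table(path: str | Path, *, source: str | None = None) -> list[AffinityRecord]:
    """Read a docking-score TSV: columns ``peptide``, ``score`` and optional
    ``binding_energy``, ``interactions`` (semicolon-separated residues)."""
    path = Path(path)
    with open(path, newline="") as fh:
        return _parse_affinity(fh, source or str(path))


def packaged_affinity_table() -> list[AffinityRecord]:
    """The packaged fixture of published docking-server scores for the five
    high-affinity rice peptides."""
    text = importlib.resources.files("oryzapep.data").joinpath("hpepdock_scores.tsv").read_text()
    return _parse_affinity(io.StringIO(text), "packaged published scores")


def packaged_logp_table() -> dict[str, float]:
    """Packaged external partition-coefficient values (structure-based
    predictor output) for the candidates and the control."""
    text = importlib.resources.files("oryzapep.data").joinpath("ilogp_values.tsv").read_text()
    out: dict[str, float] = {}
    for row in csv.DictReader(io.StringIO(text), delimiter="\t"):
        out[row["peptide"].strip().upper()] = float(row["logp"])
    return out


def _parse_affinity(fh, source: str) -> list[AffinityRecord]:
    reader = csv.DictReader(fh, delimiter="\t")
    if reader.fieldnames is None or not {"peptide", "score"} <= set(reader.fieldnames):
        raise ValueError(f"{source}: expected 'peptide' and 'score' columns")
    records = []
    for row in reader:
        be = row.get("binding_energy")
        inter = row.get("interactions") or ""
        records.append(
            AffinityRecord(
                peptide=row["peptide"].strip(),
                score=float(row["score"]),
                source=source,
                binding_energy=float(be) if be not in (None, "") else None,
                interactions=tuple(t for t in inter.split(";") if t),
            )
        )
    return records


def apply_affinity_threshold(
    records: Sequence[AffinityRecord], threshold: float = DEFAULT_AFFINITY_THRESHOLD
) -> list[AffinityRecord]:
    """High-affinity triage: retain records with score ≤ *threshold*
    (the docking-server scale is negative; default −160), order preserved."""
    return [r for r in records if r.score <= threshold]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one screening run.

    With all defaults the pipeline reproduces the published study: the two
    packaged rice storage proteins, the gastrointestinal protease cocktail,
    the 2–5-residue absorbable window, the −160 affinity threshold, the
    packaged published docking scores, and injected external partition
    coefficients.
    """

    proteins: tuple[ProteinRecord, ...] | None = None
    rules: tuple[CleavageRule, ...] | None = None
    min_len: int = 2
    max_len: int = 5
    affinity_threshold: float = DEFAULT_AFFINITY_THRESHOLD
    affinity_path: str | None = None      # None → packaged fixture
    logp_path: str | None = None          # None → packaged fixture; "" → estimate only
    lipinski_thresholds: LipinskiThresholds = LipinskiThresholds()
    strict_join: bool = False             # error on scores absent from the digest


@dataclass(frozen=True)
class CandidateReport:
    """Pipeline output: one row per absorbable-window peptide occurrence,
    with affinity, properties and Lipinski verdict, plus a provenance block."""

    table: pd.DataFrame
    provenance: Mapping[str, str]

    @property
    def high_affinity(self) -> pd.DataFrame:
        return self.table[self.table["high_affinity"]]

    @property
    def absorbable(self) -> pd.DataFrame:
        """High-affinity candidates that pass the oral-absorbability screen."""
        return self.table[self.table["high_affinity"] & self.table["orally_absorbable"]]

    def to_tsv(self) -> str:
        """Deterministic TSV report body (identical config → identical bytes)."""
        buf = io.StringIO()
        self.table.to_csv(buf, sep="\t", index=False, float_format="%.2f")
        return buf.getvalue()

    def summary(self) -> str:
        n_window = len(self.table)
        n_scored = int(self.table["scored"].sum())
        hi = self.high_affinity
        absorbable = self.absorbable
        lines = [
            f"absorbable-window peptides (len {self.provenance['length_window']}): {n_window}",
            f"scored by docking server: {n_scored} (unscored reported, not dropped)",
            f"high affinity (score <= {self.provenance['affinity_threshold']}): "
            + (", ".join(hi["peptide"]) or "none"),
            "orally absorbable (rule-of-five): "
            + (", ".join(absorbable["peptide"]) or "none"),
        ]
        return "\n".join(lines)


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> CandidateReport:
    """Run digest → length filter → affinity join/threshold → properties →
    Lipinski, returning the full audit table.

    Raises if, under ``strict_join``, the affinity table names a peptide that
    is not a digest product in the absorbable window; in lenient mode such
    entries are logged and ignored.
    """
    proteins = list(config.proteins) if config.proteins is not None else study_proteins()
    rules = list(config.rules) if config.rules is not None else default_rules()

    if config.affinity_path is not None:
        affinities = read_affinity_table(config.affinity_path)
    else:
        affinities = packaged_affinity_table()
    by_peptide = {a.peptide: a for a in affinities}

    if config.logp_path is None:
        logp_ext: dict[str, float] = packaged_logp_table()
    elif config.logp_path == "":
        logp_ext = {}
    else:
        logp_ext = load_external_logp(config.logp_path)

    rows = []
    window_peptides: set[str] = set()
    for protein in proteins:
        result = digest(protein, rules)
        for frag in select_by_length(result, config.min_len, config.max_len):
            window_peptides.add(frag.sequence)
            aff = by_peptide.get(frag.sequence)
            props = peptide_properties(
                frag.sequence, logp_override=logp_ext.get(frag.sequence)
            )
            verdict = lipinski(props, config.lipinski_thresholds)
            high = aff is not None and aff.score <= config.affinity_threshold
            rows.append(
                {
                    "fraction": protein.id,
                    "peptide": frag.sequence,
                    "start": frag.start,
                    "end": frag.end,
                    "length": len(frag),
                    "scored": aff is not None,
                    "affinity_score": aff.score if aff else None,
                    "binding_energy": aff.binding_energy if aff else None,
                    "high_affinity": high,
                    "mw": props.mw_average,
                    "logp": props.logp_estimate,
                    "logp_source": props.logp_source,
                    "hbd": props.hbd,
                    "hba": props.hba,
                    "lipinski_violations": verdict.violation_count,
                    "orally_absorbable": verdict.orally_absorbable,
                }
            )

    orphans = sorted(set(by_peptide) - window_peptides)
    if orphans:
        msg = f"affinity table names peptides absent from the digest window: {orphans}"
        if config.strict_join:
            raise ValueError(msg)
        logger.warning(msg)

    table = pd.DataFrame(rows)
    provenance = {
        "proteins": ";".join(p.id for p in proteins),
        "enzymes": ";".join(r.enzyme_name for r in rules),
        "length_window": f"{config.min_len}-{config.max_len}",
        "affinity_threshold": f"{config.affinity_threshold:g}",
        "affinity_source": affinities[0].source if affinities else "none",
        "input_hash": hashlib.sha256(
            "".join(p.sequence for p in proteins).encode()
        ).hexdigest()[:16],
    }
    return CandidateReport(table=table, provenance=provenance)
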