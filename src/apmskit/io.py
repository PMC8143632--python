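"""Readers, writers and validated domain types for all external tables.

Every downstream stage consumes the types defined here, and validation is
total: an accession that does not resolve in the loaded FASTA never escapes
this module.  Coordinates are 1-based inclusive everywhere, matching the
convention of domain databases and cross-link search exports; conversion to
0-based slices happens only at array boundaries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

#: Marker used in run-design tables for negative-control purifications
#: (cells expressing no tagged bait).
CONTROL = "CONTROL"

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: X is tolerated as an unknown-residue placeholder.
EXTENDED_ALPHABET = AMINO_ACIDS | {"X"}


class FormatError(ValueError):
    """A file violates the documented dialect (syntax-level problem)."""


class ValidationError(ValueError):
    """A file parses but its content contradicts the loaded database/design."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence entry; ``length`` is the L in the NSAF denominator."""

    accession: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def lysine_positions(self) -> list[int]:
        """1-based positions of lysine residues (cross-linkable sites)."""
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == "K"]


class ProteinDatabase:
    """An accession-keyed collection of :class:`ProteinRecord`.

    Accessions are unique; duplicate entries are rejected at construction.
    """

    def __init__(self, records: Iterable[ProteinRecord]):
        self._records: dict[str, ProteinRecord] = {}
        for rec in records:
            if rec.accession in self._records:
                raise FormatError(f"duplicate accession {rec.accession!r}")
            self._records[rec.accession] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __getitem__(self, accession: str) -> ProteinRecord:
        try:
            return self._records[accession]
        except KeyError:
            raise KeyError(f"accession {accession!r} not in protein database") from None

    @property
    def accessions(self) -> list[str]:
        return list(self._records)

    def lengths(self) -> dict[str, int]:
        return {a: r.length for a, r in self._records.items()}


@dataclass(frozen=True)
class PeptideEvidence:
    """One identified peptide in one run with its spectral count."""

    run_id: str
    peptide: str
    spectral_count: int
    protein_ids: frozenset[str]

    def __post_init__(self):
        if self.spectral_count < 0:
            raise ValidationError(
                f"negative spectral count for {self.peptide!r} in {self.run_id!r}"
            )
        if not self.protein_ids:
            raise ValidationError(f"peptide {self.peptide!r} maps to no protein")

    @property
    def is_unique(self) -> bool:
        """True when the peptide maps to exactly one protein."""
        return len(self.protein_ids) == 1


@dataclass(frozen=True)
class RunRecord:
    """One MS run: which bait it purified (or CONTROL) and its replicate index."""

    run_id: str
    bait_id: str
    replicate_index: int

    @property
    def is_control(self) -> bool:
        return self.bait_id == CONTROL


class StudyDesign:
    """The run layout of an AP-MS study: baits, replicates and controls."""

    def __init__(self, runs: Iterable[RunRecord]):
        self._runs: dict[str, RunRecord] = {}
        for run in runs:
            if run.run_id in self._runs:
                raise FormatError(f"duplicate run_id {run.run_id!r}")
            self._runs[run.run_id] = run

    def __len__(self) -> int:
        return len(self._runs)

    def __iter__(self):
        return iter(self._runs.values())

    def __contains__(self, run_id: str) -> bool:
        return run_id in self._runs

    @property
    def run_ids(self) -> list[str]:
        return list(self._runs)

    @property
    def baits(self) -> list[str]:
        seen = []
        for run in self._runs.values():
            if not run.is_control and run.bait_id not in seen:
                seen.append(run.bait_id)
        return seen

    def runs_for_bait(self, bait_id: str) -> list[str]:
        return [r.run_id for r in self._runs.values() if r.bait_id == bait_id]

    @property
    def control_runs(self) -> list[str]:
        return [r.run_id for r in self._runs.values() if r.is_control]

    def n_replicates(self, bait_id: str) -> int:
        return len(self.runs_for_bait(bait_id))

    def require_controls(self) -> None:
        if not self.control_runs:
            raise ValidationError(
                "design contains no CONTROL runs; enrichment scoring needs "
                "at least one negative-control purification"
            )


@dataclass(frozen=True)
class DomainAnnotation:
    """A named domain interval on a protein, 1-based inclusive.

    Domains of one protein may overlap: an experimentally defined interaction
    region (e.g. an HDAC-interaction domain) can encompass a Pfam domain.
    """

    protein_id: str
    domain_name: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"domain {self.domain_name!r} on {self.protein_id!r}: "
                f"invalid interval [{self.start}, {self.end}]"
            )

    def contains(self, residue: int) -> bool:
        return self.start <= residue <= self.end

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CrossLinkRecord:
    """A residue-pair cross-link observation from a cleavable-linker search."""

    protein_a: str
    residue_a: int
    peptide_a: str
    peptide_a_span: tuple[int, int]
    protein_b: str
    residue_b: int
    peptide_b: str
    peptide_b_span: tuple[int, int]
    score: float

    def swapped(self) -> "CrossLinkRecord":
        """The same observation with the two sides exchanged."""
        return CrossLinkRecord(
            self.protein_b, self.residue_b, self.peptide_b, self.peptide_b_span,
            self.protein_a, self.residue_a, self.peptide_a, self.peptide_a_span,
            self.score,
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> ProteinDatabase:
    """Load a protein FASTA into a :class:`ProteinDatabase`.

    Rejects duplicate accessions and non-amino-acid characters (the 20
    standard residues plus X are accepted), naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - EXTENDED_ALPHABET
        if bad:
            pos = next(i for i, aa in enumerate(seq) if aa in bad)
            raise FormatError(
                f"{path}: record {rec.id!r} has non-amino-acid character "
                f"{seq[pos]!r} at position {pos + 1}"
            )
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return ProteinDatabase(records)


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in proteins:
            fh.write(f">{rec.accession}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# run design
# ---------------------------------------------------------------------------

_DESIGN_COLUMNS = ["run_id", "bait_id", "replicate_index"]


def read_run_design(path: str | Path) -> StudyDesign:
    """Read a TSV of (run_id, bait_id, replicate_index); bait_id CONTROL marks
    negative-control runs."""
    df = _read_table(path, _DESIGN_COLUMNS, sep="\t")
    runs = [
        RunRecord(str(r.run_id), str(r.bait_id), int(r.replicate_index))
        for r in df.itertuples()
    ]
    return StudyDesign(runs)


def write_run_design(design: StudyDesign, path: str | Path) -> None:
    pd.DataFrame(
        [(r.run_id, r.bait_id, r.replicate_index) for r in design],
        columns=_DESIGN_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# peptide evidence
# ---------------------------------------------------------------------------

_EVIDENCE_COLUMNS = ["run_id", "peptide", "spectral_count", "protein_ids"]


def read_peptide_evidence(
    path: str | Path,
    proteins: ProteinDatabase,
    design: StudyDesign | None = None,
    delimiter: str = ";",
) -> list[PeptideEvidence]:
    """Read a peptide-evidence TSV and validate it against FASTA and design.

    ``protein_ids`` holds a delimiter-separated accession list; a row whose
    run or any of whose accessions is unknown raises :class:`ValidationError`
    listing every offender in the file.
    """
    df = _read_table(path, _EVIDENCE_COLUMNS, sep="\t")
    unknown_runs: set[str] = set()
    unknown_accessions: set[str] = set()
    evidence: list[PeptideEvidence] = []
    for row in df.itertuples():
        run_id = str(row.run_id)
        owners = frozenset(
            p.strip() for p in str(row.protein_ids).split(delimiter) if p.strip()
        )
        if design is not None and run_id not in design:
            unknown_runs.add(run_id)
        missing = {p for p in owners if p not in proteins}
        unknown_accessions |= missing
        if not (unknown_runs or unknown_accessions):
            evidence.append(
                PeptideEvidence(run_id, str(row.peptide), int(row.spectral_count), owners)
            )
    if unknown_runs or unknown_accessions:
        parts = []
        if unknown_runs:
            parts.append(f"unknown run_id(s): {sorted(unknown_runs)}")
        if unknown_accessions:
            parts.append(f"unknown accession(s): {sorted(unknown_accessions)}")
        raise ValidationError(f"{path}: " + "; ".join(parts))
    return evidence


def write_peptide_evidence(
    evidence: Iterable[PeptideEvidence], path: str | Path, delimiter: str = ";"
) -> None:
    rows = [
        (e.run_id, e.peptide, e.spectral_count, delimiter.join(sorted(e.protein_ids)))
        for e in evidence
    ]
    pd.DataFrame(rows, columns=_EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# domain annotations
# ---------------------------------------------------------------------------

_DOMAIN_COLUMNS = ["protein_id", "domain_name", "start", "end"]


def read_domain_annotations(
    path: str | Path, proteins: ProteinDatabase | None = None
) -> list[DomainAnnotation]:
    """Read a domain TSV (protein_id, domain_name, start, end; 1-based
    inclusive), checking intervals against protein lengths when a database
    is supplied."""
    df = _read_table(path, _DOMAIN_COLUMNS, sep="\t")
    annotations = []
    for row in df.itertuples():
        ann = DomainAnnotation(str(row.protein_id), str(row.domain_name),
                               int(row.start), int(row.end))
        if proteins is not None:
            if ann.protein_id not in proteins:
                raise ValidationError(
                    f"{path}: domain {ann.domain_name!r} references unknown "
                    f"accession {ann.protein_id!r}"
                )
            length = proteins[ann.protein_id].length
            if ann.end > length:
                raise ValidationError(
                    f"{path}: domain {ann.domain_name!r} on {ann.protein_id!r} "
                    f"ends at {ann.end} but the protein has {length} residues"
                )
        annotations.append(ann)
    return annotations


def write_domain_annotations(
    annotations: Iterable[DomainAnnotation], path: str | Path
) -> None:
    pd.DataFrame(
        [(a.protein_id, a.domain_name, a.start, a.end) for a in annotations],
        columns=_DOMAIN_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cross-links
# ---------------------------------------------------------------------------

_XL_COLUMNS = [
    "protein_a", "residue_a", "peptide_a", "peptide_a_start", "peptide_a_end",
    "protein_b", "residue_b", "peptide_b", "peptide_b_start", "peptide_b_end",
    "score",
]


def read_crosslinks(
    path: str | Path,
    proteins: ProteinDatabase | None = None,
) -> tuple[list[CrossLinkRecord], list[tuple[int, str]]]:
    """Read a cross-link CSV as exported by cleavable-XL search software.

    Returns ``(records, rejected)`` where ``rejected`` holds ``(row_number,
    reason)`` pairs for rows failing validation (linked residue outside its
    peptide span, span outside the protein); the remainder is loaded.
    """
    df = _read_table(path, _XL_COLUMNS, sep=",")
    records: list[CrossLinkRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        rec = CrossLinkRecord(
            str(row.protein_a), int(row.residue_a), str(row.peptide_a),
            (int(row.peptide_a_start), int(row.peptide_a_end)),
            str(row.protein_b), int(row.residue_b), str(row.peptide_b),
            (int(row.peptide_b_start), int(row.peptide_b_end)),
            float(row.score),
        )
        reason = _validate_crosslink(rec, proteins)
        if reason is None:
            records.append(rec)
        else:
            rejected.append((i, reason))
    return records, rejected


def _validate_crosslink(
    rec: CrossLinkRecord, proteins: ProteinDatabase | None
) -> str | None:
    for side, protein, residue, span in (
        ("a", rec.protein_a, rec.residue_a, rec.peptide_a_span),
        ("b", rec.protein_b, rec.residue_b, rec.peptide_b_span),
    ):
        lo, hi = span
        if not (1 <= lo <= hi):
            return f"peptide_{side} span [{lo}, {hi}] is not a valid interval"
        if not (lo <= residue <= hi):
            return f"residue_{side} {residue} outside peptide span [{lo}, {hi}]"
        if proteins is not None:
            if protein not in proteins:
                return f"unknown accession {protein!r}"
            if hi > proteins[protein].length:
                return (
                    f"peptide_{side} span ends at {hi} but {protein!r} has "
                    f"{proteins[protein].length} residues"
                )
    return None


def write_crosslinks(records: Iterable[CrossLinkRecord], path: str | Path) -> None:
    rows = [
        (r.protein_a, r.residue_a, r.peptide_a, *r.peptide_a_span,
         r.protein_b, r.residue_b, r.peptide_b, *r.peptide_b_span, r.score)
        for r in records
    ]
    pd.DataFrame(rows, columns=_XL_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# contaminants
# ---------------------------------------------------------------------------

def read_contaminants(path: str | Path, proteins: ProteinDatabase | None = None) -> set[str]:
    """One accession per line.  Contaminant-flagged proteins are retained
    through quantification (they contribute to the dNSAF denominator) and
    excluded only at the reporting layer."""
    accessions = {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }
    if proteins is not None:
        missing = {a for a in accessions if a not in proteins}
        if missing:
            raise ValidationError(
                f"{path}: contaminant accession(s) not in FASTA: {sorted(missing)}"
            )
    return accessions


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: Sequence[str], sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # malformed CSV/TSV
        raise FormatError(f"{path}: cannot parse ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df
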