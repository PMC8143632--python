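"""Cross-link to domain mapping, link classification and hotspot testing.

Cross-links from a lysine-reactive cleavable linker (DSSO) are mapped onto
1-based inclusive domain intervals.  Links between different proteins are
heteromeric; for a link within one protein the peptide evidence decides:
overlapping peptide spans (or identical linked residues) are impossible
within a single molecule, so such links demonstrate an intermolecular
self-link between two copies of the protein — homodimer evidence.
Disjoint spans on one protein are ambiguous (could be intra- or
inter-molecular).

Domain "hotspots" are assessed with a permutation test whose null redraws
each link end uniformly over the lysine positions of the same protein,
preserving per-protein link counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from apmskit.io import CrossLinkRecord, DomainAnnotation, ProteinDatabase


class LinkClass(str, enum.Enum):
    HETEROMERIC = "heteromeric"
    INTRA_PROTEIN = "intra_protein"  # requires external evidence; never auto-assigned
    SELF_LINK_INTERMOLECULAR = "self_link_intermolecular"
    AMBIGUOUS_SAME_PROTEIN = "ambiguous_same_protein"


def assign_domain(
    protein_id: str,
    residue: int,
    annotations: Iterable[DomainAnnotation],
    proteins: ProteinDatabase | None = None,
) -> list[str]:
    """All domain names whose interval contains the residue (boundaries
    inclusive); empty list when the residue falls outside every annotated
    domain.  Overlapping annotations all report."""
    if proteins is not None:
        length = proteins[protein_id].length
        if not (1 <= residue <= length):
            raise ValueError(
                f"residue {residue} outside {protein_id!r} (length {length})"
            )
    elif residue < 1:
        raise ValueError(f"residue {residue} is not a valid 1-based position")
    return [
        a.domain_name
        for a in annotations
        if a.protein_id == protein_id and a.contains(residue)
    ]


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def classify_link(record: CrossLinkRecord) -> LinkClass:
    """Classify a cross-link; symmetric under swapping the two sides."""
    if record.protein_a != record.protein_b:
        return LinkClass.HETEROMERIC
    if record.residue_a == record.residue_b or _spans_overlap(
        record.peptide_a_span, record.peptide_b_span
    ):
        return LinkClass.SELF_LINK_INTERMOLECULAR
    return LinkClass.AMBIGUOUS_SAME_PROTEIN


@dataclass(frozen=True)
class MappedCrossLink:
    record: CrossLinkRecord
    domains_a: tuple[str, ...]
    domains_b: tuple[str, ...]
    link_class: LinkClass


def map_crosslinks(
    records: Iterable[CrossLinkRecord],
    annotations: Sequence[DomainAnnotation],
    proteins: ProteinDatabase | None = None,
) -> list[MappedCrossLink]:
    """Attach domain assignments and a class to every cross-link record."""
    mapped = []
    for rec in records:
        mapped.append(
            MappedCrossLink(
                rec,
                tuple(assign_domain(rec.protein_a, rec.residue_a, annotations, proteins)),
                tuple(assign_domain(rec.protein_b, rec.residue_b, annotations, proteins)),
                classify_link(rec),
            )
        )
    return mapped


def _collapse(domains: tuple[str, ...], precedence: Sequence[str] | None,
              annotations_by_name: dict[str, int]) -> str:
    """Single display domain for a multi-domain hit.

    With an explicit precedence list the first listed name wins; otherwise
    the smallest (most specific) annotated interval wins, ties by name.
    """
    if not domains:
        return "NONE"
    if precedence:
        for name in precedence:
            if name in domains:
                return name
    return min(domains, key=lambda d: (annotations_by_name.get(d, 0), d))


def domain_link_density(
    mapped: Sequence[MappedCrossLink],
    annotations: Sequence[DomainAnnotation],
    proteins: ProteinDatabase,
    focus: str | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    precedence: Sequence[str] | None = None,
    per_partner: bool = True,
) -> pd.DataFrame:
    """Observed cross-link counts per (partner protein, focus domain) with a
    permutation p-value against a uniform-over-lysines null.

    Each link is counted exactly once, in the cell given by its partner
    protein and the (precedence-collapsed) domain its focus-side residue
    falls in; ``focus`` defaults to the protein of side A of the first link
    (the scaffold in a scaffold-centric export).  With ``per_partner=False``
    partners are pooled and cells are focus domains alone.  The null redraws
    the focus-side residue uniformly over the focus protein's lysines,
    preserving per-protein link counts; p-values use the add-one estimator
    (b + 1) / (n + 1).
    """
    if not mapped:
        raise ValueError("need at least one mapped cross-link")
    if focus is None:
        focus = mapped[0].record.protein_a

    lysines = np.array(proteins[focus].lysine_positions())
    if lysines.size == 0:
        raise ValueError(f"focus protein {focus!r} has no lysines; null undefined")

    ann_sizes = {a.domain_name: a.span for a in annotations}
    focus_annotations = [a for a in annotations if a.protein_id == focus]

    def focus_cell(residue: int, partner: str) -> tuple[str, str]:
        doms = tuple(
            a.domain_name for a in focus_annotations if a.contains(residue)
        )
        return (partner if per_partner else "*"), _collapse(doms, precedence, ann_sizes)

    # orient links so the focus side is known; links not touching focus are
    # counted under domain NONE with partner = protein of side A
    oriented: list[tuple[int, str]] = []  # (focus residue or -1, partner)
    cells = []
    for m in mapped:
        rec = m.record
        if rec.protein_a == focus:
            oriented.append((rec.residue_a, rec.protein_b))
            cells.append(focus_cell(rec.residue_a, rec.protein_b))
        elif rec.protein_b == focus:
            oriented.append((rec.residue_b, rec.protein_a))
            cells.append(focus_cell(rec.residue_b, rec.protein_a))
        else:
            oriented.append((-1, rec.protein_a))
            cells.append((rec.protein_a if per_partner else "*", "NONE"))

    observed = pd.Series(cells).value_counts()

    rng = np.random.default_rng(seed)
    resampled_idx = [i for i, (res, _) in enumerate(oriented) if res >= 0]
    exceed = {cell: 0 for cell in observed.index}
    for _ in range(n_permutations):
        perm_cells = list(cells)
        draws = rng.integers(0, lysines.size, size=len(resampled_idx))
        for j, i in enumerate(resampled_idx):
            perm_cells[i] = focus_cell(int(lysines[draws[j]]), oriented[i][1])
        perm_counts = pd.Series(perm_cells).value_counts()
        for cell in exceed:
            if perm_counts.get(cell, 0) >= observed[cell]:
                exceed[cell] += 1

    rows = [
        (
            partner,
            domain,
            int(observed[(partner, domain)]),
            (exceed[(partner, domain)] + 1) / (n_permutations + 1),
        )
        for partner, domain in observed.index
    ]
    df = pd.DataFrame(rows, columns=["partner_protein", "domain", "n_links", "p_value"])
    assert int(df["n_links"].sum()) == len(mapped), "link-count conservation"
    return df.sort_values(["p_value", "partner_protein", "domain"]).reset_index(drop=True)


def mapped_links_table(mapped: Sequence[MappedCrossLink]) -> pd.DataFrame:
    """Flat TSV-ready table of mapped cross-links."""
    rows = []
    for m in mapped:
        r = m.record
        rows.append(
            (r.protein_a, r.residue_a, "|".join(m.domains_a) or "NONE",
             r.protein_b, r.residue_b, "|".join(m.domains_b) or "NONE",
             m.link_class.value, r.score)
        )
    return pd.DataFrame(
        rows,
        columns=["protein_a", "residue_a", "domains_a",
                 "protein_b", "residue_b", "domains_b", "link_class", "score"],
    )
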