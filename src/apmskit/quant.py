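"""Distributed spectral counts, dNSAF and bait-normalized dNSAF.

Shared-peptide spectral counts are distributed among the peptide's owner
proteins in proportion to each owner's unique spectral count in the same run
(no cross-run borrowing).  The distributed count dSpC = uSpC + assigned share
is then length-normalized and scaled to the run total:

    dNSAF_k = (dSpC_k / L_k) / sum_i (dSpC_i / L_i)

so dNSAF is a unitless relative abundance summing to 1 over the proteins
detected in a run.  Bait-normalized dNSAF (bdNSAF) divides a prey's dNSAF by
the bait's dNSAF in the same purification, putting preys from different
purifications on a common, bait-relative scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from apmskit.io import PeptideEvidence, ProteinDatabase, StudyDesign


class EmptyRunError(ValueError):
    """Raised when a run contains no spectral counts at all."""


@dataclass
class QuantifiedRun:
    """Per-run protein quantification table.

    ``table`` is indexed by accession with columns ``uSpC`` (unique spectral
    count), ``sSpC_assigned`` (distributed share of shared counts), ``dSpC``
    and ``dNSAF``.
    """

    run_id: str
    table: pd.DataFrame

    def dnsaf(self, accession: str) -> float:
        if accession in self.table.index:
            return float(self.table.at[accession, "dNSAF"])
        return 0.0

    def dspc(self, accession: str) -> float:
        if accession in self.table.index:
            return float(self.table.at[accession, "dSpC"])
        return 0.0


def distribute_shared_counts(
    evidence: Iterable[PeptideEvidence],
) -> pd.DataFrame:
    """Distribute shared-peptide counts among owner proteins for one run.

    For a shared peptide with count *s* and owner set *O*, owner *k* receives
    ``s * uSpC_k / sum_{j in O} uSpC_j``.  When every owner has zero unique
    counts the share is split equally, which keeps the run total conserved.

    Returns a DataFrame indexed by accession with columns ``uSpC``,
    ``sSpC_assigned`` and ``dSpC``; total dSpC equals the summed raw
    spectral counts exactly (to floating-point resolution).
    """
    evidence = list(evidence)
    runs = {e.run_id for e in evidence}
    if len(runs) > 1:
        raise ValueError(f"evidence mixes runs {sorted(runs)}; distribute one run at a time")

    unique: dict[str, float] = {}
    shared: list[PeptideEvidence] = []
    for e in evidence:
        if e.is_unique:
            (owner,) = e.protein_ids
            unique[owner] = unique.get(owner, 0.0) + e.spectral_count
        else:
            shared.append(e)
            for owner in e.protein_ids:
                unique.setdefault(owner, 0.0)

    assigned = {acc: 0.0 for acc in unique}
    for e in shared:
        owners = sorted(e.protein_ids)
        total_u = sum(unique[o] for o in owners)
        if total_u > 0:
            for o in owners:
                assigned[o] += e.spectral_count * unique[o] / total_u
        else:
            for o in owners:
                assigned[o] += e.spectral_count / len(owners)

    accs = sorted(unique)
    df = pd.DataFrame(
        {
            "uSpC": [unique[a] for a in accs],
            "sSpC_assigned": [assigned[a] for a in accs],
        },
        index=pd.Index(accs, name="accession"),
    )
    df["dSpC"] = df["uSpC"] + df["sSpC_assigned"]
    return df


def compute_dnsaf(
    dspc: Mapping[str, float] | pd.Series,
    lengths: Mapping[str, int],
) -> pd.Series:
    """Length-normalize distributed counts into dNSAF values.

    Proteins with dSpC == 0 receive dNSAF 0 and do not enter the
    denominator; the returned values sum to 1 over detected proteins.
    """
    s = pd.Series(dict(dspc), dtype=float) if not isinstance(dspc, pd.Series) else dspc.astype(float)
    if (s < 0).any():
        raise ValueError("negative dSpC")
    missing = [a for a in s.index if a not in lengths]
    if missing:
        raise KeyError(f"no length for accession(s) {missing}")
    L = pd.Series({a: lengths[a] for a in s.index}, dtype=float)
    if (L <= 0).any():
        raise ValueError("non-positive protein length")
    saf = s / L
    total = saf.sum()
    if total == 0:
        raise EmptyRunError("empty run: all dSpC are zero")
    out = saf / total
    out.name = "dNSAF"
    return out


def quantify_run(
    evidence: Iterable[PeptideEvidence],
    proteins: ProteinDatabase,
) -> QuantifiedRun:
    """Distribute shared counts and compute dNSAF for a single run."""
    evidence = list(evidence)
    if not evidence:
        raise EmptyRunError("empty run: no peptide evidence")
    run_id = evidence[0].run_id
    table = distribute_shared_counts(evidence)
    table["dNSAF"] = compute_dnsaf(table["dSpC"], proteins.lengths())
    return QuantifiedRun(run_id, table)


def quantify_study(
    evidence: Iterable[PeptideEvidence],
    proteins: ProteinDatabase,
    design: StudyDesign | None = None,
) -> dict[str, QuantifiedRun]:
    """Quantify every run present in the evidence; returns run_id -> result.

    Runs listed in the design but absent from the evidence are quantified as
    missing (omitted) rather than erroring, so sparse designs round-trip.
    """
    by_run: dict[str, list[PeptideEvidence]] = {}
    for e in evidence:
        by_run.setdefault(e.run_id, []).append(e)
    return {run_id: quantify_run(rows, proteins) for run_id, rows in sorted(by_run.items())}


def quantification_table(quantified: Mapping[str, QuantifiedRun]) -> pd.DataFrame:
    """Long-format table (run_id, accession, uSpC, sSpC_assigned, dSpC, dNSAF)."""
    frames = []
    for run_id, q in quantified.items():
        t = q.table.reset_index()
        t.insert(0, "run_id", run_id)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def count_matrix(
    quantified: Mapping[str, QuantifiedRun],
    value: str = "dSpC",
    round_counts: bool = False,
) -> pd.DataFrame:
    """Protein x run matrix of a quantification column, 0 where undetected."""
    mat = pd.DataFrame(
        {run_id: q.table[value] for run_id, q in quantified.items()}
    ).fillna(0.0)
    mat.index.name = "accession"
    if round_counts:
        mat = mat.round().astype(int)
    return mat


def compute_bdnsaf(run: QuantifiedRun, bait_id: str, prey_id: str) -> float:
    """Prey dNSAF divided by bait dNSAF in one purification run.

    Returns 0 for an undetected prey; raises when the bait itself was not
    detected in the run (the ratio is undefined there).
    """
    bait = run.dnsaf(bait_id)
    if bait <= 0:
        raise ValueError(
            f"bait {bait_id!r} has zero dNSAF in run {run.run_id!r}; "
            "bdNSAF undefined"
        )
    return run.dnsaf(prey_id) / bait


def bdnsaf_table(
    quantified: Mapping[str, QuantifiedRun],
    design: StudyDesign,
    preys: Sequence[str] | None = None,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Replicate-level and aggregated bdNSAF per (bait, prey).

    Runs where the bait was undetected are excluded from aggregation with a
    warning.  ``aggregate`` is ``"mean"`` (default) or ``"median"``.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    rows = []
    for bait in design.baits:
        run_ids = [r for r in design.runs_for_bait(bait) if r in quantified]
        usable = []
        for run_id in run_ids:
            if quantified[run_id].dnsaf(bait) > 0:
                usable.append(run_id)
            else:
                warnings.warn(
                    f"bait {bait!r} undetected in run {run_id!r}; "
                    "run excluded from bdNSAF aggregation"
                )
        if not usable:
            continue
        prey_ids = preys
        if prey_ids is None:
            prey_ids = sorted(
                {acc for r in usable for acc in quantified[r].table.index} - {bait}
            )
        for prey in prey_ids:
            values = [compute_bdnsaf(quantified[r], bait, prey) for r in usable]
            agg = float(np.mean(values) if aggregate == "mean" else np.median(values))
            for run_id, v in zip(usable, values):
                rows.append((bait, prey, run_id, v, agg))
    return pd.DataFrame(
        rows, columns=["bait_id", "prey_id", "run_id", "bdNSAF", f"bdNSAF_{aggregate}"]
    )
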