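"""Synthetic AP-MS study generator with ground-truth manifests.

Generates everything the pipeline consumes: a proteome of tryptic-peptide
sequences (with paralog pairs sharing an exact fraction of peptides), a
bait/control run design with planted true interactors, peptide-level
spectral-count evidence, and cross-link tables with planted domain hotspots
and intermolecular self-links.  Every emitted record is covered by a truth
manifest so recovery can be measured at any stage.

The count model is Poisson to match the enrichment model class: a protein
present in a run at relative abundance *a* yields, per tryptic peptide,
``count ~ Poisson(depth * mean_count * a * w_p)`` where the per-peptide
propensities ``w_p`` sum to 1 within the protein (peptides ionize
unequally).  Every proteome protein is a low-level nonspecific background
binder in every run (abundance 1), planted preys are multiplied by their
fold change in their bait's runs, and the bait protein itself is highly
abundant in its own purifications.  An optional gamma overdispersion knob
exists for robustness experiments and is off by default.

Digestion is fully tryptic: peptides end in K or R, contain no internal
K/R, and proline is excluded from the synthetic alphabet so the
cleave-after-K/R rule regenerates the peptide set exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from apmskit.io import (
    CONTROL,
    CrossLinkRecord,
    DomainAnnotation,
    PeptideEvidence,
    ProteinDatabase,
    ProteinRecord,
    RunRecord,
    StudyDesign,
)

#: residues used inside synthetic tryptic peptides: no K/R (cleavage sites)
#: and no P (suppresses cleavage), so digestion is unambiguous.
_INTERIOR = "ACDEFGHILMNQSTVWY"
_CLEAVAGE = "KR"


@dataclass(frozen=True)
class PlantedInteraction:
    bait_id: str
    prey_id: str
    fold_change: float = 8.0

    def __post_init__(self):
        if self.fold_change < 1:
            raise ValueError("planted fold_change must be >= 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study; defaults follow the emulated design
    of a small AP-MS screen (three biological replicates per bait, negative
    controls from untagged cells, Poisson spectral counts)."""

    seed: int = 0
    baits: tuple[str, ...] = ("bait1", "bait2")
    n_replicates: int = 3
    n_controls: int = 3
    n_background: int = 30
    peptides_per_protein: tuple[int, int] = (8, 18)
    peptide_length: tuple[int, int] = (6, 14)
    paralog_pairs: tuple[tuple[str, str, float], ...] = ()
    planted_interactions: tuple[PlantedInteraction, ...] = ()
    mean_background_count: float = 2.0
    bait_abundance: float = 30.0
    dropout: float = 0.05
    depth: float = 1.0
    overdispersion: float = 0.0
    # cross-link generation
    n_crosslinks: int = 50
    hotspot_protein: str | None = None
    hotspot_domain: str = "core_interaction"
    hotspot_fraction: float = 0.7
    selflink_fraction: float = 0.1

    def __post_init__(self):
        for p in (self.dropout, self.hotspot_fraction, self.selflink_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        for _, _, frac in self.paralog_pairs:
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"shared-peptide fraction {frac} outside [0, 1]")
        if self.n_replicates < 1 or self.n_controls < 1:
            raise ValueError("need at least one replicate and one control run")


@dataclass
class SyntheticProteome:
    proteins: ProteinDatabase
    domains: list[DomainAnnotation]
    #: accession -> list of (start, end, sequence) tryptic peptides, 1-based
    peptides: dict[str, list[tuple[int, int, str]]]
    #: peptide sequence -> owning accessions
    peptide_owners: dict[str, frozenset[str]]
    paralog_map: dict[str, str]


def tryptic_digest(sequence: str) -> list[tuple[int, int, str]]:
    """Fully tryptic digestion (cleave after K/R, not before P, no missed
    cleavages); returns 1-based inclusive (start, end, peptide) triples."""
    peptides = []
    start = 0
    for i, aa in enumerate(sequence):
        at_site = aa in _CLEAVAGE and not (
            i + 1 < len(sequence) and sequence[i + 1] == "P"
        )
        if at_site or i == len(sequence) - 1:
            peptides.append((start + 1, i + 1, sequence[start:i + 1]))
            start = i + 1
    return peptides


def _proteome_accessions(config: GeneratorConfig) -> list[str]:
    accessions = list(config.baits)
    for itx in config.planted_interactions:
        if itx.bait_id not in accessions:
            raise ValueError(f"planted interaction references unknown bait {itx.bait_id!r}")
        if itx.prey_id not in accessions:
            accessions.append(itx.prey_id)
    for a, b, _ in config.paralog_pairs:
        for acc in (a, b):
            if acc not in accessions:
                accessions.append(acc)
    accessions += [f"bg{i:03d}" for i in range(1, config.n_background + 1)]
    return accessions


def generate_proteome(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> SyntheticProteome:
    """Random tryptic proteome with paralog pairs sharing exact peptides and
    domain annotations on the bait proteins.  Same config and seed produce
    byte-identical output."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    accessions = _proteome_accessions(config)
    second_of_pair = {b: (a, frac) for a, b, frac in config.paralog_pairs}

    seen_peptides: set[str] = set()

    def new_peptide() -> str:
        for _ in range(1000):
            length = int(rng.integers(config.peptide_length[0], config.peptide_length[1] + 1))
            interior = "".join(
                _INTERIOR[i] for i in rng.integers(0, len(_INTERIOR), size=length - 1)
            )
            pep = interior + _CLEAVAGE[int(rng.integers(0, 2))]
            if pep not in seen_peptides:
                seen_peptides.add(pep)
                return pep
        raise RuntimeError("could not generate a unique peptide")

    protein_peps: dict[str, list[str]] = {}
    for acc in accessions:
        if acc in second_of_pair:
            continue  # generated after its partner
        n_pep = int(rng.integers(config.peptides_per_protein[0],
                                 config.peptides_per_protein[1] + 1))
        protein_peps[acc] = [new_peptide() for _ in range(n_pep)]

    # paralogs are colinear: the partner keeps shared peptides at their
    # positions and replaces the rest, so paralog pairs align end-to-end
    paralog_map: dict[str, str] = {}
    for a, b, frac in config.paralog_pairs:
        source = protein_peps[a]
        n_shared = int(round(frac * len(source)))
        shared_idx = set(rng.choice(len(source), size=n_shared, replace=False).tolist())
        protein_peps[b] = [
            pep if i in shared_idx else new_peptide()
            for i, pep in enumerate(source)
        ]
        paralog_map[a] = b
        paralog_map[b] = a

    # the central hotspot domain of every bait must be cross-linkable:
    # if no peptide ending inside it terminates in K, flip one R -> K
    for bait in config.baits:
        peps = protein_peps[bait]
        length = sum(len(p) for p in peps)
        lo, hi = max(1, int(length * 0.40)), max(1, int(length * 0.65))
        inside = []
        pos = 0
        for i, pep in enumerate(peps):
            pos += len(pep)
            if lo <= pos <= hi:
                inside.append(i)
        if inside and not any(peps[i].endswith("K") for i in inside):
            i = inside[0]
            flipped = peps[i][:-1] + "K"
            seen_peptides.add(flipped)
            for acc, plist in protein_peps.items():
                protein_peps[acc] = [flipped if p == peps[i] else p for p in plist]

    records = []
    peptides: dict[str, list[tuple[int, int, str]]] = {}
    peptide_owners: dict[str, set[str]] = {}
    for acc in accessions:
        seq = "".join(protein_peps[acc])
        records.append(ProteinRecord(acc, seq))
        peptides[acc] = tryptic_digest(seq)
        for _, _, pep in peptides[acc]:
            peptide_owners.setdefault(pep, set()).add(acc)

    proteins = ProteinDatabase(records)
    domains = []
    for bait in config.baits:
        length = proteins[bait].length
        # N-terminal interaction module, central hotspot, C-terminal domain
        domains.append(DomainAnnotation(bait, "nterm_module", 1, max(1, length // 5)))
        lo, hi = int(length * 0.40), int(length * 0.65)
        domains.append(DomainAnnotation(bait, config.hotspot_domain, max(1, lo), max(1, hi)))
        domains.append(DomainAnnotation(bait, "cterm_domain", int(length * 0.8), length))

    return SyntheticProteome(proteins, domains, peptides,
                             {p: frozenset(o) for p, o in peptide_owners.items()},
                             paralog_map)


def generate_apms_counts(
    config: GeneratorConfig,
    proteome: SyntheticProteome,
    rng: np.random.Generator | None = None,
) -> tuple[list[PeptideEvidence], StudyDesign, dict]:
    """Spectral-count evidence for every run plus the design and a truth
    manifest (per-run true abundances, per-pair true enrichment status)."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng

    runs = []
    for bait in config.baits:
        for k in range(1, config.n_replicates + 1):
            runs.append(RunRecord(f"{bait}_r{k}", bait, k))
    for k in range(1, config.n_controls + 1):
        runs.append(RunRecord(f"control_r{k}", CONTROL, k))
    design = StudyDesign(runs)

    planted = {(p.bait_id, p.prey_id): p.fold_change for p in config.planted_interactions}

    # fixed per-peptide ionization propensities, one draw per proteome
    propensity: dict[str, np.ndarray] = {}
    for acc, peps in proteome.peptides.items():
        w = rng.gamma(2.0, 1.0, size=len(peps))
        propensity[acc] = w / w.sum()

    truth_abundance: dict[str, dict[str, float]] = {}
    evidence: list[PeptideEvidence] = []
    for run in design:
        abundance: dict[str, float] = {}
        for acc in proteome.proteins.accessions:
            a = 1.0
            if not run.is_control:
                if acc == run.bait_id:
                    a = config.bait_abundance
                elif (run.bait_id, acc) in planted:
                    a = planted[(run.bait_id, acc)]
            if acc != run.bait_id and rng.uniform() < config.dropout:
                a = 0.0
            if config.overdispersion > 0 and a > 0:
                shape = 1.0 / config.overdispersion
                a *= rng.gamma(shape, 1.0 / shape)
            abundance[acc] = a
        truth_abundance[run.run_id] = abundance

        # aggregate expected counts per peptide over owner proteins
        expected: dict[str, float] = {}
        for acc in proteome.proteins.accessions:
            a = abundance[acc]
            if a <= 0:
                continue
            scale = config.depth * config.mean_background_count * a
            for (_, _, pep), w in zip(proteome.peptides[acc], propensity[acc]):
                expected[pep] = expected.get(pep, 0.0) + scale * w
        for pep in sorted(expected):
            count = int(rng.poisson(expected[pep]))
            if count > 0:
                evidence.append(
                    PeptideEvidence(run.run_id, pep, count, proteome.peptide_owners[pep])
                )

    truth = {
        "abundance": truth_abundance,
        "interactions": {f"{b}:{p}": f for (b, p), f in planted.items()},
        "enriched": sorted(f"{b}:{p}" for (b, p), f in planted.items() if f > 1),
    }
    return evidence, design, truth


def generate_crosslinks(
    config: GeneratorConfig,
    proteome: SyntheticProteome,
    rng: np.random.Generator | None = None,
) -> tuple[list[CrossLinkRecord], list[dict]]:
    """Cross-link records with planted domain hotspots and self-links.

    A ``selflink_fraction`` of links join two lysines within one peptide of
    the scaffold (overlapping spans: intermolecular self-link evidence); of
    the remainder, ``hotspot_fraction`` place the scaffold-side residue on a
    lysine inside the hotspot domain and the rest draw uniformly over the
    scaffold's lysines.  Partner residues are uniform over partner lysines.
    Returns the records and a per-record truth list.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    scaffold = config.hotspot_protein or config.baits[0]
    hotspot = next(
        (d for d in proteome.domains
         if d.protein_id == scaffold and d.domain_name == config.hotspot_domain),
        None,
    )
    if hotspot is None:
        raise ValueError(
            f"hotspot domain {config.hotspot_domain!r} not annotated on {scaffold!r}"
        )

    partners = sorted(
        {p.prey_id for p in config.planted_interactions if p.bait_id == scaffold}
    ) or [a for a in proteome.proteins.accessions if a != scaffold]

    def lysines(acc: str) -> list[int]:
        return proteome.proteins[acc].lysine_positions()

    def peptide_span(acc: str, residue: int) -> tuple[int, int, str]:
        for start, end, pep in proteome.peptides[acc]:
            if start <= residue <= end:
                return start, end, pep
        raise AssertionError("residue outside digested protein")

    scaffold_lys = lysines(scaffold)
    hotspot_lys = [k for k in scaffold_lys if hotspot.contains(k)]
    if not hotspot_lys:
        raise ValueError(f"hotspot domain on {scaffold!r} contains no lysines")

    records: list[CrossLinkRecord] = []
    truth: list[dict] = []
    for _ in range(config.n_crosslinks):
        score = float(rng.uniform(50.0, 300.0))
        if rng.uniform() < config.selflink_fraction:
            # two lysines within one peptide of the scaffold: overlapping spans
            k1 = scaffold_lys[int(rng.integers(0, len(scaffold_lys)))]
            s, e, pep = peptide_span(scaffold, k1)
            in_pep = [k for k in scaffold_lys if s <= k <= e]
            k2 = in_pep[int(rng.integers(0, len(in_pep)))]
            records.append(
                CrossLinkRecord(scaffold, k1, pep, (s, e), scaffold, k2, pep, (s, e), score)
            )
            truth.append({"class": "self_link_intermolecular", "from_hotspot": False})
            continue

        from_hotspot = rng.uniform() < config.hotspot_fraction
        pool = hotspot_lys if from_hotspot else scaffold_lys
        ka = pool[int(rng.integers(0, len(pool)))]
        sa, ea, pa = peptide_span(scaffold, ka)

        partner = None
        for _attempt in range(100):
            cand = partners[int(rng.integers(0, len(partners)))]
            if lysines(cand):
                partner = cand
                break
            warnings.warn(f"partner {cand!r} has no lysines; resampling")
        if partner is None:
            raise RuntimeError("no cross-linkable partner with lysines")
        partner_lys = lysines(partner)
        kb = partner_lys[int(rng.integers(0, len(partner_lys)))]
        sb, eb, pb = peptide_span(partner, kb)
        records.append(
            CrossLinkRecord(scaffold, ka, pa, (sa, ea), partner, kb, pb, (sb, eb), score)
        )
        truth.append({"class": "heteromeric", "from_hotspot": bool(from_hotspot)})
    return records, truth


def two_paralog_reference_config(seed: int = 0, fold_change: float = 30.0) -> GeneratorConfig:
    """The two-paralog study design: two scaffold baits that are paralogs
    sharing half their tryptic peptides, 18 planted true interactors each
    with 7 in common (the shared-core preys), three replicates per bait and
    three negative-control runs.

    The planted fold change defaults to 30: stable complex subunits in
    AP-MS are enriched tens-fold over no-transgene controls.
    """
    shared = [f"core{i:02d}" for i in range(1, 8)]
    only_a = [f"preyA{i:02d}" for i in range(1, 12)]
    only_b = [f"preyB{i:02d}" for i in range(1, 12)]
    planted = tuple(
        [PlantedInteraction("scaffoldA", p, fold_change) for p in shared + only_a]
        + [PlantedInteraction("scaffoldB", p, fold_change) for p in shared + only_b]
    )
    return GeneratorConfig(
        seed=seed,
        baits=("scaffoldA", "scaffoldB"),
        paralog_pairs=(("scaffoldA", "scaffoldB", 0.5),),
        planted_interactions=planted,
        n_background=25,
        hotspot_protein="scaffoldA",
    )
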