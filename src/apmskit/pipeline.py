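"""End-to-end orchestration: quantify -> filter -> enrich -> network ->
cluster -> cross-link mapping, plus the ancillary enzyme-activity
normalization.

``run_pipeline`` consumes a :class:`PipelineConfig` (constructible from a
YAML file), validates every input before any computation, executes the
stages, and writes TSV/Newick/GraphML/JSON outputs together with a manifest
recording input hashes, parameters and seeds.  Re-running an identical
config reproduces every output: the only stochastic stage (enrichment MCMC)
is fully determined by its seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats

import apmskit
from apmskit.enrichment import (
    McmcSettings,
    enrich_count_matrix,
    enriched_sets,
    prevalence_filter,
)
from apmskit.io import (
    read_crosslinks,
    read_domain_annotations,
    read_fasta,
    read_peptide_evidence,
    read_run_design,
)
from apmskit.network import (
    build_network,
    interactome_overlap,
    jaccard_matrix,
    standardize_heatmap,
    upgma_cluster,
)
from apmskit.quant import bdnsaf_table, count_matrix, quantification_table, quantify_study
from apmskit.xlmap import domain_link_density, map_crosslinks, mapped_links_table


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    fasta: str
    design: str
    evidence: str
    out_dir: str
    domains: str | None = None
    crosslinks: str | None = None
    contaminants: str | None = None
    z_min: float = 3.0
    fc_min: float = 2.0
    burn_in: int = 2000
    iterations: int = 10000
    seed: int = 0
    protein_id_delimiter: str = ";"
    bdnsaf_aggregate: str = "mean"
    n_permutations: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        paths = {"fasta": self.fasta, "design": self.design, "evidence": self.evidence}
        for name in ("domains", "crosslinks", "contaminants"):
            value = getattr(self, name)
            if value:
                paths[name] = value
        return paths


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    All referenced inputs are checked for existence before any stage runs;
    a stage failure raises :class:`PipelineError` naming the stage.
    """
    missing = [p for p in config.input_paths().values() if not Path(p).exists()]
    if missing:
        raise PipelineError(f"stage=validate: missing input file(s) {missing}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def write_tsv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        outputs[name] = str(path)

    # --- load & validate ------------------------------------------------
    try:
        proteins = read_fasta(config.fasta)
        design = read_run_design(config.design)
        design.require_controls()
        evidence = read_peptide_evidence(
            config.evidence, proteins, design, config.protein_id_delimiter
        )
    except Exception as exc:
        raise PipelineError(f"stage=load: {exc}") from exc

    # --- quantification -------------------------------------------------
    try:
        quantified = quantify_study(evidence, proteins, design)
        write_tsv(quantification_table(quantified), "quantification.tsv")
        counts = count_matrix(quantified, "dSpC", round_counts=True)
        bdnsaf = bdnsaf_table(quantified, design, aggregate=config.bdnsaf_aggregate)
        write_tsv(bdnsaf, "bdnsaf.tsv")
    except Exception as exc:
        raise PipelineError(f"stage=quantify: {exc}") from exc

    # --- enrichment ------------------------------------------------------
    try:
        settings = McmcSettings(config.burn_in, config.iterations, config.seed)
        retained = prevalence_filter(counts, design)
        results = enrich_count_matrix(
            counts, design, settings, config.z_min, config.fc_min
        )
        filter_log = pd.DataFrame(
            {"prey_id": list(counts.index),
             "retained": [p in set(retained) for p in counts.index]}
        )
        write_tsv(filter_log, "prevalence_filter.tsv")
        write_tsv(results, "enrichment.tsv")
    except Exception as exc:
        raise PipelineError(f"stage=enrich: {exc}") from exc

    # --- network & modules ----------------------------------------------
    try:
        sets = enriched_sets(results)
        overlap_rows = []
        baits = design.baits
        for i, a in enumerate(baits):
            for b in baits[i + 1:]:
                ov = interactome_overlap(sets.get(a, set()), sets.get(b, set()))
                overlap_rows.append(
                    (a, b, len(ov.shared), len(ov.only_a), len(ov.only_b))
                )
        write_tsv(
            pd.DataFrame(overlap_rows,
                         columns=["bait_a", "bait_b", "shared", "only_a", "only_b"]),
            "overlap.tsv",
        )
        newick = None
        if len(baits) >= 2:
            jac = jaccard_matrix({b: sets.get(b, set()) for b in baits})
            write_tsv(jac, "jaccard.tsv", index=True)
            tree = upgma_cluster(jac)
            newick = tree.to_newick()
            (out / "dendrogram.nwk").write_text(newick + "\n")
            outputs["dendrogram.nwk"] = str(out / "dendrogram.nwk")
        enriched_any = sorted(set().union(*sets.values())) if sets else []
        if enriched_any:
            dnsaf_matrix = count_matrix(quantified, "dNSAF").reindex(enriched_any).fillna(0.0)
            write_tsv(standardize_heatmap(dnsaf_matrix), "heatmap_standardized.tsv",
                      index=True)
        graph = build_network(results, bdnsaf)
        nx.write_graphml(graph, out / "network.graphml")
        outputs["network.graphml"] = str(out / "network.graphml")
    except Exception as exc:
        raise PipelineError(f"stage=network: {exc}") from exc

    # --- cross-link mapping ----------------------------------------------
    n_rejected_xl = 0
    if config.crosslinks:
        try:
            domains = (
                read_domain_annotations(config.domains, proteins) if config.domains else []
            )
            xls, rejected = read_crosslinks(config.crosslinks, proteins)
            n_rejected_xl = len(rejected)
            mapped = map_crosslinks(xls, domains, proteins)
            write_tsv(mapped_links_table(mapped), "crosslinks_mapped.tsv")
            if mapped:
                density = domain_link_density(
                    mapped, domains, proteins,
                    n_permutations=config.n_permutations, seed=config.seed,
                )
                write_tsv(density, "domain_link_density.tsv")
        except Exception as exc:
            raise PipelineError(f"stage=xlmap: {exc}") from exc

    # --- manifest ---------------------------------------------------------
    manifest = {
        "package": "apmskit",
        "version": apmskit.__version__,
        "parameters": asdict(config),
        "input_sha256": {k: _sha256(v) for k, v in config.input_paths().items()},
        "outputs": sorted(outputs),
        "n_runs": len(design),
        "n_baits": len(design.baits),
        "n_rejected_crosslinks": n_rejected_xl,
        "enriched_counts": {b: len(s) for b, s in sorted(enriched_sets(results).items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    summary = [
        "# Pipeline summary",
        f"runs: {len(design)}; baits: {', '.join(design.baits)}",
        "enriched preys per bait: "
        + ", ".join(f"{b}={n}" for b, n in manifest["enriched_counts"].items()),
        f"seed: {config.seed}; burn-in: {config.burn_in}; iterations: {config.iterations}",
    ]
    if newick:
        summary.append(f"bait dendrogram: {newick}")
    (out / "summary.md").write_text("\n".join(summary) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# enzyme-activity normalization (ancillary)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityRecord:
    """One enzyme-activity measurement: raw fluorescence (RFU), the bait
    abundance it is normalized to (relative western-blot units) and the
    treatment condition label."""

    sample_id: str
    rfu: float
    bait_abundance: float
    condition: str


def normalize_activity(
    records: Sequence[ActivityRecord],
    contrast: tuple[str, str] | None = None,
) -> dict:
    """Normalize activity to bait abundance and summarize per condition.

    ``normalized = RFU / bait_abundance``; records with non-positive
    abundance are excluded with a warning.  When ``contrast`` names two
    condition labels, a two-sample t-test (Welch) between them is reported.
    """
    rows = []
    for rec in records:
        if rec.bait_abundance <= 0:
            warnings.warn(
                f"sample {rec.sample_id!r}: non-positive bait abundance; excluded"
            )
            continue
        rows.append((rec.sample_id, rec.condition, rec.rfu,
                     rec.rfu / rec.bait_abundance))
    table = pd.DataFrame(
        rows, columns=["sample_id", "condition", "rfu", "normalized_activity"]
    )
    per_condition = (
        table.groupby("condition")["normalized_activity"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    out = {"table": table, "per_condition": per_condition}
    if contrast is not None:
        a, b = contrast
        xa = table.loc[table["condition"] == a, "normalized_activity"]
        xb = table.loc[table["condition"] == b, "normalized_activity"]
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError("contrast needs >= 2 samples per condition")
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        out["contrast"] = {
            "conditions": (a, b),
            "mean_difference": float(xa.mean() - xb.mean()),
            "t_statistic": float(t),
            "p_value": float(p),
        }
    return out
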