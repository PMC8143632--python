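"""The complete analysis on the two-paralog reference design.

Simulates the full input bundle (FASTA, design, evidence, domains,
cross-links) to disk, runs the pipeline from a config, and prints the
recovered interactome structure: enriched preys per scaffold and their
overlap -- the paralog-switching signature the analysis chain exists to
measure.
"""

import json
import tempfile
from pathlib import Path

from apmskit.io import (
    write_crosslinks, write_domain_annotations, write_fasta,
    write_peptide_evidence, write_run_design,
)
from apmskit.pipeline import PipelineConfig, run_pipeline
from apmskit.synth import (
    generate_apms_counts, generate_crosslinks, generate_proteome,
    two_paralog_reference_config,
)

workdir = Path(tempfile.mkdtemp(prefix="apmskit_demo_"))
cfg = two_paralog_reference_config(seed=1)
proteome = generate_proteome(cfg)
evidence, design, truth = generate_apms_counts(cfg, proteome)
xls, _ = generate_crosslinks(cfg, proteome)

write_fasta(proteome.proteins, workdir / "proteome.fasta")
write_run_design(design, workdir / "design.tsv")
write_peptide_evidence(evidence, workdir / "evidence.tsv")
write_domain_annotations(proteome.domains, workdir / "domains.tsv")
write_crosslinks(xls, workdir / "crosslinks.csv")

manifest = run_pipeline(PipelineConfig(
    fasta=str(workdir / "proteome.fasta"),
    design=str(workdir / "design.tsv"),
    evidence=str(workdir / "evidence.tsv"),
    domains=str(workdir / "domains.tsv"),
    crosslinks=str(workdir / "crosslinks.csv"),
    out_dir=str(workdir / "out"),
    seed=1,
))

print("enriched preys per bait:", manifest["enriched_counts"])
overlap = json.loads((workdir / "out" / "manifest.json").read_text())
print("outputs:", ", ".join(manifest["outputs"]))
print((workdir / "out" / "summary.md").read_text())
print("The design plants 18 true interactors per scaffold with 7 shared;")
print("the recovered counts above measure how faithfully the chain replays")
print("that structure from raw peptide-level counts.")
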