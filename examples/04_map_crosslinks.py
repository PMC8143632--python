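"""Cross-link to domain mapping with a planted interaction hotspot.

Synthetic DSSO-style cross-links concentrate in the scaffold's central
interaction domain; the permutation test (residues redrawn uniformly over
the scaffold's lysines) flags the hotspot, and same-protein links with
overlapping peptides are classified as intermolecular self-links
(homodimer evidence).
"""

from apmskit.synth import GeneratorConfig, generate_crosslinks, generate_proteome
from apmskit.xlmap import domain_link_density, map_crosslinks, mapped_links_table

cfg = GeneratorConfig(seed=5, n_background=8, n_crosslinks=60,
                      hotspot_fraction=0.8, selflink_fraction=0.15)
proteome = generate_proteome(cfg)
records, truth = generate_crosslinks(cfg, proteome)
mapped = map_crosslinks(records, proteome.domains, proteome.proteins)

table = mapped_links_table(mapped)
print(table["link_class"].value_counts().to_string())

density = domain_link_density(
    mapped, proteome.domains, proteome.proteins, focus="bait1",
    n_permutations=1000, seed=0, per_partner=False,
    precedence=[cfg.hotspot_domain],
)
print()
print(density.to_string(index=False))
print()
print("The hotspot domain's link count is far above the uniform-lysine null")
print("(small p), while links elsewhere are consistent with chance.")
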