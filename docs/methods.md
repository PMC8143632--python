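# Methods

This note documents the models and procedures implemented in `apmskit`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices that matter for
reproducibility.

## Distributed spectral counts and dNSAF

Spectral counting treats the number of MS/MS spectra matched to a
protein's peptides as a proxy for its abundance in a run. Peptides shared
between proteins (common for paralogs such as the two Sin3 scaffolds,
HDAC1/HDAC2 or RBBP4/RBBP7) would otherwise be double-counted or
discarded; instead each shared peptide's count *s* is **distributed**
among its owner set *O* in proportion to the owners' unique spectral
counts in the same run:

    share_k = s · uSpC_k / Σ_{j∈O} uSpC_j .

When every owner has zero unique counts the share is split equally — the
degenerate case is left open by the originating method descriptions, and
the equal split is the unique choice that preserves count conservation
without importing information from other runs. Distribution never borrows
unique counts across runs: each purification replicate is quantified on
its own evidence.

The distributed count `dSpC = uSpC + Σ shares` is length-normalized and
scaled to the run:

    dNSAF_k = (dSpC_k / L_k) / Σ_i (dSpC_i / L_i) ,

a unitless relative abundance summing to 1 over the proteins detected in
the run. Invariants enforced (and tested): `Σ dSpC` equals the raw count
total to 1e-9; `dSpC ≥ uSpC ≥ 0`; `Σ dNSAF = 1 ± 1e-9`; increasing a
protein's unique count never decreases its dSpC. Protein length is the
full sequence length of the database entry, including any affinity tag
present in the recombinant construct — whether published analyses strip
tag residues from `L` is generally unstated, so the full length is used
and noted here. Contaminant-flagged proteins stay in the dNSAF
denominator by default (normalization should reflect total identified
signal); a switch excludes them at the reporting layer only.

**bdNSAF** divides a prey's dNSAF by the bait's dNSAF in the same run,
expressing prey recovery per unit of purified bait. It is reported per
replicate and aggregated as the mean over replicates in which the bait
was detected (median available; the aggregation choice is not dictated by
the quantities themselves). Runs where the bait has zero dNSAF are
excluded from aggregation with a warning — the ratio is undefined there,
not zero.

## Prevalence filter and Poisson enrichment model

Preys observed only sporadically are removed before scoring: a prey is
retained iff, for some bait, it is detected (`dSpC > 0`) in at least half
of that bait's replicates, implemented as `detections ≥ ceil(n/2)` — the
natural reading of "at least half" with integer detections (2 of 3, 2 of
4).

Each retained prey is scored per bait against the **pooled**
negative-control runs with a Poisson generalized linear model on spectral
counts:

    y_ij ~ Poisson(μ_ij),   log μ_ij = α_i + o_j + β_i x_j

where `x_j` indicates bait runs and `o_j` is a known log-offset for run
depth (the per-prey `log L` offset used by some spectral-count models is
constant within a prey's row and is absorbed into `α_i`). Priors are
weakly informative normals: `α ~ N(0, 10²)` and `β ~ N(0, 3²)` on the
natural-log scale — the β prior says fold changes beyond ~e⁹ are
implausible, which regularizes preys with all-zero control counts without
biasing effects of realistic size (a 30-fold enrichment is shrunk by
under 2%).

Sampling is random-walk Metropolis-within-Gibbs, alternating α and β
updates. Because the Poisson likelihood depends on the data only through
the count totals and group exposures, each update is O(1) per prey, and
all preys' chains advance in lockstep as vectorized array operations —
scoring hundreds of preys at the default burn-in 2000 / 10,000 retained
draws takes well under a second. Step sizes adapt per prey toward a 0.44
acceptance rate during burn-in and are frozen afterwards, so retained
draws come from a fixed, valid kernel. Given identical data and seed the
output is bit-identical; within a multi-bait analysis each bait's chain
gets a seed derived deterministically from the top-level seed.

Reported statistics: `log2fc = E[β]/ln 2` and `z = E[β]/SD[β]` over
retained draws. A prey is **enriched** when `z ≥ 3` and `log2fc ≥ 2`,
both inclusive. Preys with zero counts in both groups are skipped with a
sentinel (never scored, never enriched). Scoring consumes integer
spectral counts; when fed from quantification the distributed counts are
rounded to the nearest integer, which only affects preys with substantial
shared-peptide signal and keeps the Poisson likelihood exact. One caveat
is inherited from the literature this model class comes from: published
implementations derive their Z-like statistic from a Bayes factor, and
whether a particular released version matches the coefficient-based
`E[β]/SD[β]` exactly cannot be determined from their descriptions; the
coefficient-based form is used here and stated as such. Measured behavior
under the benchmark conditions (3 runs/group, mean control count 2): null
false-call rate well under 1%, power at 8-fold enrichment above 90%.

## Networks, modules and heatmaps

Enriched-prey sets support exact overlap partition (shared / A-only /
B-only) and the Jaccard index `|A∩B|/|A∪B|`; two empty sets get `J = 0`
with a warning (0/0 has no information, and 0 keeps such baits maximally
distant rather than spuriously identical). Baits are clustered by UPGMA
(average linkage) on the distance `1 − J`: clustering operates on a
similarity in the source analyses, and `1 − J` is the canonical monotone
transform to a distance. The implementation delegates to
`scipy.cluster.hierarchy.linkage(method="average")` behind the module
surface; bait labels are sorted before the matrix is built, so merge ties
resolve by label order and results are platform-independent. Merge
heights are non-decreasing (ultrametricity, asserted in tests and checked
against an exhaustive pair-averaging oracle); Newick export uses the
cophenetic convention (leaf depth = half the merge height).

Heatmap standardization is per prey row: subtract the row minimum, divide
by the maximum of the *shifted* row, mapping each row onto [0, 1]
(a constant row maps to zeros). Dividing by the shifted-row maximum —
rather than the raw-row maximum, which the usual one-line descriptions
leave ambiguous — is chosen so the output exactly spans a heatmap colour
scale; the transform is idempotent and invariant to adding a constant to
a row.

Paralog preference compares two paralogous preys' bdNSAF across a bait's
replicates: means, their ratio, and a call of "prefers A/B" only when one
paralog exceeds the other in *every* replicate; one-sided detection is
reported as "A only"/"B only", never as a 0/0 ratio.

## Cross-link mapping

Coordinates are 1-based inclusive throughout. A residue maps to *all*
domains whose interval contains it — annotations may legitimately nest
(an experimentally defined interaction region can encompass a Pfam
domain) — and reporting layers may collapse multi-domain hits by an
explicit precedence list or, by default, to the smallest (most specific)
interval.

Classification: links between different proteins are heteromeric. For a
link within one protein, overlapping peptide spans or identical linked
residues are impossible within a single molecule, so such links are
classified `self_link_intermolecular` — direct homodimer evidence; links
with disjoint spans are `ambiguous_same_protein` (intra- vs
inter-molecular cannot be distinguished without structural information,
and the plain `intra_protein` label is reserved for externally resolved
cases). Classification is symmetric under swapping the two sides.

The hotspot test formalizes the qualitative notion of a "cluster of
cross-links" in a domain: the null redraws each link's focus-side residue
uniformly over the **lysine** positions of the same protein — the
linker's chemistry targets lysines, so a uniform-over-residues null would
be miscalibrated — preserving per-protein link counts. P-values use the
add-one permutation estimator `(b+1)/(n+1)`. Every input link appears
exactly once in the summary (asserted).

## Global alignment

Needle-style global alignment with affine gaps: BLOSUM62, gap open 10.0,
gap extend 0.5 (a gap of length L costs `10 + 0.5·L`), end gaps
unpenalized — the defaults of the classic tool, which is what published
percent-similarity figures are produced with. The engine is Biopython's
`PairwiseAligner` configured to this scheme; an independently written
three-state DP and an exhaustive alignment enumerator serve as test
oracles. Statistics follow the EMBOSS conventions: identity = % of
alignment columns with identical residues, similarity = % of columns with
a positive substitution score (identities included), gaps = % of columns
containing a gap; all over the full alignment length, rounded to whole
percent when compared against printed values. When multiple alignments
tie for the optimal score, the aligner's deterministic first alignment is
reported; the score is tie-invariant. The comparison against the
published full-length and domain similarity values for the two Sin3
scaffold isoforms requires the reference sequences, which are not
redistributed with the package; the acceptance test documents the
expected `data/reference/` layout.

## Synthetic study generator

The generator emulates the *statistical* structure of a small AP-MS
screen: a proteome of fully tryptic peptides (cleave after K/R, no
proline in the synthetic alphabet so digestion is exact and unambiguous);
paralog pairs sharing an exact, configurable fraction of peptides at
colinear positions; a run design of ≥3 replicates per bait plus
negative-control runs from untagged cells; and Poisson peptide counts
`~ Poisson(depth · mean_count · abundance · w_p)` with fixed per-peptide
propensities `w_p` (peptides ionize unequally). Every proteome protein is
a nonspecific background binder in every run (abundance 1), planted
interactors are multiplied by their fold change in their bait's runs, the
bait itself is highly abundant in its own purifications, and a per
protein-run dropout (default 0.05) emulates stochastic missingness.
Counts are Poisson to match the enrichment model class; a gamma
overdispersion knob exists for robustness experiments and defaults to
off. Cross-link generation places a configurable fraction of scaffold
residues on lysines inside a designated hotspot domain, draws the rest
uniformly over lysines, and plants intermolecular self-links as two
lysines within one scaffold peptide. Generation is deterministic given
the config seed (byte-identical FASTA on repeat).

Defaults for the **two-paralog reference design**: two scaffold baits
sharing 50% of peptides, 18 planted interactors each with 7 in common,
fold change 30 (stable complex subunits in AP-MS are enriched tens-fold
over no-transgene controls, often absent from them entirely; the 8-fold
setting is kept separately as the power-benchmark floor), mean background
count 2, three replicates per bait, three controls, 25 background
proteins.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: peptide-level FDR and
identification error, intensity/retention-time structure, correlated
background binding (the CRAPome-style contaminant correlation structure),
missed cleavages and modified peptides, overdispersion beyond Poisson
(off by default), and between-replicate depth drift. Results on real
exports additionally depend on upstream search and filtering software,
which this package deliberately consumes rather than reimplements.

## Pipeline and numerics

The pipeline validates all inputs before any computation, runs
quantify → filter → enrich → network → cluster → cross-link mapping, and
writes a manifest with input SHA-256 hashes, all parameters and seeds;
deterministic stages are byte-identical on re-run and stochastic stages
are identical given seeds. Problem sizes in tests and the acceptance
script (e.g. 200 null preys, 50 recovery seeds, 100 oracle matrices,
1000 alignment pairs) were chosen so the entire battery runs in seconds
on one core while keeping binomial noise well inside the asserted
margins. The enzyme-activity helper normalizes raw fluorescence to bait
abundance (`RFU / abundance`) and compares conditions with a Welch
two-sample t-test — the underlying reports mark significance without
naming a test, so the choice is recorded in the output.

Known limitations: the enrichment Z is coefficient-based (see above);
UPGMA tie-breaking follows sorted-label index order rather than a full
lexicographic cluster comparison; the hotspot test conditions on observed
per-protein link counts rather than modelling them; and percent-similarity
comparisons are only as meaningful as the substitution matrix and gap
parameters they assume.
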