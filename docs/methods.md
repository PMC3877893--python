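# Methods

`cyanoscreen` reimplements, as desk-scale software, a PCR-based screen for
cyanobactin biosynthesis capacity in cyanobacteria. The wet-lab study this
kind of screen supports amplifies a fragment of the cluster's *N*-terminal
protease gene (the A-gene) with degenerate primers, confirms amplicon
identity against the homologous C-terminal protease (G-gene), builds a
maximum-likelihood phylogeny of the confirmed fragments, and reads lateral
gene transfer off the disagreement between the A-gene tree and the 16S
rRNA species tree. Every component here is testable against ground truth
because the input data come from a fully recorded simulator.

## Primer design (`primer_design`)

Candidate priming sites are conserved windows of a nucleotide alignment.
The per-column consensus is the minimal IUPAC code covering **all**
observed bases (ambiguities in the input expand first): a primer intended
to be universal must bind every known template, so a majority consensus
would be wrong here. Window filters: length 17–22 by default, per-primer
degeneracy ≤ 96, per-column gap fraction ≤ 0.10 (indels break annealing;
the threshold is ours), and degeneracy ≤ 2 at each of the three 3′-terminal
positions (polymerase extension is most sensitive there). Pairs are ranked
by combined degeneracy, then mean gap fraction, then 3′-end degeneracy,
ties broken leftmost. The nominal product length is measured on the
consensus with majority-gap columns dropped — one number, as a screen
reports it, although real amplicons vary.

Melting temperatures use the Wallace rule, Tm = 2(A+T) + 4(G+C), reported
as a (min, max) range over the degenerate family. Because positions
contribute independently, the range is computed exactly from per-position
extrema at any degeneracy — no enumeration. Wallace is deliberately simple
and parameter-free; it ranks candidates deterministically and is
replaceable if nearest-neighbor accuracy is ever needed.

The package ships the published screening pair as its default:
CBT_AF `TTVGGYTAYGAYTTYGG` (degeneracy 48) and CBT_AR
`AGACCARGAACGRACTTC` (degeneracy 4), nominal product 804 bp.

## In-silico PCR (`insilico_pcr`)

Primer annealing is IUPAC set intersection per position, implemented as
4-bit masks over numpy sliding windows; a site is reported when the number
of non-intersecting positions is at most `max_mismatch`. The default is 0
mismatches *against IUPAC semantics* — the degenerate codes already encode
the intended tolerance; values up to 3 emulate the permissive end of an
annealing-temperature gradient. Both template strands are scanned, and
both primer arrangements (forward primer facing right with the reverse
primer facing left, and the mirror) are paired, so the predicted product
set is exactly strand-symmetric. Products are excised verbatim from the
forward strand with 0-based half-open coordinates. An empty product list
is the "PCR-negative strain" outcome, not an error. No 3′-anchor rule is
applied at match time; the design stage already constrains 3′ degeneracy.

## A/G triage (`gene_classify`)

The two protease genes are homologous over portions of their length, so
the screen recovers both and must discard G-gene amplicons. In place of a
BLASTn against a public database, queries are scored by canonical k-mer
containment, score_X = |kmers(q) ∩ profile_X| / |kmers(q)|, with k = 11
and the winner required to lead by a margin (default 0.05); below the
margin the call is "ambiguous" and surfaced rather than dropped.
Containment (not Jaccard) keeps scores comparable when short amplicons
meet full-length references. Two limits are intentional: k-mer identity
needs a reference panel containing close relatives of the expected
queries (the role the public database plays for BLASTn), and the method
separates paralogous families at tens of percent divergence — it is not a
remote-homology search. The genome scan classifies sliding windows
(default 900/300) and merges overlapping same-label windows into maximal
intervals.

## Alignment (`msa`)

Progressive alignment with affine gap costs (match +1, mismatch −1, gap
open −4, extend −1; integers for deterministic oracles), profile–profile
Gotoh DP with the column score being the mean residue-pair score (pairs
with an existing gap score 0), merged up an average-linkage guide tree on
1 − Jaccard k-mer distances. Traceback prefers diagonal, then up, then
left; guide-tree ties break lexicographically — every run is
reproducible. The horizontal-gap state of the DP unrolls into a prefix-max
scan, so rows vectorize in numpy and the aligner handles the screen's
~800 bp amplicons in milliseconds. There is no iterative refinement;
for conserved coding genes at this scale the progressive pass suffices,
and externally produced alignments can be imported as aligned FASTA.

## Phylogenetics (`phylo`)

* **Distances.** Kimura 2-parameter with pairwise deletion: sites with a
  gap or ambiguity in either row are excluded;
  d = −½ln(1−2P−Q) − ¼ln(1−2Q). Saturation (non-positive log argument) is
  an error, reported rather than capped — except inside the bootstrap
  driver, where resampled replicates may saturate a pair and a cap of 5
  substitutions/site keeps the replicate's NJ start defined.
* **Starting trees.** Neighbor joining with deterministic tie-breaks
  (smallest Q criterion, then lexicographic cluster labels); negative
  branch lengths clamp to zero. NJ is exact on additive matrices, which
  the tests exploit.
* **Model.** K80 with transition/transversion ratio κ, equal base
  frequencies (implied by the model, never parameterized), discrete-gamma
  rate heterogeneity with K = 5 equal-probability categories (slice means
  renormalized to average exactly 1) and a proportion p_inv of invariant
  sites. The closed-form K80 transition matrix is used throughout and is
  tested against a numeric matrix exponential.
* **Likelihood.** Felsenstein pruning over pattern-compressed columns with
  uniform root frequencies. Gaps and ambiguity codes enter as partial
  vectors (1 for each compatible base). The invariant-site term treats a
  site as "constant" when the intersection of per-leaf compatible base
  sets is non-empty, contributing ¼ per compatible state — the exact
  marginal over the unknown invariant state, equal to ¼ for ordinary
  constant sites.
* **Optimization.** Coordinate ascent: each branch by bounded scalar
  maximization on [10⁻⁸, 10], then κ ∈ [0.1, 100], α ∈ [0.05, 50],
  p_inv ∈ [0, 0.99]; sweeps repeat until the gain drops below 10⁻⁶ (up to
  50 sweeps, then a warning with the best configuration — α and p_inv are
  correlated and can form a slow ridge). A proposal is kept only when it
  improves, so the log-likelihood never decreases. Branch-length updates
  use cached "below/above" conditional vectors per edge, making the
  likelihood a bilinear function of one transition matrix; each branch
  refit costs one vector rebuild plus cheap per-candidate evaluations.
* **Search.** NNI hill climbing: both rearrangements per internal edge,
  each evaluated with the five surrounding branch lengths re-optimized;
  the best strictly improving move is accepted and the scan repeats until
  none improves, in a deterministic edge order. SPR is out of scope at
  this problem size.
* **Bootstrap.** Nonparametric column resampling; replicate r draws from
  a generator seeded `seed + r`, so replicates are independent and the
  whole run is reproducible. Each replicate reruns NJ → branch
  optimization → NNI with the model parameters fixed at the fit from the
  original alignment (a 10–50× saving; `refit_per_replicate=True` restores
  the full procedure) and with looser convergence settings, which affect
  replicate branch lengths but not the topologies that supports count.
  Supports are mapped onto the single best tree (the way published figures
  annotate one ML tree), as the percentage of replicates containing each
  bipartition.

## Tree comparison (`tree_compare`)

Clades are internal-edge bipartitions with bootstrap support at or above a
display threshold — 70 for gene trees, 50 for reference (16S) trees, the
conventional display rules. Incongruence is the unrooted Robinson–Foulds
distance after pruning both trees to their shared taxa (suppressed
degree-2 nodes sum their branch lengths); supports and lengths are ignored
by RF itself. Lateral-transfer candidates come from a transparent greedy
heuristic: repeatedly remove the leaf whose removal most reduces RF (ties
lexicographic) until the trees agree or a budget is spent — the recorded
trajectory is strictly decreasing by construction. A maximum-agreement
subtree would be more powerful but is deliberately out of scope; the
greedy list is directly checkable against simulation truth. A "novel
clade" is a maximal supported clade with ≥ 2 query taxa and no member
annotated with a known chemotype; single query sequences are loners, not
clades.

## Synthetic data (`synthetic_data`)

The generator produces every input the pipeline consumes, with truth
recorded:

* **Species tree.** Yule pure-birth process, rescaled to a fixed
  root-to-tip height (default 0.3 substitutions/site). Unscaled Yule
  depths grow like ln(n)/λ and would saturate the K2P estimator; 0.3
  leaves strong signal while staying comfortably within its range, a
  realistic order of divergence for a conserved biosynthesis gene across
  genera.
* **Gene tree.** Horizontal transfer is modeled as seeded leaf-SPR: a
  random leaf (the recipient) is pruned and regrafted at the midpoint of a
  non-adjacent edge (the donor lineage), retried until the topology
  actually changes. Whole-gene transfer of single lineages keeps the truth
  recipients unambiguous for the recovery checks.
* **Sequences.** Root drawn uniformly; per site, an invariant flag (prob
  p_inv) or one of K gamma categories is drawn once and shared across the
  tree; children mutate through the closed-form K80 matrix. Defaults
  κ = 4, α = 0.5, p_inv = 0.1, K = 5. Indels, off by default so the true
  alignment is the ungapped site grid, are single-base deletion events
  (probability `indel_rate · t` per site per branch) inherited by all
  descendants; insertions are not modeled.
* **Paralogs.** The G family duplicates the A root, mutates it along a
  branch of length `paralog_divergence` (default 1.0), then evolves down
  the same tree re-using the A family's random stream, so tips differ only
  where the duplication branch substituted. Without that coupling the two
  families would accumulate an extra 2× tree height of incidental
  divergence and the duplication depth would no longer control A-vs-G
  identity.
* **Templates.** Each taxon's genomic template carries the A core and the
  G core, each framed by one random expansion of the forward primer and
  the reverse complement of one expansion of the reverse primer, inside
  random flanks (400 bp) and a 500 bp spacer. Default core length is 769,
  so products are 17 + 769 + 18 = 804 bp, the published nominal length.
  The screen therefore recovers two products per strain, and
  classification decides which enter the phylogeny. Emitted reference
  panels contain the true cores of all taxa — the stand-in for a public
  database that holds close relatives of everything the screen can
  amplify.

What the generator does **not** emulate: realistic genomic base
composition or codon structure, insertions, within-gene recombination,
rate variation across lineages, and sequencing error. Passing tests
demonstrate correctness of the algorithms under the stated model, not
robustness to those real-data complications.

## Pipeline (`pipeline`, CLI `cyanoscreen`)

Stages: simulate-or-ingest → PCR → classify → align → tree (+bootstrap) →
compare → report. One top-level seed fans out to per-stage seeds by
stable CRC hashing of stage names, so any stage is reproducible in
isolation. Artifacts (FASTA/Newick/TSV) and SHA-256 checksums go into a
manifest; `--resume` reloads stages whose artifacts still match. A strain
is "positive" when at least one of its amplicons classifies as A. The
comparison stage takes any reference Newick; for simulated runs the truth
species tree serves as the 16S-analogue reference.

## Verification strategy and problem sizes

Every numerically substantive operation is tested against an independent
oracle: brute-force expansion search for degenerate matching, exhaustive
alignment enumeration for the DP, matrix exponentials for transition
probabilities, internal-state enumeration for the pruning likelihood (all
unrooted topologies with ≤ 5 leaves), dendropy for Robinson–Foulds, and
additive matrices for NJ. Simulation studies run at sizes a laptop handles
in minutes: 100 four-taxon replicates at 2000 sites for topology recovery,
20 six-taxon replicates for κ/α recovery, 100 bootstrap replicates (the
scaled-down stand-in for the conventional 1000) for support calibration,
and 12-taxon end-to-end screens. The no-signal bootstrap condition
simulates on a star tree: truly identical sequences would make every
replicate's NJ tie-break identically, which manufactures spurious 100%
supports, whereas star-tree data have no true internal structure and give
the intended low supports.

## Known limitations

* The α/p_inv ridge can leave the joint optimizer short of the exact
  optimum at the sweep cap (it warns); branch-length-only optimization
  converges cleanly.
* k-mer triage requires close references and nucleotide-level divergence
  between classes; it does not replace profile or translated search.
* The greedy displaced-taxon heuristic can name an adjacent leaf instead
  of the true recipient when a transfer lands next to it; recovery is
  evaluated statistically over seeds, not promised per instance.
* No model selection: the substitution model is fixed to K2P+Γ+I by
  design.
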