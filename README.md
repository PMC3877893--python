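# cyanoscreen

In-silico screening and molecular phylogenetics of cyanobactin
*N*-terminal protease (**A**) genes.

Cyanobactins are ribosomally synthesized cyclic peptides made by
cyanobacteria from a biosynthetic gene cluster whose two proteases — the
*N*-terminal protease (A) and the *C*-terminal protease (G) — are
mutually homologous. Screens for cyanobactin capacity amplify a fragment
of the A-gene with degenerate primers, discard the G-gene amplicons the
primers also recover, and place the confirmed sequences in a
maximum-likelihood phylogeny; incongruence between that gene tree and the
16S rRNA species tree is the signature of horizontal transfer of the
cluster. `cyanoscreen` implements that entire strategy as a reusable,
deterministic pipeline for people who work on RiPP gene screening and
phylogenetics: primer design from alignments, in-silico PCR with IUPAC
semantics, k-mer A/G triage, progressive alignment, K2P+Γ+I maximum
likelihood with nonparametric bootstrap, tree comparison, and a
ground-truthed synthetic data generator to validate all of it.

The default primer pair is the published screening pair
CBT_AF `5'-TTVGGYTAYGAYTTYGG-3'` / CBT_AR `5'-AGACCARGAACGRACTTC-3'`
(degeneracies 48 and 4), which amplifies a nominal **804 bp** region of
the A-gene.

## The model at the core

Distances and likelihoods use the Kimura 2-parameter model with
gamma-distributed rate variation (five discrete categories) and a
proportion of invariant sites (K2P+Γ+I):

* distance: `d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)` with transition and
  transversion proportions P, Q under pairwise deletion;
* likelihood: Felsenstein pruning with the closed-form K80 transition
  matrix, per-site rates from equal-probability gamma slices (mean 1) and
  the invariant-site mixture
  `L = p_inv·L_inv + (1-p_inv)·(1/K)·Σ_k L(r_k)`;
* inference: neighbor-joining start, coordinate-ascent fitting of branch
  lengths and (κ, α, p_inv), NNI hill climbing, bootstrap supports mapped
  onto the best tree.

Gene/species incongruence is the unrooted Robinson–Foulds distance on
shared taxa; lateral-transfer candidates are found by greedily removing
the leaves that most reduce it.

## Worked example

Simulate a 12-strain study with two lateral transfers, then run the whole
screen on it:

```bash
cyanoscreen simulate --taxa 12 --hgt 2 --seed 1 --out demo_data
printf 'seed = 1\nn_taxa = 12\nn_hgt_events = 2\nbootstrap = 100\nout_dir = demo_out\n' > demo.cfg
cyanoscreen run demo.cfg
```

which prints:

```
positives: 12/12
incongruence: RF=8/18
displaced: t01 (RF after removal 6)
displaced: t11 (RF after removal 0)
```

Reading: all 12 strains were PCR-positive and kept an A-classified
amplicon (each strain also yields one G-gene amplicon, which the
classifier discards — the screen's false-positive analogue). The
reconstructed A-gene tree disagrees with the species tree by a
Robinson–Foulds distance of 8 out of a possible 18 — the footprint of the
two simulated transfers — and greedily removing `t01` then `t11` restores
full agreement, so those strains are the lateral-transfer candidates.
`demo_out/` holds the stage artifacts: amplicon FASTA, classification and
screen-report TSVs, the aligned A-genes, the ML gene tree with bootstrap
supports in Newick, and the incongruence/displaced-taxa tables.

Individual stages are also available (`cyanoscreen design`, `pcr`,
`classify`, `scan`, `align`, `tree`, `compare`); see `--help` on each.

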