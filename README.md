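# phyloshift

Phylogeny-wide scanning for evolutionary shifts in protein–ligand binding
affinity. The package reconstructs ancestral protein sequences at every node
of a rooted phylogeny, attaches replicate affinity (pKd) estimates to each
ancestral and extant sequence through a pluggable predictor interface, and
then locates the branches on which affinity changed:

- **`core_io`** — FASTA alignment / Newick tree data model, support-aware
  polytomy collapse, midpoint rooting, TSV node tables.
- **`asr`** — empirical amino-acid models (LG/WAG/JTT, discrete-gamma rate
  variation, optional 21st gap state), pruning likelihoods, marginal
  ancestral reconstruction with per-site posteriors, and posterior sampling
  of ancestral sequences.
- **`affinity`** — pKd/Kd algebra, replicate aggregation (mean, SE), the
  predictor contract, and an additive synthetic predictor for testing.
- **`shift_scan`** — branch-wise Welch tests of child vs. parent replicate
  pKds with Benjamini–Hochberg FDR control, robustness checks against
  ancestral-sequence ambiguity (ML vs. posterior draws), ambiguity–affinity
  correlations, and KDE mode estimation.
- **`bm_ratescan`** — Brownian-motion trait model whose branch rates carry
  discrete, inherited shift multipliers; reversible-jump MCMC over shift
  configurations (birth/death/move/scale plus a σ²-ridge rescale move),
  with measurement error folded into a pruning likelihood and an ASDSF
  convergence gate across independent chains.
- **`kinetics`** — label-free sensorgram fitting: reference subtraction,
  steady-state one-site Kd, association-phase exponential fits (kobs, and
  kon/koff by regression), half-saturation Km, and Welch comparisons of
  binding constants on the −log10 scale.
- **`domain_cluster`** — similarity graphs from −log10-capped E-values with
  degree capping, Markov clustering (pre-inflation, inflation sweep), and
  annotated-node cluster selection.
- **`consensus`** — clade presence/absence (MRP) matrices with PHYLIP/TSV
  export and majority-rule consensus trees with frequency supports.
- **`synth`** — seed-deterministic generators with machine-readable ground
  truth for every stage: sequence evolution on trees, motif-driven affinity
  profiles with planted shifts, BM traits with planted rate multipliers,
  and 1:1 Langmuir sensorgrams.

## Command line

```bash
# simulate a tree + profiles with one planted +0.7 pKd shift, then scan
phyloshift simulate profiles --leaves 32 --seed 7 --prefix demo
phyloshift scan --tree demo.nwk --profiles demo.profiles.tsv --out scan.tsv

# Brownian-motion rate-shift inference (4 chains, ASDSF gate reported)
phyloshift bmshift --tree t.nwk --values v.tsv --chains 4 \
    --gens 100000 --thin 100 --burnin 0.25

# kinetics: fit Kd/Km from a sensorgram TSV
phyloshift simulate sensorgram --kd-um 3.2 --out sg.tsv
phyloshift kinetics fit --input sg.tsv

# MCL clustering sweep with annotated-node selection
phyloshift cluster --edges edges.tsv --annotated ids.txt
```

File formats are plain text throughout: FASTA alignments, Newick trees with
supports as internal labels, and TSV tables (affinity profiles:
`node_id, source, rep_1..rep_n, mean, se`; sensorgrams:
`time_s, conc_M, response, probe_id, phase`).

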