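# Methods note

This note records the model, the generator design, and the numerical choices
behind `cistranskit`, including simplifications a user should know about.

## Experimental design being modeled

Two inbred strains (A, B) are compared across four arms:

| arm | groups compared | isolates |
|---|---|---|
| F0 | parental strain A vs B | total strain difference |
| F1_allele | allele A vs allele B within F1 hybrids | cis effects (shared nucleus) |
| F0_NSG | strain A vs B donor cells sharing one host | removes environmental differences |
| F1_NSG_allele | alleles within F1 donor cells in a host | cis effects in the chimera context |

Classification is a two-axis scheme: features significant in F0 and in the
F1 allelic contrast with the same sign are **cis**; F0-only is **trans**;
allelic-only is **mixed** (compensated or context-dependent); neither is
**same**; both-significant with opposite signs is reported explicitly as
**discordant** rather than silently binned. Among trans features, the
chimera arms split the call: no F0-NSG difference ⇒ **trans-environmental**;
an F0-NSG difference without F1-NSG allelic imbalance ⇒
**trans-cell-autonomous**; the remainder is **unresolved**. The cis check is
resolved first via allelic imbalance, as a decision list.

## Pseudogenomes and allele assignment

Variants (SNPs and anchored indels up to 6 bp) are spliced into the
reference per strain. Coordinates are 0-based half-open internally, 1-based
in VCF. The coordinate map is piecewise-constant in the offsets; positions
falling in sequence deleted from the target frame snap to the nearest left
anchor and carry a `deleted` flag, so the map round-trips exactly everywhere
else. The length invariant `len(pseudo) = len(ref) + Σ(len(alt) − len(ref))`
is enforced by construction and tested.

A read is assigned to a haplotype iff it matches that haplotype's sequence
exactly over its span, the span covers ≥ 1 position where the haplotypes
differ, and the homologous window in the other haplotype differs from the
read. Reads matching both frames (possible near indel edges) or neither are
unassigned. This is deliberately exact-match only: with error-free synthetic
reads, precision and recall are both testable at 100%; with a nonzero
simulated error rate, recall degrades (mismatching reads are unassigned)
while precision is preserved.

## Differential engine

A transparent simplification of DESeq2, calibration-tested rather than
numerically identical:

- median-of-ratios size factors (library-size fallback when no feature is
  observed in every sample);
- per-feature NB dispersion by method of moments within groups, then a
  linear blend `α = 0.2·α_raw + 0.8·(a0 + a1/μ)` toward a least-squares
  trend fitted on features with μ > 1, clipped to [1e−8, 10]. The blend is
  linear (not log-space) because log-space averaging let low outliers drag
  the estimate down and produced anticonservative null calibration;
- Wald test on log2 fold change via the delta method, with a pseudo-count of
  0.5 on normalized means; paired (allelic) designs average per-replicate
  log-ratios and their model variances instead;
- Benjamini–Hochberg across features passing a strict abundance floor;
  filtered features get `padj = NaN` and can never be significant.

Against pydeseq2 on a planted dataset, log2 fold changes correlate at
r > 0.95 and both engines recover > 90% of planted 4-fold features (see
`tests/test_quantify.py`). Null calibration (fraction of raw p < 0.05 on
5,000 null features) sits in [0.03, 0.07].

All threshold comparisons are strict: |log2FC| > 1, padj < 0.05, TPM > 8,
normalized tags > 16 (accessible) and > 32 (active) at 1e7 tags per library.

## Synthetic generators

All generators draw from `numpy.random.default_rng` seeded through fixed
per-generator stream keys from `SimulationConfig.seed`, so one seed
determines every output. Counts are NB with `var = μ + αμ²`. Not emulated:
fragment-length models, GC bias, duplicates, mappability.

- **Genomes/reads**: Poisson variant count at the configured density,
  non-overlapping anchors (successive anchors ≥ `max_indel_len + 2` apart,
  which thins a few percent off the Poisson draw), 10% indels. Reads are
  drawn uniformly over features and haplotypes; each read records its true
  haplotype and whether its span is discriminable — the assignment truth.
- **Design counts**: each feature gets one regulation class; a class is a
  row of arm→biased flags (cis biases all four arms; trans-environmental
  only F0; trans-cell-autonomous F0 and F0-NSG; mixed only the allelic
  arms). A planted |log2FC| f splits symmetrically (2^{±f/2}); allelic arms
  halve the baseline mean.
- **Stimulus (LPS) arms**: strain-specific responders follow three
  archetypes defined by the non-responder's basal level — low (μ0/F), equal
  (μ0), high (μ0·F, i.e. already at the induced level) — while the responder
  goes μ0 → μ0·F. Responsive features are a minority (30% strain-specific +
  10% shared by default): with half the features induced, median-of-ratios
  size factors absorb the induction and the treated-vs-basal contrast
  collapses, so a stable majority is both realistic and necessary. The
  cis/trans regulation of a responder is drawn conditional on its basal
  category, planting the basal × regulation dependence the chi-squared test
  must detect. F1 allelic means mirror the strain means for cis features
  and average them for trans features, per treatment.
  High-basal features have no strain difference in the treated state (the
  non-responder starts there), so the pipeline classifies regulation per
  condition and combines: the treated-state call is used when informative
  (cis/trans/discordant), otherwise the basal-state call
  (`combine_regulation_calls`).
- **Motif landscapes**: positive sequences carry an intact site *sampled
  from the target PWM* (instances vary across pairs); in mutated pairs the
  negative copy carries a substitution at a random top-half-informative
  motif position plus 3 random background substitutions outside the site,
  emulating the linked variation a comparator strain carries at a
  differential locus. Unmutated pairs are identical, so they score equally
  for every PWM and drop as zeros. Decoy PWMs are Dirichlet draws with
  moderate sharpness (concentration 1/5 per base); sharper decoys, or a
  fixed planted instance, make decoy p-values anticonservative because the
  paired differences stop being exchangeable in sign.
- **Variant-driven peaks**: at a lower variant density (1/1000), only peaks
  with ≥ 1 variant within the central 200 bp are eligible for a planted
  effect (sizes 1.5/2.5/3.5 log2 units so every fold-change stratum is
  populated); every differential peak therefore harbors local variation
  while similar peaks carry variants at the background rate.
- **Ligand network**: exponential prior scores; one planted active ligand
  gets an additive exponential bump on the focal strain's target set;
  per-strain target sets are disjoint. One ligand is forced below the
  sender-expression floor to exercise the strict > 10 TPM filter.

## Statistical components

- **Motif-mutation statistic**: per peak, difference of maximal PWM log-odds
  scores (both strands, uniform background, pseudocount 0.01, N scores 0)
  between the higher- and lower-signal strain sequences; zero differences
  dropped; two-sided Wilcoxon signed rank; BH q across PWMs within a run.
- **Chi-squared association**: Pearson chi-squared without continuity
  correction on the basal-category × regulation-class contingency table,
  restricted to cis/trans by default.
- **Ligand activity**: Pearson correlation between a ligand's prior scores
  and the binary target-membership indicator over the union of targets and
  the expressed background; z-scores across strains use ddof = 1. The prior
  matrix is an input, not computed — the bespoke analysis is the filtering
  and scoring, not network propagation. The target fold-change cutoff
  defaults to log2 > 2, the literal reading of "log (fold change) > 2"; it
  is exposed as `target_lfc` since the intended base is ambiguous.

## Limitations

- The NB engine is not DESeq2: no Cox–Reid adjustment, no outlier
  refitting, no lfcShrink. It is validated by calibration, power, and a
  pydeseq2 cross-check, not by numerical identity.
- Generators plant clean, symmetric effects; recovery rates near 1.0 on
  these benchmarks do not predict performance on real data with mapping
  bias, batch structure, or correlated features.
- Allele assignment requires perfect matches, so sequencing errors trade
  recall for precision; no quality-aware alignment is attempted.
- The coordinate map's left-snap convention for deleted positions is a
  choice; peaks whose midpoints are deleted in a strain are skipped with a
  warning rather than re-anchored.
- Evaluation metrics in the scorecard are computed only for stages that ran;
  the scorecard is descriptive, not a hypothesis test.
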