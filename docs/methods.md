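# Methods

## Problem and model

The package classifies members of a two-lobe enzyme superfamily (kinase-like
fold: an N-lobe domain, a short linker, a C-lobe domain) into functional
families. The premise is that function tracks two signals that plain
sequence identity misses: the multi-domain architecture (MDA) of the full
protein, and a small number of specificity-determining positions (SDPs) in
the catalytic unit that are conserved within a functional family but differ
between families.

## Pipeline

1. **Hit resolution** (`sequence_domains.resolve_hits`). Domain scan hits
   for one sequence are treated as weighted closed intervals; a
   weighted-interval-scheduling dynamic program selects the non-overlapping
   subset with maximum total score. Ties are broken toward more hits, then
   toward the lexicographically smallest hit list, so resolution is fully
   deterministic.
2. **Functional units** (`build_functional_units`). An N-lobe hit followed
   immediately by a C-lobe hit with a linker of at most `linker_max = 20`
   residues forms one catalytic unit, identified as
   `seq_id/n_start-c_stop`. Unpaired lobes are logged and skipped; a
   sequence can contribute several units (tandem kinases).
3. **MDA assignment**. The resolved architecture is rendered as a token
   string in which each paired lobe couple collapses to one `FU:` token.
   Units are partitioned by MDA before any clustering, so families never mix
   architectures accidentally; they may span architectures only through the
   explicit pooling step below.
4. **S90 clustering** (`clustering.greedy_cluster`). Within each MDA,
   units are greedily clustered at ≥ 90 % pairwise sequence identity to a
   representative (identity = matches / shorter length under global affine
   alignment, BLOSUM62, gap open −10 / extend −0.5). This collapses
   near-duplicates so tree building scales with the number of distinct
   sequences, not redundancy.
5. **Merge tree** (`build_merge_tree`). Clusters are agglomerated
   greedily: at each step the pair with the highest profile–profile
   alignment score merges (ties to the lexicographically smallest id pair),
   their alignments are joined by profile alignment, and merge order and
   score are recorded. Profiles are Henikoff-weighted residue frequencies
   with background pseudocounts; profile–profile scoring uses
   `P · B62 · Qᵀ` under affine gaps, normalised by the shorter profile.
6. **Tree cutting** (`funfam_cut.cut_tree`). The tree is walked
   post-order. At a node whose two children are both coherent groups, the
   columns of the joint alignment are scored: a column is an SDP when both
   groups are conserved (≥ `tau_cons` = 0.8), the between-group similarity
   gap (`groupsim`, the smaller within-group conservation minus between-group
   similarity) is ≥ `tau_gs` = 0.4, and the gap fraction is ≤ 0.5. A merge
   is cut — the children become separate families — when both children have
   ≥ `n_min` = 3 members and at least `k_min` = 2 SDP columns separate them.
   If either child is small (< 6 members) **and** low-diversity
   (DOPs < 70), the SDP requirement doubles to `2·k_min` instead of vetoing
   the cut outright: small shallow clusters provide weaker evidence, so they
   must show more columns, but genuine boundaries with many SDPs still cut.
   (An outright veto was tried first and rejected: it irreversibly merged
   true families whose first contact in the tree happened while one side was
   still a small cluster.)
7. **Cross-MDA pooling**. The per-MDA families become the starting
   clusters of one final merge-and-cut pass, allowing a functional family
   whose members occur in several architectures to coalesce into one FunFam
   (its `mda_set` then lists all contributing MDAs).
8. **Unannotated assignment**. Clusters with no experimentally annotated
   member are excluded from family building (annotation purity) and instead
   scanned against the final family profiles for an advisory assignment.

## Downstream operations

- **DOPs** (diversity of positions): 100 × (distinct column conservation
  values, rounded to 4 decimals) / columns. Identical alignments score near
  0; diverse ones above 70.
- **EC purity**: fraction of families whose experimentally annotated
  members share a single 4-digit (or 3-digit) EC number.
- **Profile scanning with E-values**: scores of shuffled-background decoys
  against a profile are fitted to a Gumbel distribution by moments
  (λ = π/(σ√6), μ = mean − γ/λ); a scan hit requires E ≤ 1e-18. With 200
  calibration decoys this keeps false hits below 1 % while consensus-level
  probes score tens of σ above the null.
- **Family mapping**: reference families are labelled one-to-one, split,
  merged or unmapped against a test partition by membership overlap, with
  split taking precedence over merged; scan hits may supplement membership.
- **Druggability**: drug records are kept only with max phase 4, binding
  ('B') assays, pChEMBL ≥ 6, activity < 1 mM and an ATC code starting
  `L01E`; families are tested for target enrichment with the hypergeometric
  tail and flagged at Benjamini–Hochberg q < 0.05.

## Numerical choices

- `ClassifyParams.pseudocount_weight = 0.01` while `build_profile` defaults
  to 1.0 in isolation. A unit pseudocount flattens a singleton profile by
  roughly half but a large cluster barely at all, which systematically makes
  blob–blob merges outscore blob–singleton merges and produces caterpillar
  trees that strand singletons above every cut. A 0.01 pseudocount keeps
  probabilities strictly positive (no log/score singularities) without the
  size-dependent flattening.
- Alignment kernels are compiled with numba; the first call pays a
  compilation cost of a few seconds.
- Conservation uses normalised BLOSUM62 similarity
  `max(0, (B62 + 4)/(diag_max + 4))` averaged over residue pairs and
  down-weighted by gap fraction, so it is bounded in [0, 1].

## Synthetic generator design

The generator plants 6 families (18–22 sequences each) over a 280-residue
unit (100 N-lobe, 10 linker, 170 C-lobe) and three MDA layouts. Two design
choices matter for making recovery a fair, non-brittle test:

- **Separation columns.** Besides 5 planted SDP columns per family pair,
  each family consensus carries 30 "separation" columns drawn from
  high-similarity residue pairs (K/R, Q/E, F/Y, A/S, M/L, I/V) assigned over
  balanced splits of the families. Because each pair's BLOSUM62 similarity
  exceeds 0.6, these columns can never satisfy the SDP `groupsim ≥ 0.4`
  criterion — they separate family profiles in score space (so the merge
  tree groups families correctly) without ever being confusable with true
  SDPs. Every family pair differs deterministically at 18 of them.
- **Fixed mutation counts.** Each sequence receives exactly
  `round(rate × mutable positions)` substitutions at non-planted positions
  rather than independent per-site coin flips. The mean mutation load is
  identical, but the variance reduction keeps within-family profile scores
  cleanly above cross-family scores at every seed instead of merely on
  average.

SDP and separation columns are frozen (never mutated); decoy domain hits
(`9.99.99.99`) overlapping the N-lobe test hit resolution; ~10 % of
sequences are flagged non-experimental to exercise the held-out path; drug
records target two designated families at rate 0.6 against a 2 % background.

## Limitations

- The generator's families are well separated by construction; the 20-seed
  ARI ≥ 0.9 criterion demonstrates correctness of the pipeline, not
  performance on borderline real superfamilies.
- Whether every planted druggable family clears q < 0.05 depends on the
  sampled target draw; FDR control guarantees the absence of false
  positives, not uniform power.
- Profile–profile agglomeration is O(k²) in the number of clusters per MDA;
  the intended scale is thousands, not millions, of sequences.
- E-value calibration fits a Gumbel by moments from 200 decoys; extreme
  tail E-values are order-of-magnitude estimates, which is sufficient for
  the conservative 1e-18 acceptance cutoff.
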