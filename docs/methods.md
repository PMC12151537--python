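# Methods

## The barcode model

Each fluctuating CpG (fCpG) site on the male X chromosome carries a haploid
binary methylation state.  The model underlying every analytic result in
this package is a two-state Markov chain applied independently per site and
per division: a methylated site demethylates with probability `p_d` per
division, an unmethylated site remethylates with probability `p_m`.  With

```
λ = 1 − p_d − p_m          (per-division autocorrelation)
π = p_m / (p_d + p_m)      (stationary methylated fraction)
```

the methylated probability after `k` divisions from a methylated start is
`m_k = π + (1 − π)·λᵏ`.  The expected pairwise difference (PWD) between two
cells that shared ancestry for `s` divisions and then evolved independently
to depths `a` and `b` is computed by transition-matrix powers: the ancestor
state distribution at the split is propagated down each branch and the
cross-branch mismatch probability summed.  No closed-form shortcut is used
for the pairwise oracle, which keeps it an independent check on both the
simulator and the distance kernel.

Assumptions inherited by everything downstream: sites are independent and
identically distributed (no site-specific rates), flips happen only at
divisions (barcodes freeze when cells stop dividing), and the progenitor
barcode is fully methylated.

## Site selection

The cascade retains sites that look intermediate at three levels: bulk WGBS
mean in [0.25, 0.75]; single-cell group means (all cells, inhibitory
neurons, excitatory neurons) of a first reference individual all inside
[0.2, 0.8]; all-cell mean of a second individual inside [0.3, 0.7].  Two
conventions were genuinely open and are fixed as follows:

- **Boundary values are retained.**  The discard conditions are phrased as
  strict inequalities ("less than 0.2 or more than 0.8"), so a mean of
  exactly 0.2 survives.
- **Undefined group means discard the site.**  A group mean over fewer than
  `min_cells` (default 10) covered cells cannot certify "fluctuating"; the
  site is dropped at that stage rather than passed through.
- Group means are means of per-cell binary states, not read-weighted means,
  consistent with the binary barcode model.

The bulk reference is an input table; the external seven-male WGBS data it
represents is not recomputed here.

## Barcode matrix

`binarize` calls 1 when mc/cov > 0.5, 0 when < 0.5, and missing on an exact
tie: discordant reads on a haploid chromosome indicate technical error and
no majority rule is defensible, so ties are excluded rather than called.
Cells need ≥500 covered fCpG sites (the file-size proxy sometimes used to
pre-screen deposited cells is deliberately not replicated — the site-count
rule is the principled criterion it approximates).  Missing is a
first-class state end to end; nothing is imputed.

## Pairwise distances

PWD is the Hamming mismatch fraction over mutually covered sites, defined
only when ≥30 sites are shared (pairs below the gate are excluded, not
errors).  The production kernel packs each cell's states and coverage mask
into uint64 words; mismatches are `popcount((s_a ⊕ s_b) & m_a & m_b)`.
The kernel is certified against a naive double loop (also shipped, in
`fcpg.distance.pairs_naive`) in the test suite; it is never trusted on
faith.  Summaries stream, so million-pair runs need not materialize a full
pair table (`store="close"` keeps only sub-threshold pairs).

## Kinship statistics

"Closely related" means PWD < 0.05 (strict).  All sub-threshold pairs are
counted, not per-cell minimum-PWD partners; a per-cell nearest-neighbor
mode exists as an option (`nearest_neighbor_pairs`).  The within/between
enrichment ratio uses unweighted means of per-report rates; zero
between-rate yields an infinity flag rather than an error.  Percent-same
fidelity for a label divides pairs where both cells carry the label by
pairs where at least one does.  Because close pairs can arise by chance, a
permutation null (labels shuffled across cells) estimates the chance-level
fidelity implied by label frequencies alone.

## Stopwatch

The proxy time axis is per-cell barcode methylation, descending; no
calibration to calendar time is attempted.  Emergence curves are per-type
empirical cumulative fractions along this axis; ties in methylation break
by cell id so outputs are bit-reproducible.  The "predominantly methylated"
site cutoff (0.8) mirrors the stage-2 stability threshold and is
configurable.

## Trees

Binary alignments (0/1/-) are exported in relaxed PHYLIP and FASTA together
with a ready-to-run IQ-TREE command (two-state GTR2+FO+G4 model, which
handles back-mutation and missing data; 1,000 bootstraps).  The external ML
engine is an interface boundary — its inputs are generated and its newick
output parsed, but it is not wrapped or shipped.  The in-repo tree method
is neighbor joining (via scikit-bio) on the PWD matrix.  Incomplete
distance matrices are handled by dropping cells with fewer than 3
qualifying partners and imputing remaining gaps with the mean of the two
cells' observed distances (flagged behavior; sparse overlap is expected at
realistic coverage).  Optional rooting adds an artificial fully methylated
progenitor taxon whose distance to each cell is its unmethylated fraction.
Robinson–Foulds distances are normalized by the 2(n−3) maximum.

## The simulator

`fcpg.sim` generates the study conditions: one complete binary division
tree per individual (realized lazily over the sampled lineages), root
barcode all-methylated, per-division independent flips, cell types exiting
at scheduled depths, per-site independent coverage masking with single-read
semantics, and an optional read-error knob.  Region placement is either
inherited from the earliest lineage branches (radial migration: related
cells co-locate) or drawn uniformly at exit (tangential migration).

The `paper_like` preset encodes the package's reference conditions, chosen
once from the closed forms:

- **5,000 sites, coverage 0.1** → ~500 covered sites per cell and ~50
  shared sites per pair.  At a reduced site count these two scales cannot
  both match the full-data ratios (covered scales with coverage `c`, shared
  with `c²`); the pair-overlap scale wins because the PWD statistics are
  the core, and the per-cell QC threshold is set to 400 at preset scale so
  the coverage rule still bites.
- **Symmetric rates p_d = p_m = 0.05** → stationary methylation 0.5, giving
  deep unrelated pairs PWD ≈ 0.45–0.5 (the randomization regime) while
  shallow types remain clearly methylated.  Real per-division flip rates
  are unknown; these are assumptions, not estimates.
- **Exit schedule** mirroring caudal-to-rostral development: a small
  near-progenitor population (depth 2–4), brainstem/thalamic inhibitory
  neurons shallow (6–11), cortical interneurons intermediate (9–13,
  tangential placement), cortical excitatory neurons deep (11–18, radial
  placement), glia deepest (16–20); ~2,000 cells per individual, 3
  individuals.

What the simulator does **not** emulate: site-specific flip rates,
postnatal division outside the schedule, cell death, read-depth variation,
real chromosomal coordinates, or the broad overlap-size distribution of
real sparse data.  That last gap matters for one statistic: real
between-individual close pairs arise mostly as chance matches between
highly methylated low-overlap cells, and with the preset's concentrated
~50-site overlaps such chance matches are nearly impossible, so the
simulated between-individual close-pair rate is ≈0 and the within/between
enrichment ratio is very large or infinite.  Tests therefore check the
direction of the enrichment (within > between), not its magnitude, and
passing them shows the pipeline recovers planted structure under these
conditions — not that real-data effect sizes are reproduced.

## Numerical and engineering choices

- All thresholds default to the reference analysis values (0.25/0.75,
  0.2/0.8, 0.3/0.7, ≥500 sites/cell, ≥30 shared/pair, PWD < 0.05).
- Every stochastic component funnels through one `numpy` generator seeded
  from a single integer; identical seeds give byte-identical simulation
  bundles and manifests.
- Problem sizes in tests and in `scripts/acceptance.py` (e.g. 10,000–20,000
  sites for Markov checks, 64-cell trees, 0.25-scale enrichment replicates)
  are chosen so three-standard-error bands are tight while the whole suite
  runs in well under a minute of compute per section.
- Degenerate inputs: empty allc files yield empty streams; all-missing
  sites have undefined means; equidistant taxa yield zero-length internal
  NJ branches; zero between-rates yield an infinity flag.

## Known limitations

Female (two-X) cells and autosomal ternary states are out of scope, as are
bisulfite alignment, GEO retrieval, ML tree search internals, and any
spatial model beyond region labels.  Fidelity percentages are descriptive;
no formal test of shared progenitors is attempted.
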