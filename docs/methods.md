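# Methods

`coevnet` implements a coevolving-residue network analysis for protein
families, exercised end to end on synthetic alignments with planted
covariation, and a small amount of downstream experimental algebra
(double-mutant-cycle energetics). This note records the models, the
parameters that matter, the numerical conventions, and what the synthetic
data does and does not establish.

## Alignment model and conservation

An alignment is a rectangle of equal-length rows over the 20 standard amino
acids plus the gap `-`. Non-standard letters (B, Z, X, U, J, O) are mapped
to the gap on input: they carry no information on a 20-letter entropy scale.
Column conservation is Shannon entropy in log base 20,

    H_c = - sum_i p(x_i) log20 p(x_i),

with frequencies taken over the non-gap rows only, so H_c ranges from 0
(one residue type) to 1 (all twenty equally frequent). Gaps are never a
21st symbol. For display profiles, columns more than 10% gapped (strictly)
are assigned the value 1 — they carry no usable conservation signal.

Sequence-level preprocessing mirrors standard family curation: an inclusive
400–500 residue length window; greedy redundancy removal in input order at a
90% identity cutoff (a sequence is kept iff its identity to every previously
kept sequence is at most the cutoff — deterministic, though the surviving
count depends on input order, so redundancy counts are conventions, not
reproduction targets); and truncation of the alignment to the non-gap
columns of a chosen reference sequence, which fixes the 1-based residue
numbering used by everything downstream. Pairwise identity is matches over
mutually non-gapped columns; a pair with no such columns is an error, except
inside redundancy removal where it is treated as identity 0 (such a pair
cannot be redundant).

## Paralog separation

Name-based database retrieval often mixes two similar-length sub-families
under different evolutionary constraints. The split works on the distance
matrix `d = 1 - identity`, locally normalized by dividing each entry by the
*product* of its two rows' scales, where a row's scale is the mean of its
`floor(n/2)` smallest off-diagonal distances. Normalization damps
oscillations in cluster variance when the families have unequal internal
diversity. The two-way partition is spectral: Gaussian affinity
`exp(-(d'/sigma)^2)`, symmetric normalized Laplacian, Fiedler-vector
embedding, seeded 2-means refinement.

Numerical choice: the kernel bandwidth `sigma` is the median off-diagonal
normalized distance. Locally normalized distances sit well above 1 (each
entry is divided by a product of two scales that are each < 1), so a unit
bandwidth would underflow all affinities to the numerical floor and the
partition would collapse; the median bandwidth makes the kernel scale-free
in `d'`. A floor of 1e-12 is added to all affinities so the graph is never
numerically disconnected. Cluster labels are arbitrary; identity is assigned
through a user-supplied anchor sequence (e.g. a biochemically annotated
family member).

## Coupling scores

For an eligible column pair (both columns < 10% gapped on the full
alignment):

* joint entropy `H_cd` (log base 20, range [0, 2]) over the rows where both
  columns are non-gap (complete-pair deletion, which maximizes the rows
  available to each pair);
* `MI_cd = H_c + H_d - H_cd`, with the marginals recomputed on the same
  mutually non-gapped subset so independence gives exactly 0;
* `NMI_cd = MI_cd / H_cd` in [0, 1], removing the entropy dependence of raw
  MI; `0/0` (two conserved columns) is defined as 0;
* a bivariate Z-score against column-specific backgrounds: column `i` gets
  the mean `mu_i` and variance `var_i` of its NMI values over all partners,
  a pair gets `mu_ij = (mu_i + mu_j)/2` and `var_ij = (var_i + var_j)/4`
  (modeling the pair score as the mean of two independent column-level
  normals), and `Z_ij = (NMI_ij - mu_ij)/sqrt(var_ij)`.

The combination rule is isolated behind one parameter: `combine="mean"`
(default, above) or `combine="precision"` (precision-weighted product of the
two normals). On alignments of independent uniform columns the default
standardization centers at 0 with variance near 2, not 1 — the /4 rule
halves the per-pair variance estimate relative to the empirical NMI spread.
This global scale constant is irrelevant to the pipeline, which only ever
consumes pair *rankings*; the mean-of-normals rule is kept as the default
for its simplicity and symmetry.

Implementation: all-pairs joint counts come from a single one-hot matrix
product (float32 GEMM, cast back to float64 — counts are exact integers, so
the entropy arithmetic is full double precision; memory scales as
`(20 L)^2`). A scalar per-pair path exists as a reference implementation and
the two are tested against each other.

## Split-half consensus resampling

Raw scores are sensitive to which sequences happen to be in the alignment.
Each iteration: draw `subset_size` sequences at random (default 300), halve
into two disjoint splits (default 150 each), score each split, take each
split's top-k couplings, and record the couplings present in *both* top-k
lists (the consensus). Over `iterations` rounds (default 100) each pair
accumulates a 0–100 count; only pairs at 100% feed the network analysis.
`k` defaults to one less than the number of eligible positions (the natural
generalization of 462 picks from 463 positions).

Conventions fixed here and logged because no external convention exists:

* the eligible-position universe (hence the pair universe and `k`) is fixed
  once on the full alignment and reused for every split, so all splits rank
  the same pairs — split-local gap fluctuations cannot eject a position;
* top-k boundary ties break by ascending (i, j) position order;
* a column whose NMI background variance is zero within a split (e.g.
  conserved within that split) is dropped from that split's ranking with a
  warning;
* one master seed; per-iteration generators are spawned from it by counter,
  so any iteration can be replayed. Sampling is by row index after a seeded
  shuffle, so subset identities depend only on seed and row order.

Couplings are labeled with 1-based positions, which coincide with reference
residue numbers on a reference-truncated alignment.

## Residue networks

The 100%-reproducible couplings define a simple graph; its maximal cliques
(Bron–Kerbosch with pivoting, via networkx; enumeration is cross-checked
against brute-force subset search in the tests) are the coevolving residue
networks, reported at size >= 2, largest first with lexicographic
tie-breaks. The "top cliques" are the `n_top` largest (default 5) and their
member union; "neighbors" of a position are its co-members across the
selected cliques. A node-count guard protects against the exponential worst
case. Joint-identity histograms for a position pair drop rows gapped in
either column, remove cells below a 5% frequency floor, then renormalize —
filter before normalization, so a dominant cell can reach exactly 1.0.

## Structural context

Residue–residue distances are closest-atom distances over heavy atoms
(altloc blank/'A' only; hydrogens excluded for comparability with crystal
structures). Contact accuracy of a coupling set is the fraction of couplings
within a cutoff (default 8 Å); couplings with unresolved residues are
skipped with a warning, and accuracy over zero resolvable pairs is an error,
not 0. Domain assignment is an interval lookup over the four-domain
architecture (1–154, 155–256, 257–368, 369–463); the published boundaries
overlap at 154/256/368 and those residues are assigned to the lower-numbered
domain. Disagreements between the reference sequence and the structure's
residue identities are reported explicitly, never skipped silently.

## Kinetics and mutant-cycle energetics

Initial rates fit `v = kcat E0 S / (Km + S)` by bounded nonlinear least
squares (at least 4 distinct substrate concentrations required; standard
errors from the fit covariance). Energetics use

    ddG = -R T ln(spec_mut / spec_wt),   spec = kcat/Km,
    coupling = ddG_XY - ddG_X - ddG_Y,

with R = 1.9872e-3 kcal/mol/K and T = 298.15 K by default (assays at 25 °C);
ddG is positive for an impaired mutant and the coupling is zero for
multiplicatively additive mutations. The sign convention is validated in the
tests against the published cycle values. Published kcat/Km values are
carried explicitly in the bundled reference table because they were rounded
independently of kcat and Km (one published row disagrees with kcat/Km of
its own rounded kcat and Km by ~9%); uncertainty propagation is first-order
in the four specificity ratios and is reported, not asserted.

## Synthetic data: what it emulates, what it does not

`generate_msa` samples rows independently (a star tree): background columns
draw iid from a uniform (or supplied) residue profile, conserved columns are
constant, and each planted coupled group draws one joint state per row, each
member column emitting its state's residue with probability `coupling`
(1 = deterministic covariation) and a background residue otherwise — so all
within-group pairs covary and the planted groups are clique-like by
construction. Gaps are iid per cell (default 2%, typical of a
length-filtered family core). `generate_paralog_mixture` derives two family
consensuses differing at a chosen fraction of columns (default mixture:
~50% divergence, ~0.08 per-cell within-family mutation, giving ~85%
within-family identity). `generate_kinetic_data` uses the wild-type-like
defaults kcat = 6.96 s⁻¹, Km = 28 µM, substrate grid 10–800 µM, 5%
multiplicative noise truncated at -90%, triplicate assays.

What passing tests show: the pipeline recovers planted clique structure
exactly (group sizes 3/5/6, 200 sequences x 100 columns, subset 150 — a
scaled version of the study-size 300/150 protocol chosen to fit the
generated family size — across 20 seeds), never promotes independent
background pairs to 100% reproducibility, and separates planted paralog
mixtures perfectly at twofold distance separation. What they do not show:
robustness to phylogenetic correlation between rows (no tree is simulated),
to alignment error, or to the weaker, noisier couplings of real families —
on real data the 100% reproducibility cutoff trades recall for precision by
design.

## Known limitations

* The all-pairs score matrix is dense; ~500 eligible columns need ~1 GB
  transiently. Chunking would lift this but is not implemented.
* Maximal-clique enumeration is exponential in the worst case; the guard
  refuses huge graphs rather than attempting them.
* The redundancy filter is order-dependent by design (deterministic, but a
  different input order gives a different surviving set).
* Reproducibility percentages are themselves stochastic in the master seed;
  network-scale summaries (coupling counts, clique counts) on real data
  should be read with that reseeding variability in mind.
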