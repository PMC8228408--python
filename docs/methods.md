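# Methods

## The model

RNA molecules do not appear in evolution fully formed: they accrete
substructures — stems, loops, bulges, joints — over time. Given a rooted
tree whose leaves are the substructures of one molecule, the branching
order is a chronology: substructures branching near the root are older.
This package quantifies two consequences of that history:

1. **Step-matrices of character change.** Substructure lengths, coded as
   ordered multistate characters, are traced along rooted trees under
   maximum parsimony; the aggregated unambiguous ancestral→descendant
   changes form a matrix of transformation frequencies (the data behind
   bubble charts). Under gradual evolution most changes are single steps,
   producing a double-diagonal pattern.
2. **The Menzerath–Altmann law.** The mean length y of the x-th accreted
   substructure shrinks with x. The general law y(x) = A·x^b·e^(−cx) has
   two classical special cases: c = 0 (power law, used for protein
   domains) and b = 0 (pure exponential, y = A·e^(−cx), used here for
   accretion series). A is the length of the first construct; c measures
   the push towards economy per added part. Since the accretion rank x is
   approximately linear in relative age t, the b = 0 form is equivalent to
   exponential decay N(t) = N₀e^(−λt) with N₀ = A, λ = c·k (k parts per
   unit relative time).

## Character coding

Lengths are coded into the 36-symbol alphabet `0–9A–Z` (0–35). `0` is
reserved for *absence*, so a present substructure always codes ≥ 1.
Characters are ordered (Wagner): the state graph is the linear chain, and
a change i→j costs |i − j|. Lengths above 35 clip to `Z` with a warning —
the alphabet is bounded and overflow is rare for real substructures.

Stems are maximal runs of consecutively stacked pairs; *any* interruption
of stacking — even a 1-nt bulge — terminates a stem, so interrupted
helices contribute several stem characters, mirroring the practice of
coding stems and their interruptions as separate homologs. Stems are
located on the full pair set, so the two crossing helices of a pseudoknot
are both recovered. Unpaired runs are classified by flanking context:
hairpin loop (closed by one stem end), bulge/internal loop (between the
two ends of adjacent stems, depending on whether the opposite strand also
has unpaired residues), multiloop segment (junction of ≥ 3 stems), joint
(between stems on the exterior), and 5′/3′ free ends. A fully unpaired
molecule degenerates to a single 5′ free end.

G:U wobble pairs count toward stem length (helical regions include
non-canonical pairs). Because wobble pairs are also coded separately in
some analyses, `decompose(gu_separate=True)` additionally emits a
`gu_pairs` character per stem holding the wobble count; its class defaults
to helical and is configurable in `build_character_matrix`. The default is
off, since the topology-only fixtures carry no sequence.

Homology across molecules is an explicit label map
`(molecule, substructure index) → label`; `positional_homology` supplies
the kind-and-order labeling adequate for template-sharing molecules.
Curated maps should be used for real alignments, where homology is
assessed from the relative position of substructures.

## Parsimony and unambiguous changes

`sankoff_cost` is the standard Sankoff dynamic program over rooted trees,
summing child minima at polytomies (no arbitrary binarization). For the
|i − j| metric, every most-parsimonious reconstruction (MPR) keeps internal
states within the observed state range (shifting an out-of-range block of
nodes toward the range strictly lowers cost), so the DP restricts to that
range; custom cost functions fall back to the full 0–35 range.

A branch change is *unambiguous* when every MPR assigns the same parent
state i and child state j with i ≠ j — the intersection-over-MPRs
criterion. This is decided exactly by enumerating all MPRs after counting
them by dynamic programming; when the count exceeds `mpr_limit` (default
100 000) the implementation falls back to requiring singleton final sets
at both branch ends, which is a subset of the exact criterion (documented
lower bound) and warns. Multi-step changes (e.g., 3→0) are recorded as a
single off-diagonal cell, not decomposed into unit steps. Missing leaf
states are treated as state 0 (absent) by default; `missing="error"`
raises instead.

Step-matrix export always writes both raw counts and the per-character
average frequency, covering both plausible normalizations of "average
frequency of change".

## Node-distance ages

depth(leaf) = number of internal nodes on the root-to-leaf path (root
counted — the raw convention is exported via `leaf_depths` for debugging);
nd = (depth − min depth)/(max depth − min depth). The shallowest leaf
(origin) anchors 0, the deepest (present molecule) anchors 1; sister
leaves tie. Branch lengths are deliberately ignored. Equal-depth trees
(e.g., fully balanced) degenerate to all-zero ages with a warning.

## Statistics

- OLS of mean length on nd (ages in [0, 1]; slopes are in nucleotides or
  base pairs per unit relative time).
- Pearson r with the two-sided t test (df = n − 2).
- Spearman ρ with average ranks for ties; the two-tailed p-value is an
  exact permutation value (all n! orderings) for n ≤ 9 and the t
  approximation above.
- Normality screen of the lengths: one-sample KS against a normal with
  plug-in mean/sd, plus a Lilliefors-corrected p, because the plug-in KS
  p-value is conservative when parameters are estimated.
- Mean lengths exclude absences (state `0`), so a substructure's size is
  averaged only over molecules that have it; all-absent characters drop
  with a warning.

Accretion rank x is the cumulative count of substructures with age ≤ nd;
ties in nd share x. Only present substructures contribute x increments.

## MA fitting

Fits are log-linear OLS (ln y = ln A + b·ln x − c·x), matching the
straight-line procedure standard for these series; a nonlinear
least-squares refit is available (`nonlinear_check=True`) and is reported
only when it moves a parameter by more than 1%. SE(A) is obtained by the
delta method (SE of the log-space intercept × A), so it is on A's scale.
F-statistics use df (k, n − k − 1) with right-tailed p; for the special
form F equals R²(n − 2)/(1 − R²). A perfectly flat series returns c = 0,
F = 0, p = 1 rather than a 0/0. For short series ln x and x are nearly
collinear; the general fit flags condition numbers above 10⁴. Reported
decay exponents for these RNAs span c ≈ 0.012 (rRNA) to 0.490 (tRNA); one
prose source gives 0.460 for tRNA, but the tabulated 0.490 is used as
authoritative throughout.

## Synthetic data: what it does and does not emulate

`gen_accretion_history` builds a fully pectinate (caterpillar) tree —
the shape real trees of substructures approximate — and lengths
y(x) = A·e^(−cx)·e^(ε), ε ~ N(0, noise_sd). Defaults are n_sub = 10,
A = 13.56, c = 0.490, noise_sd = 0.2: the sample size and fitted
parameters of the strongest observed decay regime (tRNA-like), with noise
chosen to reproduce the residual scatter typical of the published
log-linear fits (R² ≈ 0.8 at these settings). Multiplicative noise keeps
every length strictly positive, so no truncation is applied — at these
parameters the noiseless curve itself drops below 1 for x ≥ 6, and any
floor would both bias parameter recovery and break the exact zero-noise
round trip; non-integer "lengths" are unproblematic because the observable
is a mean over taxa.

`simulate_ordered_character` walks ±1 steps down each branch
(Poisson(step_rate) steps, equal up/down probability, reflecting at 0 and
35 since the alphabet is bounded). `gen_molecule_set` renders molecules on
a four-armed template (stems of 7/5/5/4 bp with hairpins, 2-nt joints,
free ends — tRNA-like proportions) with ±1 length jitter and a variable
last arm absent with probability 0.1; it verifies its own decomposition
and returns the exact expected-length table, making it a self-checking
end-to-end fixture.

What the generators do **not** emulate: sequence evolution (no
substitutions or indels), thermodynamic folding, correlated evolution
among characters, tree-shape heterogeneity of real molecule trees, and
non-exponential length distributions. Passing tests therefore demonstrate
the correctness and calibration of the machinery under the stated
generative model, not the empirical adequacy of that model for any
particular RNA family — the latter requires the published data matrices
and rooted trees, which are consumed through the same interfaces (NEXUS
matrices, Newick/NEXUS trees, TSV chronologies).

## Numerical choices and sizes

- Deterministic traversal (preorder, children in input order) makes all
  outputs bit-reproducible; each generator draws from a single
  numpy Generator seeded by the config.
- The acceptance script uses 200 random parsimony instances (≤ 6 leaves,
  states ≤ 5 — small enough for exhaustive enumeration), 500 noisy MA
  replicates at n = 10, and one 100-leaf / 50-character simulation; these
  sizes give stable estimates while the whole script runs in seconds.
- Exact Spearman permutation p is limited to n ≤ 9 (9! ≈ 3.6×10⁵
  orderings); beyond that the t approximation is standard and accurate.

## Known limitations

- The unambiguity fallback above `mpr_limit` undercounts changes (by
  design, with a warning); analyses of very flat characters on very large
  polytomous trees may want a higher limit.
- Loop classification around pseudoknots uses the innermost enclosing pair
  on the full pair set; deeply nested crossing systems beyond the
  ten-alphabet dot-bracket writer are not renderable (parsing from CT or
  bpseq still works).
- The significance-entry counts of published bubble charts depend on an
  unstated threshold and are not reproduced.
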