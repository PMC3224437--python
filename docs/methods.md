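# Methods

## Kinetic reaction-system simulation

A reaction network is a stoichiometry matrix S ∈ ℤ^(m×r) (educts negative,
products positive) with an educt-only matrix Sᵉ, per-reaction rate laws and
nominal kinetic constants.  Mass-action rates are v_j = k_j ∏_i x_i^(−sᵉ_ij);
enzymatic reactions use the reversible Michaelis–Menten form

    v = (Vmax⁺/KMs·[S] − Vmax⁻/KMp·[P]) / (1 + [S]/KMs + [P]/KMp),

optionally extended to mixed inhibition with denominator
1 + [I]/K_i + ([S]/KMs + [P]/KMp)(1 + [I]/K_ii); K_i = K_ii is the
non-competitive case used by the bundled fixtures.  The system evolves as
dx/dt = S·v(x, k).

**Parameter variability.**  Population-like heterogeneity of enzyme activity
is modeled as independent multiplicative log-normal noise on every kinetic
constant: k = k_nominal·exp(ε), ε ~ N(0, σ²), with σ = 0.2 by default.  With
μ = 0 the nominal value is the *median* of the perturbed constant; a
`lognormal_mode="mean"` switch uses μ = −σ²/2 so the nominal value is the
mean instead.  The choice is immaterial for the correlation structure of log
steady states in first-order systems (a multiplicative location only shifts
log concentrations).  σ may be set per reaction or per constant; by default
all constants of an enzymatic reaction (both Vmax and both KM values, plus
inhibition constants) fluctuate.

**Steady states.**  Systems containing only zeroth- and first-order
mass-action reactions have linear flux balance A x + b = 0 and are solved
exactly; a singular system or a non-positive solution raises an error.
Anything else is integrated (LSODA) until ‖dx/dt‖ < tol·(1 + ‖x‖) with
tol = 10⁻⁹, doubling the time horizon (initially 100) up to 14 times, and
the endpoint is polished by a Newton root solve of the flux balance.  During
ensemble simulation consecutive draws warm-start from the previous steady
state and try the Newton solve first, verified against the same residual
tolerance, with integration as fallback — monostability of all bundled
fixtures is verified separately by parameter and initial-value sampling
(`verify_monostability`, log-uniform initial states over two decades).

**Fixture parameterization.**  All exchange (input/output) reactions use
rate 1.  Three parameter choices in the motif library are deliberate:

- Reversible *intermediate* reactions in the reversible-chain and branched
  motifs run at rate 10, an order of magnitude above the exchange fluxes.
  These motifs represent metabolites coupled by fast near-equilibrium
  reactions; in a linearized analysis the indirect partial correlation of a
  reversible chain vanishes only in the limit where back-reaction flux
  dominates the external input, so a slow-reversible parameterization would
  leave a genuine (if small) indirect partial correlation.
- The cofactor motif gives its hexose-phosphate intermediates exchange
  reactions (biologically: pentose-phosphate, glycogen and hexosamine
  branches) and supplies ATP at rate 10.  Without intermediate exchange,
  steady-state flux conservation ties the terminal metabolite rigidly to the
  pathway input constant, an artifactual direct dependence; without excess
  ATP supply a fraction of parameter draws has no positive steady state at
  all (cofactor demand exceeding supply).
- Enzymatic chains receive input flux 0.5 (0.25 under end-product
  inhibition) against Vmax⁺ = 2: a saturating enzyme cannot carry an input
  flux above its maximal rate, so the margin keeps every log-normal draw
  feasible.

## GGM estimation

Pearson correlations P use the standard product-moment formula; partial
correlations come from Ω = P⁻¹ via a Cholesky factorization with a
condition-number guard of 10¹² (requiring n > m in practice).  The diagonal
of Z is set to +1 by convention (the formula itself yields −1) and excluded
from all statistics.  Two-sided Fisher-z p-values use q = m − 2 conditioned
variables for the full GGM, q = 0 for Pearson, and q = 1..3 for low-order
variants.  "Significantly positive" always means p ≤ α̃ and ζ > 0.

Low-order partial correlations of order q are computed exactly by inverting
the (q+2)×(q+2) submatrix of P for each pair and conditioning subset
(algebraically identical to the classical recursion).  An edge is retained
only when the order-q partial correlation is significant for *every*
conditioning subset; the reported value is the minimum-magnitude one.  This
all-subsets rule is the standard conservative convention for low-order
graphical model estimation.

For a 151-metabolite panel at α = 0.01 the Bonferroni level over 11325 pairs
is α̃ = 8.83·10⁻⁷; inverting the Fisher transform at n = 1020 gives an
absolute partial-correlation cutoff of 0.1653.  (A cohort analysis of this
design is sometimes quoted with a cutoff of 0.1619; direct inversion of the
printed formula does not reproduce that figure, and this implementation
follows the formula.)

Stability diagnostics resample the data (bootstrap with replacement at full
n; subsampling without replacement at chosen sizes, 100 repetitions by
default) and report mean ± sd of the mean absolute off-diagonal difference
between resampled and original partial correlations, skipping and counting
ill-conditioned replicates.

## Graphs, modularity and triads

The GGM graph has an edge for every significant (by default significantly
positive) partial correlation.  For a partition into metabolite classes V_i,
with A(V′,V″) the sum of adjacency entries between two node sets (so a
within-class edge counts twice),

    R_ij = A(V_i, V_j)/A(V_i, V)        (relative out-degree, row-stochastic)
    Q = Σ_i [A(V_i,V_i)/A(V,V) − (A(V_i,V)/A(V,V))²]   (modularity)

Both accept weighted adjacency.  Significance of Q is assessed against
degree-preserving double-edge-swap randomizations (5·e accepted swaps per
null network, invalid swaps redrawn; the degree multiset is asserted after
every call).  Edge attributes travel with the first-endpoint stub during a
swap, which doubles as the weighted, neighbor-preserving rewiring variant —
the literature describes several closely related weighted schemes; this one
is an interpretation and documented as such.  Singleton classes carry no
partition information and are dropped (with a warning) from class-based
statistics.

`anneal_partition` maximizes Q by simulated annealing over single-node
moves with geometric cooling (T: 0.25 → 10⁻³, factor 0.9, 20·|V| moves per
temperature); the best-seen partition is returned, so the result never
scores below the initial one.  The schedule is an implementation choice
tuned only for the small graphs in scope.

A *triad* is an unordered metabolite triple with exactly two significantly
positive and one significantly negative partial correlation; the negative
pair is flagged as the predicted distance-2 pair, since two metabolites that
both correlate strongly with a shared neighbor but not with each other
acquire a negative partial correlation.

## Fatty-acid pathway model and distances

Measured lipids carry brutto annotations only (total side-chain carbons and
double bonds).  The bundled model (`src/ggmetab/data/fatty_acid_model.yaml`,
plain YAML, user-editable) contains the de novo saturated series C2:0–C26:0
with SCD desaturations to C16:1/C18:1 and the monounsaturated elongation
series, plus the ω-3 and ω-6 polyunsaturated pathways; double-bond positions
are omitted, and isobaric species from different pathways (C18:3, C20:4,
C22:5, C24:5) are merged into single nodes carrying both pathway tags.  The
Δ12/Δ15 desaturations absent in humans are deliberately missing, so the
polyunsaturated component is disconnected from the de novo series (formal
distance ∞).  Acyl-carnitines live on a separate β-oxidation model: linear
chains of C2 removal steps per double-bond count.

The distance between two metabolites is the minimum over all side-chain
decompositions into model fatty acids and (for two-residue lipids) over both
residue matchings of the summed per-residue shortest-path lengths.  Each
residue evolves independently, so steps on different residues add; whether a
single biochemical "step" could act on both residues at once is not
observable at brutto resolution, and the summed-steps convention is the
generalization consistent with taking the shortest possible route.  Pairs
across projection domains (carnitine vs biosynthesis lipid), lipids with
differing residue counts, modified carnitines (OH/DC/M-DC) and non-lipid
classes are *not applicable* (NaN), distinct from *unconnected* (∞).
Distances ignore reaction direction and are symmetric.

## Evaluation

Applicable pairs are stratified by pathway distance (1, 2, …, ∞).  A pair is
predicted positive when its partial correlation is significantly positive
(an `"absolute"` rule using |ζ| is available); condition positive is
distance exactly 1.  Reported are TP/FP/TN/FN, sensitivity TP/(TP+FN),
specificity TN/(TN+FP), their harmonic mean F1 (note: harmonic mean of
sensitivity and specificity, not the precision-recall F1), and the
two-sided Wilcoxon rank-sum p comparing ζ of direct vs indirect pairs.
Rates with zero denominators are undefined (None), never zero.  Significant
*negative* partial correlations at distance 2 count as negative predictions;
their enrichment is visible through the triad detector instead.

## Synthetic panels

`generate_synthetic_panel` emulates the shape of a targeted serum panel:
154 metabolites in 8 classes (14 amino acids, 1 hexose, 38 acyl-carnitines,
36 diacyl-PCs, 38 acyl-alkyl-PCs, 13 lyso-PCs, 9 sphingomyelins, 5
hydroxy-sphingomyelins; published class counts for panels of this design
add up to 154 even where m = 151 is quoted, and the discrepancy is carried
as-is — all pair-count arithmetic derives from actual column counts).  In
`block_cov` mode log concentrations are multivariate normal with a
block-diagonal precision matrix, each class a chain with adjacent partial
correlations of configurable strength (default 0.3; |strength| < 0.5 keeps
the chain precision positive definite); per-metabolite baselines are drawn
once.  In `simulator` mode each class is an independently simulated
reversible first-order reaction chain with exchange reactions.  Both return
the exact generating adjacency for evaluation.

What the generator does *not* emulate: cross-class dependence (shared
fatty-acid pools), heavy-tailed or skewed measurement error, batch effects
and missingness.  Passing recovery tests on these panels therefore
demonstrates correctness of the estimator under its own model assumptions,
not performance on real cohort data.

## Problem sizes and numerical choices

Default validation runs use n = 1000 samples and σ = 0.2 for kinetic
ensembles, n = 5000 for planted-precision recovery (m = 10, 20 seeds), and
1000 rewiring nulls for modularity z-scores; these sizes give stable
qualitative results while keeping a full run in the order of seconds.
Concentrations are natural-logged (the base only rescales and leaves
correlations unchanged).  Missing values are rejected, never imputed.  The
condition-number guard (10¹²) and the integration tolerance (10⁻⁹ relative
derivative norm) are configurable.

## Known limitations

- Purely irreversible reaction chains without exchange fluxes are not
  identifiable by any correlation-based method; the irreversible-chain motif
  documents this failure mode rather than working around it.
- Bimolecular and antagonistic mechanisms (isomerization plus
  co-consumption) can cancel correlations and weaken edges.
- n ≤ m panels need shrinkage or low-order estimation; only the low-order
  route is implemented here, and its all-subsets scan is exponential in q
  (practical for q ≤ 3 on small panels).
- The bundled fatty-acid model is a compact curation, not a complete
  reaction database; it is a plain text file precisely so users can replace
  it.
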