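# Methods

This note documents the models and procedures the package implements,
the tunable parameters with their defaults, what the synthetic fixtures
do and do not emulate, and the numerical choices made where the design
was genuinely open.

## Gene categorization

Average log2 expression of a gene population across tissues is bimodal: a
low-expression subpopulation (LES; genes essentially off) superposed with
a high-expression subpopulation (HES).  `fit_bimodal` fits a
two-component Gaussian mixture by maximum likelihood
(sklearn `GaussianMixture`, `n_init=3`, seeded) to per-gene mean
log2(TPM + 0.1); the 0.1 pseudocount keeps zero TPM finite.  Thresholds
(log2-TPM units):

| threshold | value | meaning |
|---|---|---|
| high | μ_HES | above: highly expressed |
| low | μ_LES + σ_LES | below: lowly expressed |
| rare | μ_LES | below: rarely expressed |
| τ_rel | μ_HES − σ_HES | gate for the relative pass |

A fit is flagged degenerate when a component carries <1% of mass or the
separation (μ_HES − μ_LES)/(2√(σ_HES σ_LES)) is below 1 (the standard
bimodality condition); thresholds are still produced with the forced
ordering rare < low < high.  Boundary equalities resolve to the lower
category (the high/rare inequalities are strict).

The relative pass re-examines each gene with a moderate entry: tissues
are sorted ascending by TPM and each of the n−1 intervals is tested for a
fold change (on TPM + 0.1) above 4 in the edge interval (first interval
for promotions, last for demotions) or 1.5 elsewhere.  A jump counts only
when its greater value exceeds τ_rel; promotions additionally require the
tissue's own value above τ_rel, demotions below; tissues labelled both
ways revert to moderate; entries fixed by the absolute pass never change.
The pass is monotone: raising one tissue's TPM never lowers that tissue's
category (property-tested).

## Dual-tissue model

`build_dual_tissue` expands a classified single-compartment model into
lumen (L), intestine (I), other tissue (X) and extracellular space (E).
Internal, demand and sink reactions are copied into I and X;
bacterial-degradation-dependent reactions into I only.  Each transport
reaction gets three copies — I↔L (absorption from the lumen), I↔E and
X↔E (exchange between the tissues) — so the intestine can both absorb
food and provision the other tissue.  Exchanges become uptake-only lumen
reactions (capacity inherited from the source bound) and secretion-only E
exchanges; oxygen, water, orthophosphate and protons (configurable) are
freely bidirectional through E.  Metabolite ids carry the compartment in
brackets: `glc[c_I]`, `glc[c_X]`, `glc[l]`, `glc[e]`.

The nutrient policy keeps the diet bacterially dominated with linear
mass couplings on the lumen uptakes (masses in g/mmol from metabolite
annotations): side nutrients jointly ≤ 2% and individually ≤ 0.5% of
bacterial intake by mass, stored metabolites jointly ≤ 1%; the
ATP-maintenance reaction (`RCC0005` by default) is bounded below by 10
flux units in both I and X.  The couplings are explicit inequalities
referencing the bacterial uptake flux — mathematically equivalent to
encoding the caps inside uptake stoichiometries, and easier to audit.
With all caps saturated, bacteria still supply ≥ 1/1.03 ≈ 97% of consumed
mass (tested at ≥ 95%).

## iMAT++

Per-reaction activation thresholds ε come from FVA with bacterial intake
fixed at one unit and each side/storage uptake capped at 1% of it by
mass: ε(r, dir) = min(0.01, capacity/2); blocked directions get ε = 0 and
are never forced.  GPR rules map to effective categories with AND = worst
(a complex is as available as its scarcest subunit) and OR = best (any
isozyme suffices); rare-effective reactions form R_OFF, high-effective
ones R_ON, low-or-rare-effective ones the flux-minimized set.  During
non-intestine integrations, I/L reactions are judged by intestine
expression and only their low/rare outcomes apply.

The MILP (GLPK through optlang; binaries as big-M indicators with
M = 1001, just above the 1000 flux bound) proceeds in frozen stages:

1. maximize Z_fit = Σ z_g + Σ y_off (z_g ≤ 1 credits a high gene once,
   however many of its reactions flow; y_off = 1 blocks a rare-dependent
   reaction); freeze Z_fit = Z_fit,max;
2. minimize Z_low = Σ|v| over the low/rare set; freeze
   Z_low ≤ Z_low,min + δ_low, δ_low = 1e-5;
3. minimize Z_total = Σ|v| (parsimonious step) → PFD; freeze
   Z_total ≤ Z_total,min (1 + 0.05);
4. find latent reaction-directions — zero flux, high-only genes, every
   reactant active (nonzero Σ|coefficient·flux| over its reactions) —
   maximize the count forced ≥ ε, freeze it, re-minimize total flux, and
   repeat until no new latent direction appears (cap: 20 iterations).
   After each pass the total-flux cap is re-frozen at the new minimum
   × 1.05, so later passes inherit a budget consistent with the forced
   reactions.  The final vector is the OFD.

|v| uses the standard forward/reverse split; |v| < 1e-9 counts as zero
flux, metabolite activity uses a 1e-6 floor (above solver feasibility
tolerance).  The solver's first optimum is accepted at every stage — no
lexicographic tie-breaking — because the FVA labelling step downstream
accounts for degeneracy explicitly.  GLPK is deterministic, so identical
inputs give identical OFDs.

## Network labelling

Within the frozen fitting space, each reaction-direction is labelled OFD
(carries > 1e-6 in the OFD), else ALT if its FVA capacity exceeds 1e-6,
else NONE.  The fast variant first runs a small batch of seeded
randomized-objective solves and marks every direction observed active —
a witness proves nonzero capacity, so the screen can only skip solves
whose answer is already known, and labels are identical to exhaustive FVA
(equivalence-tested).  Tissue networks are reported single-tissue (I/L
rows for the intestine, X/E for the rest) with one correction: an I/L
direction labelled ALT for the intestine but NONE in every other tissue's
integration is removed from the intestine network.

The six non-intestine OFDs are combined into E-metabolite demands as the
weighted sum of their X↔E transport fluxes (weights default to equal and
should be set to relative tissue activity, e.g. normalized UMI counts,
when available); the intestine integration then runs with X blocked and
those demands fixed as E-compartment drains.

## Flux potential analysis

All reactions are made forward-only (reversible r → r_f and a
reactant/product-swapped r_r; split bounds keep the source magnitudes
capped at 1000 so the split model is exactly feasibility-equivalent and
re-merging recovers the stoichiometry).  For a target k and tissue T:

FP_k(T) = max v_k subject to S·v = 0, 0 ≤ v ≤ 1000 (lower bounds are
relaxed in this LP), v = 0 outside T's network, and Σ wᵢ vᵢ ≤ a with
wᵢ = cᵢ/(1 + dᵢ)^n; rFP_k(T) = FP_k(T)/FP_k(S) where the super system S
sets every cᵢ = 1.  Defaults: allowance a = 1, distance order n = 1.5.
An optional constant `background_load` is subtracted from the allowance
to represent network remainder outside the modelled system (the chain
fixture uses 0.5, making the closed form (a − 0.5)/Σw exact).

Coefficients: single gene c = max-over-tissues(TPM)/TPM_T; isozymes sum
their TPM profiles before normalizing; complexes take the maximum
(worst) per-protein coefficient; nested rules recurse with OR = min of
child coefficients when profiles cannot be summed.  Gene-less reactions
get c = 1; exchanges and bacterial intake/degradation are exempt (c = 0,
no allowance cost); a tissue with zero TPM where another tissue expresses
the gene is capped at c = 1e4 rather than ∞ to keep the LP
well-conditioned (effectively blocking).  In the dual model, I/L
coefficients always use intestine expression; when the target lies in X,
I↔E transports are exempted so the non-intestinal tissue is not penalized
for the longer supply route; intestine targets block X entirely.

Metabolic distance is the length of the shortest valid path in the
reaction adjacency graph (two reactions adjacent when one produces what
the other consumes), ignoring hub metabolites — by default the 21
highest-degree metabolites of the loaded model, override with an explicit
list (toy fixtures pass their own).  A breadth-first traversal from each
query (its reverse twin removed) fixes first-reached paths; a path
containing both directions of one reversible reaction is invalid, in
which case the *earlier* of the two twin occurrences on the path is
eliminated and the search repeated until a valid path emerges.  This
disambiguation of "the first reaction that creates a loop" was chosen
because it recovers the exhaustive-search shortest valid distance on all
random-network test beds (the alternative, eliminating the later
occurrence, misses ~1%).  Unreachable pairs take the maximum distance
observed in the network; the matrix is finalized symmetric (minimum of
the two directed values) with a zero diagonal.  Neighbor lists are
sorted, so tie-breaking is deterministic across processes.

Metabolite-level potentials target a drain (production) or source
(degradation) of the metabolite: demand/sink preferred, then transports
facing the extracellular compartment, then the rest; among candidates the
first whose super system can carry flux at all is used (a drain into a
compartment with no outlet would make the score vacuous), and a demand or
sink is inserted temporarily when none exists (gene-less, c = 1).  All
other sink/demand/transport movers of the metabolite are blocked to
prevent shortcuts.

## Site calls

A target is tissue-enriched when max rFP ≥ 0.2 and
(top1 − top3)/top1 ≥ 0.5; a secondary site is called when
(top2 − top3)/top2 ≥ 0.5.  These two parameters are exposed
(`SiteCallParams`) and deliberately simple — they encode "biased toward
one or two tissues" as a ratio rule that is scale-invariant and
column-order-invariant.  Reaction-level calls are high-confidence only
with OFD support in the primary or secondary tissue; metabolite-level
calls record OFD status as a flag without requiring it, because the
parsimonious flux step silences drains by design and a zero OFD flux
there carries no evidence.

## Synthetic data

`synth_expression` draws per-gene mean log2 expression from a
two-component Gaussian mixture (defaults μ = (1, 6), σ = (1, 1), equal
weights — a clearly separated LES/HES structure) and adds per-tissue
Gaussian jitter of 0.3 log2 units, small against the 1.5-fold
relative-categorization gate.  It emulates only the marginal bimodality
and mild cross-tissue variation of aggregated expression data — not
scRNA-seq count noise, dropout, or library-size effects — so a green
categorization test establishes threshold recovery and rule correctness,
not robustness to raw single-cell artifacts.

The toy models are stated worlds: `gene_centered` (one high gene with two
parallel substrate-specific reactions plus a latent branch, and a
baseline demand so the 5% parsimony slack is realistic relative to ε),
`shared_gene_shunt` (a bypass gated by a control gene high in two of
seven tissues, its other genes shared with a second pathway),
`fpa_chain` (mass balance forces equal fluxes, giving the FPA closed
form), `isolated_target` (every non-target reaction with nonzero weight
sits behind a hub metabolite, making the high-distance-order limit
rFP → normalized target-gene expression exact — on a chain fixture the
d = 1 neighbors decay only as 2⁻ⁿ and that limit is not reachable at
tight tolerance), and `dual_system` (a miniature worm supporting the full
pipeline).  Fixtures are pure functions of their seed.

## Known limitations

- Distances, coefficients and FPA LPs are computed densely; genome-scale
  models would need the distance matrix cached and the FVA screening
  batch enlarged (both hooks exist) plus a faster MILP backend than GLPK.
- The intestine integration re-uses the flux thresholds computed on the
  unmodified dual model (X-side entries zeroed); thresholds are not
  re-derived under the combined-demand constraints.
- The enrichment rule for site calls is a transparent stand-in for a
  more elaborate statistical test; its parameters are configurable.
- Tissue weights for combining OFDs default to equal activity; supply
  measured relative activities (e.g. UMI fractions) for real data.
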