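# Methods

This note documents the statistical procedures implemented in
`littoral`, the assumptions behind them, the defaults of the synthetic
community generator, and the numerical conventions that matter for
reproducing results.

## Data model

All analyses operate on a **community table**: a taxon × sample matrix
of biomass (mg m⁻³ for plankton, mg m⁻² for benthos; units are
metadata and never converted), optionally paired with an abundance
matrix of identical shape, plus per-sample metadata (habitat, station,
depth stratum, replicate) and a per-taxon registry (higher group,
indicator-guild flags, saprobic valence s_i ∈ [0, 4.5]). Samples are
grouped into disjoint **habitats** — typically an archival reference
data set and two contemporary sites along a disturbance gradient.

Vertical casts are merged by `integrate_strata`, which averages the
samples sharing a station (and habitat) taxon-wise, yielding one
integral water-column sample per station. The operation is idempotent
and linear, so column totals of the integrated table equal group-wise
means of the original column totals.

## Biotope confinement

For taxon *i* and habitat *j*, with n_ij the taxon's pooled biomass in
the habitat, n_i its biomass over all habitats, N_j the habitat's
total biomass and N the grand total,

    F_ij = (n_ij·N − n_i·N_j) / (n_ij·N + n_i·N_j − 2·n_ij·N_j).

F_ij ∈ [−1, +1]: −1 iff the taxon is absent from the habitat, +1 iff
it occurs nowhere else, and 0 exactly on proportional shares
(n_ij/N_j = n_i/N). The denominator equals
n_ij·(N − N_j) + N_j·(n_i − n_ij), hence is strictly positive whenever
n_i > 0 and N_j < N — the index is always defined for a proper habitat
subset. "Totals" are read as summed biomass of all taxa, the only
reading under which Σ_j N_j = N and the ±1 endpoints behave as stated.

Numerically, the two endpoints are algebraically forced, and the
implementation returns them exactly rather than through the product
expression (whose rounding can leave an exclusive taxon at 1 − 2 ulp);
interior values use the formula as printed.

A habitat's **key species** are its *dominant* taxa attaining the
maximum positive F_ij there; exact ties all qualify, and a habitat
whose dominants all have F ≤ 0 has no key species. F values are
computed for every taxon with positive total biomass and filtered to
dominants only at reporting time (reported rounded to 3 decimals).

## Dominance filtering, clustering, ordination

A taxon is dominant when its habitat-mean biomass reaches the
group-specific threshold in at least one habitat: 10 mg m⁻³
(plankton), 10 × 10³ mg m⁻² (benthic macroalgae), 1 mg m⁻² (benthic
microalgae). Retained rows keep their values — including zeros — in
all habitats, because the zeros carry the confinement signal.

The retained taxon × habitat-mean matrix is transformed elementwise by
log₁₀(x + 1) and (a) clustered with Ward linkage on Euclidean
distances between taxon rows, cut into k communities (default k = 3,
labelled a, b, c in order of first appearance; Ward merge heights are
monotone), and (b) ordinated by PCA on the covariance matrix with
habitats as variables. With only a handful of commensurate
log-transformed variables, covariance rather than correlation PCA is
the natural default. Component signs are fixed so each component's
largest-magnitude loading is positive, making runs bit-reproducible.
Explained-variance fractions over all components sum to 1.

## Indicators

* **Shannon H** on biomass proportions, natural log by default (a
  `base` option is exposed); zero entries are skipped. H = 0 for a
  monoculture and ln k for a perfectly even k-taxon community.
* **Saprobity index** S = Σ s_i·h_i / Σ h_i over the indicator species
  present in the habitat. The frequency weight h_i defaults to the
  number of habitat samples in which the indicator occurs (a raw
  occurrence count); any positive weighting can be plugged in as a
  callable. S is invariant to uniform rescaling of the weights and
  bounded by the contributing valences.
* **Saprobic zones**: oligosaprobic 0.50–1.50, β-mesosaprobic
  1.51–2.50, α-mesosaprobic 2.51–3.50, polysaprobic 3.51–4.50. The
  two-decimal interval edges leave gaps such as (1.50, 1.51); interior
  boundaries split these at the midpoint (1.505, 2.505, 3.505) as
  half-open intervals so that every S in [0.50, 4.50] classifies,
  while any S printed to two decimals classifies exactly as the
  printed intervals dictate. Values outside [0.50, 4.50] are
  `out_of_range`.
* **E/O**: count of eutrophic over count of oligotrophic indicator
  species present (presence/absence only). **M/E**: mesosaprobiont
  biomass over endemic biomass in the habitat — values above 1 flag a
  community where tolerant widespread taxa outweigh the endemic
  assemblage. Both carry a raw value plus a compact rendering: r ≥ 1 →
  "round(r):1", r < 1 → "1:round(1/r)", rounding half away from zero;
  degenerate denominators yield explicit sentinels ("M:0", "NA")
  rather than exceptions.

## ABC / k-dominance stress classification

Each k-dominance curve ranks taxa by its own variable in descending
order (stable ties) and accumulates percentages of the total; curves
are scale-invariant, non-decreasing and end at 100 %. The biomass and
abundance curves of a habitat (replicates pooled by summation — one
curve pair per habitat) are compared pointwise over ranks 1..R−1; the
terminal rank, where both curves are 100 %, is vacuous and excluded.
Biomass everywhere ≥ abundance with at least one strict inequality →
**unstressed**; the reverse → **heavily stressed**; anything else —
including exact equality of the curves — **moderately stressed** (the
"curves intersect" case, since neither lies above the other).
Comparisons use a 10⁻⁹ tolerance on the percentage scale so that
algebraically tied curves classify as ties. Crossing ranks (sign
changes of the curve difference) are reported alongside.

## Synthetic community generator

The generator emulates the survey design statistically — no
mechanistic ecology. Defaults of the canned three-habitat scenario
(`scenario_baikal_like`):

| parameter | default | rationale |
|---|---|---|
| taxa / habitats / samples | 45 / 3 / 3 per habitat | survey dimensions (≈ 42–46 phytoplankton taxa, three stations per site) |
| baseline biomass | log-normal, μ_log10 = −0.4, σ_log10 = 0.4 (mg m⁻³) | puts per-habitat totals near 2 × 10² mg m⁻³ and leaves ≈ 15–25 taxa above the 10 mg m⁻³ plankton threshold |
| confinement | round-robin preferred habitats, enrichment e = 20 | three balanced planted blocks with F values in the range reported for real key species |
| exclusivity | taxon t045 exclusive to the impacted habitat, baseline 50 mg m⁻³ | a planted key species that always passes the dominance filter |
| guilds | eutrophic 0.30, oligotrophic 0.15 → E/O ≈ 2:1; mesosaprobiont 0.20 on the impacted block, endemic 0.20 on the reference block | makes M/E flip from ≪ 1 (reference) to ≫ 1 (impacted) |
| valences | indicator fraction 0.8; Normal(1.6, 0.3) clipped to [0, 4.5] | oligosaprobic/β-mesosaprobic boundary region, where the survey's S values sit |
| noise | multiplicative log-normal, sd 0.3 (natural log) | keeps biomass positive and reproduces ecological skew; additive Gaussian would allow negatives |
| body mass | mass_t = exp(0.6·(1 − κ)·z_t), z = standardised log baseline | κ = 0 unstressed, κ = 1 curves coincide (moderate), κ = 2 heavy. The amplitude 0.6 is deliberately below the log-baseline spread (≈ 0.92 nats) so the coupling damps rather than inverts the abundance ordering — above the spread, κ = 0 communities paradoxically cross |

Abundance is biomass / body-mass, so the whole ABC stress axis is
controlled by the single κ parameter. All randomness flows through one
`numpy.random.Generator`; identical (scenario, seed) pairs give
identical tables, registries and ground-truth records.

What the generator does **not** emulate: species interactions,
zero-inflated detection, temporal autocorrelation, within-habitat
environmental gradients, and taxonomic correlation of guild
membership. Passing recovery tests therefore demonstrate that the
pipeline recovers the structure it assumes, not that real communities
satisfy those assumptions.

## Numerical conventions

* CSV floats are written with shortest round-tripping repr and parsed
  with pandas' `round_trip` parser, so write → read preserves values
  bit-for-bit (the default fast parser does not).
* Long-form tables treat absent (taxon, sample) pairs as zeros
  (absence); duplicated pairs are an error naming the pair.
* SE of the habitat mean = sample standard deviation (ddof = 1)/√n,
  reported as missing for n = 1.
* Ward clustering on a matrix of identical rows is rejected for k > 1
  (zero distances); k = 1 is valid.
* Pipeline outputs are deterministic: no timestamps, sorted manifest
  keys, fixed PCA sign convention — identical configs give
  byte-identical files.

## Problem sizes used in the checks

Recovery experiments run the canned scenario at 45 taxa × 9 samples:
20 seeds for key-species and cluster recovery, 200 seeds for valence
recovery; the ABC κ gradient uses 20-taxon communities at 20 seeds per
κ. These sizes make each planted effect comfortably detectable while
keeping the whole suite fast to iterate on.

## Known limitations

* Saprobic valences and guild memberships must come from authoritative
  published lists; the bundled dominant-taxon registry carries
  placeholder valences flagged as non-authoritative and is suitable
  only for smoke tests.
* F_ij carries no significance test; it is a descriptive fidelity
  index.
* The zone classifier follows the two-decimal printed convention;
  alternative gap conventions would reclassify only values inside the
  0.005-wide midpoint bands.
* Whether microalgal "flagellates" coincide exactly with the
  mesosaprobiont guild is a registry decision, not a package rule: the
  M/E numerator is whatever the registry flags as mesosaprobiont.
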