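# Methods

## Data model and counting unit

All statistics are built on one primitive, the *citation*: the triple
(informant, species, disease). An informant naming the same species for two
diseases contributes two citations; exact duplicate triples are collapsed
at load time (the collapse count is logged). This single counting unit
makes the four indices mutually consistent: `U_is` (the per-informant use
count entering the use value) is the number of distinct diseases informant
*i* cites species *s* for, so `Σ_i U_is = Nr` and `UV = Nr / ns` exactly —
the package verifies the two computation routes against each other in its
tests. `Nuc`, the citation count of a disease, counts (informant, species)
citations symmetrically with `Nr`; `Ni` and `Nti` in the therapeutic
potential count *distinct informants*, following the definitional wording
of those quantities ("informants who mentioned").

The roster size `ns` includes informants with zero reports: it is the size
of the interviewed population, not of the citing subset. Per-informant
knowledge counts (the basis of all group comparisons) are distinct species
and distinct diseases cited, zero for silent informants.

Labels are canonicalized (accent-fold, case-fold, whitespace collapse)
before any matching, so `Curing healer` and `curing_healer` are one level.
Closed vocabularies (gender, age class, education, experience, therapist
category, marital status, organ, preparation, administration, biological
form, habitat) reject unknown labels at load; residence and disease are
open by default and can be closed via configuration. Missing optional
attributes are empty strings on disk and a distinct missing marker in
memory.

## Undefined values and edge cases

- `IAR` and `ICF` divide by `Nr − 1` / `Nuc − 1` and are reported as
  missing below two citations, rather than forced to 0 or 1.
- `STP` requires `Ni ≥ 1`; the selection retains pairs with `Ni ≥ 2`
  (singleton citations carry no consensus and are discarded). No further
  STP cut-off is applied.
- `RSI` has denominator `a + b + c − d`. It is zero only when either no
  species exists anywhere (undefined; an error) or the two communities are
  identical with full indication agreement (`a = b = 0`, `d = c`), which
  is reported as the limit value 100%. Note that the formula itself exceeds
  100% whenever `2d > a + b + c`; real paired surveys operate far below
  that regime (shared same-disease species are a minority of the union),
  and the bound `RSI ≤ 100` is asserted in tests only under
  `2d ≤ a + b + c`.
- Percent tables round half-up to 1 decimal at presentation; internal
  values keep full precision. Rounded share columns therefore sum to
  100 ± 0.1.

## Group statistics

Rank tests use the tie-corrected asymptotic normal approximation for two
groups (no continuity correction, so identical groups give p = 1 exactly)
and Kruskal-Wallis with tie correction for three or more. The rate model is
a plain Poisson GLM with log link, treatment coding, intercept and no
offset; dispersion is fixed at 1, with the Pearson dispersion statistic
reported for diagnostics only (no quasi-Poisson or negative-binomial
refit — overdispersed data will show dispersion well above 1 and wider
true uncertainty than the Wald intervals suggest). Reference levels are
fixed to the field convention used throughout the package: male,
rural residence, traditional health practitioner; other factors default to
their most frequent level. Rate ratios are exponentiated coefficients to
machine precision. The significance threshold is 0.05 with no
multiple-testing correction — a deliberate mirror of common practice in
descriptive ethnobotany, and a caveat for users running many factors.

## Synthetic survey generator

The generator defines the study conditions the package is tested under:

- **Roster**: informant attributes drawn independently per factor from the
  configured margins (defaults: 42.6/57.4% female/male, 81.9% traditional
  health practitioners, 43.1/20.7/36.2% across the three residence
  communities, and so on).
- **Flora**: species are apportioned to families deterministically
  (largest-remainder) from configured counts — 227 species, 192 genera, 79
  families by default, the leading family holding 27 species and 21 genera.
  The unnamed small-family tail is stood in for by 37 synthetic 2-species
  families preserving the pooled tail (74 species, 67 genera). Biological
  form and habitat are sampled per species (36.4% herb, 45.0% anthropized
  by default).
- **Citations**: each informant's number of cited species is Poisson with
  mean `base_rate × Π multipliers` over their group levels; planted
  multipliers default to 0.75 (female), 1.53 / 1.75 (the two urban
  communities vs rural) and 0.44 / 1.47 (herbalist / curing healer vs
  traditional health practitioner). `base_rate` is resolved so the marginal
  mean is 4.2 species per informant. Because each citation is a distinct
  species (one disease per cited species), the species count is exactly
  Poisson and rate-ratio recovery is well-specified. A negative-binomial
  dispersion knob exists for robustness experiments only.
- **Species salience**: citation weights follow `rank^-0.55` over a random
  species permutation, giving a long-tailed use-value profile whose top
  species collects roughly 3% of all citations (UV ≈ 0.15 at the default
  size) while the median species sits near 0.01.
- **Community structure**: each residence community draws on an
  overlapping subset of the species pool (each species available with
  probability 0.8 per community) and assigns each species its own small
  indication set, drawn independently from a Zipf-weighted disease pool
  (103 diseases, exponent 1.1). Cross-community agreement on an indication
  then arises mostly through popular diseases, which keeps pairwise RSI in
  the realistic 5–10% range.
- **Per-report attributes**: organ, preparation and administration are
  sampled i.i.d. per report (39.4% leaf, 41.7% decoction, 71.7% oral by
  default, with the remaining mass spread over the other levels in
  plausible proportions).

`generate_paired_communities` realises an exact planted overlap
`(a, b, c, d)`: every planted species is forced to receive at least one
citation in its community, each of the `d` designated common species is
cited for one identical disease on both sides, and the two sides' other
indication pools are disjoint, so no random extra citation can create an
accidental shared indication. It requires `n_species ≥ a + b + c`.

What the generator does **not** emulate: snowball-recruitment network
structure (informants are i.i.d.), correlation between informant attributes
(e.g. age and experience are independent here), knowledge secrecy, recipe
composition (multi-species remedies), and the empirical concentration of
distinct *diseases* per informant (the study population names far fewer
distinct diseases than species; the generator's disease concentration is
milder). Passing tests therefore demonstrate correctness of the statistics
and recovery of planted structure, not that any particular real survey
will show the same index values.

## Determinism and numerics

A fixed seed reproduces every generated dataset byte-for-byte; the pipeline
stamps outputs with a hash of the analysis-relevant configuration plus the
seed, and identical config+seed runs produce identical files. Ranking ties
break by citation count descending, then name ascending; species with
undefined IAR sort last. Rounding is half-up (decimal arithmetic, not
banker's rounding) and applied only at presentation.

## Problem sizes used in the shipped checks

The test suite exercises the oracle equivalence on 200 random
micro-surveys (≤ 10 informants × 10 species × 5 diseases), similarity
recovery on 100 random planted overlaps, and stochastic parameter recovery
on 100 surveys of 2 000 informants each with a 1 000-replicate null
calibration of the rank test — sizes chosen to give stable Monte-Carlo
verdicts at interactive runtimes.
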