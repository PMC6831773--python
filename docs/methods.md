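# Methods

## Buoyant-density model

A nucleic-acid species bands at its equilibrium (buoyant) density ρ in an
isopycnic gradient; diffusion makes the band approximately Gaussian in ρ.
¹³C substitution increases the density of DNA by up to ~0.036 g/ml and of
rRNA by up to ~0.035 g/ml at full labeling, so a taxon that assimilated a
¹³C substrate with atom fraction *a* bands near ρ₀ + a·Δmax. All inference
in this package reduces to estimating each OTU's band center per gradient
and differencing it between isotope treatments.

### Weighted-mean estimator (fully sequenced gradients)

For a gradient whose fractions f have densities ρ_f, the mean BD of OTU o is

    ρ̄_o = Σ_f w_of ρ_f / Σ_f w_of,

where w_of is the OTU's relative abundance *within* fraction f. Within-
fraction normalisation prevents deeply sequenced fractions from dominating
and makes the estimator invariant to per-fraction library size (tested).
The flip side is compositional coupling: a fraction's relative abundances
always sum to one, so fractions containing almost no nucleic acid at all
are dominated by whichever taxon bands nearest. The estimator is therefore
accurate when every collected fraction holds real signal — which is how the
synthetic communities are built (below) and how gradient windows are chosen
in practice.

### Fixed-σ estimator (sparsely sequenced gradients)

RNA-SIP studies often sequence a subset of fractions. Assuming the OTU's
density distribution is normal with σ fixed at the value fitted to the bulk
RNA concentration profile of that gradient, the band center is

    µ_o = argmax_µ Σ_f w_of · log N(ρ_f; µ, σ),

maximised on a density grid (step 1e-4 g/ml) spanning the gradient ± 2σ.
With a quadratic log-density this maximiser coincides with the weighted
mean of the observed fractions up to grid resolution; the grid search is
kept because it is σ-aware at the boundaries, bounded, and deterministic.
The bulk profile is fitted by least squares (`scipy.optimize.curve_fit`);
a fit whose σ exceeds the sampled density span is unidentifiable and falls
back to concentration-weighted moment estimates, flagged on the profile.

### Shifts

Mean BD is computed per gradient, averaged with equal weight across
replicate columns of a treatment × isotope (the design pools replicate
columns without stated weights), and differenced: shift = ρ̄(¹³C) − ρ̄(¹²C).
OTUs absent from all gradients of either isotope get no shift record —
absence is not a shift of zero. A treatment missing an isotope entirely is
a hard error.

## The labeling cascade

Filter 1 retains OTUs with shift > `min_shift` (default 0: any upward
drift passes, matching the intentionally permissive first gate of this
design — roughly half of all null OTUs pass it). Filter 2 keeps an OTU iff
its genus has filter-1 survivors in both the DNA and the RNA assay.

Filter 3 is the significance gate. Per genus and assay, the mean shift of
*all* the genus's shift records in the treatment (any sign) is bootstrapped
(percentile method, default 1000 resamples, 90% CI). Including unshifted
members matters: a genus in which most OTUs did not move should not be
declared labeled on the strength of its lucky tail. A genus is
significantly labeled iff its CI lower bound exceeds zero **in both
assays**; requiring both assays keeps the genus-wise false-call rate near
the product of the per-assay rates (~0.25% rather than ~5%), which is what
makes null experiments come back empty (tested: ≥ 90% of ¹²C-vs-¹²C runs).
Within significant genera, `retain_mode` controls member retention:

* `genus` (default) — all filter-2 members are retained. A genus-level
  gate matches the genus resolution of the CI itself and does not penalise
  homogeneous genera: with any member-level cut at the CI lower bound, a
  fraction Φ(−1.645/√n) of genuinely labeled members (≈ 20–30% for typical
  genus sizes) would fall below the bound by construction, since the CI of
  the mean is narrower than the member spread.
* `above_lower` — members need shift ≥ the CI lower bound (per-OTU
  resolution, at the recall cost just described).
* `above_upper` — members need shift > the CI upper bound (a conservative
  outlier-only reading).

Single-OTU genera get a degenerate point CI at their shift, flagged, and
are significant iff that shift is positive. All bootstrap draws derive from
one seed; identical seeds give identical CIs and sets.

Filter 4 anchors a shift threshold on the canonical nitrifier of the
contrast: *Nitrosomonas* for ammonia-fed treatments, *Nitrospira* for the
nitrite-fed treatment (configurable). Cross-feeders and heterotrophs fixing
CO₂ anaplerotically acquire only a few percent of their carbon from the
substrate, far less than chemolithoautotrophs, so candidates shifted less
than the maximum shift of the *labeled* reference OTUs are removed. A
reference-genus member only counts as labeled (is protected and can anchor
the threshold) if its own shift clears its genus's filter-3 CI lower bound;
without this, unlabeled members of a reference genus — e.g. comammox
*Nitrospira* in a nitrite-fed column — would ride through on chance-positive
shifts and contaminate the downstream contrasts. If the reference genus has
no labeled OTU the filter passes through with a warning. Filter 5 re-applies
the both-assay genus rule, which filter 4 can break.

Stage sets are nested (F5 ⊆ … ⊆ F1) and stage sizes monotone
non-increasing; both are asserted.

## Guild classification and contrasts

Per assay, ammonia oxidizers are L(NH₄⁺) minus the labeled sets of all
other treatments — including the ATU treatment, so ATU-resistant labelers
are conservatively excluded — and nitrite oxidizers are L(NO₂⁻) minus
L(NH₄⁺+ClO₃⁻). Per-assay calls are unioned with the supporting
(treatment, assay) evidence recorded. An OTU labeled in both defining
contrasts may hold both oxidizer guilds (a comammox-like profile); this is
recorded, not suppressed. The binary *Nitrospira* contrast partitions the
genus's labeled OTUs into NH₄⁺-only (comammox candidates — comammox growth
is not supported by external nitrite alone), NO₂⁻-only (canonical NOB) and
shared sets; the partition is property-tested.

Fractional ¹³C uptake divides each labeled OTU's shift by the summed shift
of the labeled set (per treatment × assay; sums to 1). Genus ranking over
the run uses min(Δ relative abundance in total DNA, Δ in total RNA),
descending — a genus must rise in both assays to rank high; ties break
alphabetically.

## Nitrogen chemistry

NH₄⁺ removal is (in − out)/in. NO₂⁻ removal is normalised by the NO₂⁻
*produced* — the ammonium removed, or the influent NO₂⁻ for nitrite-fed
columns — after subtracting the ~0.3 µM trace NO₂⁻ present in the feed
water from the effluent (floored at zero; the correction's placement is a
package choice, applied where the trace physically sits). NO₃⁻ accretion is
(out − in)/produced, reported as not-determined when |out − in| is below
2× the measurement sd (default 1 µM). All percentages are scale-invariant
(tested). The mass balance computes σ_day = total N out − total N in and
applies a one-sample two-tailed t test (σ is already a per-day paired
difference); the balance is closed when p ≥ α (default 0.05). Summaries
report mean ± sd over days.

## Synthetic experiments

The generator emulates the four-treatment (NH₄⁺, NH₄⁺+ATU, NO₂⁻,
NH₄⁺+ClO₃⁻) × two-isotope column design with one replicate column per cell,
16 fractions per gradient (CsCl window 1.66–1.78 g/ml for DNA, CsTFA
1.74–1.84 g/ml for RNA), and 10⁴ multinomial reads per fraction. Expected
within-fraction relative abundances follow each taxon's Gaussian band
(σ 0.010 g/ml), with the ¹³C band center at µ₀ + a·Δmax (Δmax 0.036 DNA /
0.035 RNA). RNA gradients report 8 of 16 evenly spaced fractions,
exercising the sparse estimator.

The default 60-OTU community plants 6 comammox and 6 NOB *Nitrospira*, 4
*Nitrosomonas* (AOB), 4 *Pedomicrobium* cross-feeders and 40 heterotrophs.
Atom fractions encode the design's biology: ammonia oxidizers are labeled
only in the NH₄⁺-only treatment (a = 1 comammox, 0.85 AOB — canonical AOB
assimilate somewhat less per division here, placing the filter-4 reference
threshold below the comammox shifts, as observed in situ); NOB are labeled
under NH₄⁺ (in-situ nitrite) and NO₂⁻; cross-feeders carry a = 0.1 in NH₄⁺
(secondary label, well below the reference threshold); nothing is labeled
under chlorate. Heterotroph band centers tile the whole collected window —
GC content varies widely across a community, so every fraction holds real
material under both isotopes. This keeps the within-fraction relative
abundances well conditioned; without it, near-empty tail fractions become
winner-takes-all for the nearest band and bias shifts by ~0.01 g/ml.

Day-15 community profiles enrich each taxon by 1 + 3·a (renormalised);
day-0 profiles are the base abundances. Chemistry follows the treatment
regimes (99% NH₄⁺ removal untreated, ~15% under ATU, ~8% under chlorate,
88% NO₂⁻ removal in nitrite-fed columns) with nitrogen conserved into
effluent NO₃⁻ and measurement noise of sd 1 µM on concentrations above
~3 µM and 0.1 µM near the detection limit (colorimetric error shrinks with
concentration; constant-sd noise clipped at zero would fabricate a positive
N imbalance). A `dose_response_community` variant plants focal taxa at atom
fractions {0, 0.25, 0.5, 1.0} on the heterotroph background for estimator
calibration. All outputs are byte-identical for a given seed.

What the simulator does *not* emulate: PCR and primer bias, chimeras,
per-fraction library-size variation, gradient-to-gradient density
miscalibration, diffusion differences between taxa, and partial/mixed
labeling kinetics over time. Passing tests therefore demonstrate the
correctness and calibration of the inference machinery under the stated
banding model, not robustness to those real-data artifacts.

## Numerical choices and edge cases

* Depth equalization subsamples without replacement
  (multivariate hypergeometric); columns below the target depth are dropped
  with a warning, never upsampled. Default depth = the minimum library size.
* Bootstrap: percentile method, n_boot = 1000 (≥ 100 enforced), CI level
  0.90. At large genus sizes the CI endpoints converge to the normal-theory
  percentiles m ± 1.645·sd/√n (tested at n_boot = 10⁴ within 0.0005 g/ml);
  at genus size 30 the two-sided null exclusion rate is ~11–12% against the
  nominal 10%, the usual small-sample anticonservatism of the percentile
  method.
* Grid step for the sparse estimator: 1e-4 g/ml, well below every tolerance
  used.
* All-zero OTUs raise an "absent" signal rather than returning 0; degenerate
  flat concentration profiles fall back to moment estimates; a zero-variance
  zero σ-series counts as a closed balance without running the t test.
* Ranking fold changes use a 1e-6 pseudo-fraction for absent genera.

## Problem sizes

Test and acceptance runs use the default design (60 OTUs, 16 gradients,
10⁴ reads/fraction), 200 gradients for sparse-estimator agreement, 50 null
experiments, 2000 bootstrap-calibration replicates and 200 chemistry
series — sizes at which every Monte-Carlo margin in the assertions is
several standard errors wide while the whole suite stays fast.

## Known limitations

* The package detects labeling; it does not quantify atom-fraction excess
  (no qSIP-style isotope-physics inversion, no GC-content corrections).
* The fixed-σ estimator assumes a single Gaussian band per OTU; mixed
  populations with bimodal labeling will be summarised by one center.
* Filter 4 presumes the reference genus is present and labeled; in its
  absence the cascade is permissive (pass-through with warning).
* Guild logic is strict set algebra on labeled sets; partial labeling that
  drops an OTU in a single treatment changes its guild call.
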