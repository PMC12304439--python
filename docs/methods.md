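# Methods

This note documents the models, conventions and numerical choices behind
`pelagifd`, in the order the pipeline runs them, together with what the
synthetic data generator does and does not emulate.

## Biomass standardisation and depth layers

Each midwater haul is towed horizontally at a fixed immersion depth, so a
haul samples a single depth. Catch mass (kg) per species is divided by the
filtered volume, `vertical opening × horizontal opening × distance
trawled` (all m), giving densities in kg m⁻³. When distance is absent it
is derived from the nominal towing protocol (1 h at 4 kn = 7408 m) with a
logged warning.

Four layers partition the sampled 20–2000 m column: epipelagic 20–175 m,
upper mesopelagic 175–700 m, lower mesopelagic 700–1000 m, bathypelagic
1000–2000 m. Intervals are half-open `[min, max)` — a haul at exactly
175 m belongs to the upper mesopelagic — and 2000 m closes the deepest
layer, making the assignment total. The bounds are conventionally printed
as touching values without stating ownership; the half-open convention is
ours and is applied consistently.

Layer assemblages aggregate haul densities by the per-species **mean**
across the layer's hauls (default), which is robust to unequal haul counts
(7/27/16/18 in the reference design); a `sum` option exists, under which
density × volume conservation holds exactly.

## Traits

26 traits describe food acquisition: 16 continuous (ratios of linear
measurements, e.g. eye diameter / head depth; two absolute measures in
cm — caudal peduncle minimum depth as "caudal throttle width" and
operculum width as "gill outflow"), 2 ordinal (gill raker development in
3 ordered categories; oral gape axis in 5), and 8 binary presence/absence
observations. Ratio traits are scale-invariant by construction: doubling
every linear measurement changes only the two absolute traits. A zero
denominator yields a missing cell plus a logged anomaly rather than an
error.

**Species exclusion.** A species is dropped when the traits with *no*
observed value in any of its individuals exceed 25 % of the trait set
(7/26 = 26.9 % excludes; 6/26 = 23.1 % is retained).

**Imputation** runs at the individual level (missingness in this kind of
data is ~1 % of cells but concentrated in small-bodied species). Each of
`m = 5` chains performs 50 chained-equation sweeps: every incomplete
column is regressed (OLS) on all other trait columns and each missing cell
is replaced by the observed value of a donor drawn uniformly from the
`k = 5` rows with the nearest regression prediction (predictive mean
matching). Because donors are observed values, imputations automatically
respect positivity, binary codes and ordinal ranks. Chains are seeded
deterministically from a master seed; pooling is the mean across chains
for continuous traits and majority vote (ties to the lower code) for
ordinal/binary. Observed cells are never altered and complete tables pass
through unchanged. This is a deliberately compact chained-equations
implementation: one model family (OLS + PMM) rather than a configurable
model per column type.

**Species summary.** Continuous → mean over individuals; ordinal → median
category (rounded); binary → presence when at least half the individuals
show the trait. Binary species-level values are kept as 0/1 because the
species matrix feeds Gower simple matching; biomass-weighted *proportions*
of binary traits are handled separately by the CWM, where they belong.

## Functional space

**Gower dissimilarity** with equal unit weights over the 26 traits:
continuous columns contribute `|xᵢ−xⱼ| / range`; ordinal columns are first
converted to tie-averaged ranks (Podani's convention) and then treated as
continuous; binary columns use simple matching. A constant column carries
no information and contributes 0 while keeping its unit weight in the
denominator (warned), so d stays comparable across datasets.

**PCoA**: double-centre −½D², eigendecompose, scale eigenvectors by
√eigenvalue. Gower dissimilarities are generally non-Euclidean; when
negative eigenvalues exceed a 1e−8 relative tolerance the default
correction replaces d by √d (Euclidean-embeddable for Gower), with the
Cailliez additive constant and an uncorrected mode (warning recorded) as
alternatives. Percent variation uses positive eigenvalues only.

**Space quality** for a candidate dimensionality m is the mean squared
deviation (mSD) over unordered pairs between the m-axis Euclidean
distances — rescaled so their maximum matches the maximum target
dissimilarity — and the dissimilarities the PCoA actually embedded (√d
under the default correction). Targeting the embedded matrix keeps the
score's two defining properties exact: a perfect embedding scores 0 and
nested projections never worsen the score. The profile is reported for
m = 2…min(S−1, 10); m = 4 is the default compromise and all downstream
hull work uses it.

**Convex hulls** use Qhull. Coincident points (duplicate null draws) are
deduplicated before hull construction; every species sitting on a vertex
position is reported as a vertex. Sets with fewer than m+1 affinely
independent points raise a dimensionality error; assemblage-level wrappers
fall back to the largest feasible dimensionality with a logged flag.

## Diversity indices

For an assemblage with relative biomass weights wᵢ (Σwᵢ = 1) and 4-axis
coordinates xᵢ:

- **FRic**: hull volume of the species present; also reported as a
  fraction of the whole-community hull volume for comparability.
- **FEve**: minimum spanning tree over Euclidean distances; edge values
  EW = dist/(wᵢ+wⱼ) normalised to PEW; FEve rescales Σ min(PEW, 1/(S−1))
  to [0,1]. Species are processed in sorted label order so MST ties
  resolve deterministically; S ≥ 3 required.
- **FDis**: Σ wᵢ‖xᵢ − c‖ with c = Σ wᵢxᵢ.
- **FDiv**: with G the unweighted centroid of the hull vertices and
  dGᵢ = ‖xᵢ − G‖: FDiv = (Δd + d̄G)/(Δ|d| + d̄G), Δd = Σ wᵢ(dGᵢ − d̄G).

All four are invariant to rigid motions of the space; FEve and FDiv live
in [0,1].

## Null model and SES

The null hypothesis is that traits are independent of depth distribution.
For an S-species assemblage, each of 999 draws assigns every species slot
a whole coordinate row resampled **with replacement from the full species
pool** (not just the layer's species), keeping the observed biomass
weights in slot order. Whole-row resampling preserves trait covariance —
the standard trait-swap null; an independent per-trait shuffle is
available as an option. Weights are never randomized.

SES = (obs − mean(null)) / sd(null) (n−1 denominator). Significance uses a
two-branch rule: Shapiro–Wilk at α = 0.05 on the null values, retried on
the log scale when all values are positive; if normal (either scale),
|SES| > 1.96 on the working scale decides; otherwise the observed value is
compared with the 2.5 %/97.5 % percentiles (linear interpolation between
order statistics — a decision invariant under monotone transforms). The
reported SES is always on the raw index scale. Adjusted Fisher–Pearson
skewness on the working scale is reported, with |skew| > 1 flagged as
largely asymmetric.

**Known property**: because null draws contain duplicates while a real
assemblage's species are distinct, hull-based indices (FRic) have a
slightly smaller null mean than an equally random distinct-species
assemblage, biasing its SES positive by roughly +1 at S = 20 of a
42-species pool. The FDis/FEve/FDiv kernels are essentially unaffected.
Calibration statements therefore target FDis; FRic SES values are
interpreted via their sign *contrast* across layers (filtered layers still
come out robustly negative, divergent layers positive).

## CWM and layer-profile PCA

CWM for a trait at a sampling depth is the biomass-weighted mean over the
species present, excluding the two nominal-use ordinal traits; binary
traits give biomass-weighted proportions present. Uncertainty comes from a
nonparametric bootstrap at the individual level: each of 999 draws samples
200 individuals with replacement, species chosen proportionally to biomass
and individuals uniformly within species (equivalently, one flattened
individual-level multinomial), the statistic being the mean trait value.
The defaults (999 × 200) are our choice — the method itself does not
prescribe sizes — and the summary mean provably converges to the analytic
weighted mean at rate sd/√n_boot. Depth-specific individual pools can be
requested via a window; the species-wide pool is the fallback.

The layer-profile PCA standardises the 4-layer × trait matrix of median
bootstrap CWMs (medians over the layer's sampling depths) to unit
variance and decomposes the correlation structure; with 4 layers at most
3 components are non-null and their variance shares sum to 100 %.

## Functional rarity

Uniqueness Uᵢ = minⱼ≠ᵢ dᵢⱼ from the community Gower matrix. Restrictedness
Rᵢ = 1 − (occupied depth extent)/(total sampled extent), clipped to [0,1],
using continuous depth ranges (an occupied-stations variant would count
sites instead; depth extent matches the "depth-range restrictedness"
notion used here). A species caught at a single depth has zero extent,
R = 1, and is flagged. Species above both community medians are reported
as functionally rare.

## Synthetic community generator

The generator emulates the survey's statistical structure so that every
stage — including SES inference — can be validated against planted ground
truth:

- **Species pool**: 42 archetypes built on the packaged reference table
  (per-species depth ranges, individual counts 3–39, standard length
  mean ± SD). Traits follow a three-factor latent model — a depth axis
  (tied to the species' position on the log-depth gradient), a body-plan
  axis and a trophic-apparatus axis — with trait-specific loadings and
  log-normal idiosyncratic noise. This concentrates roughly half the
  Gower/PCoA variance on four axes, matching the correlated structure of
  real morphometrics, and produces the expected qualitative depth trends
  (eye size and ventral photophores declining, gape surface and large
  teeth increasing with depth).
- **Individuals**: continuous trait values are the archetype times
  multiplicative log-normal noise (log-SD 0.10); raw measurements are
  back-solved by inverting each trait formula given the individual's
  standard length, so trait derivation is honestly exercised end-to-end
  (zero noise recovers archetypes exactly). Missing measurements are
  injected missing-at-random conditioned on standard length (small fish
  lose cells more often), exactly `round(rate × cells)` of them
  (default rate 1 %).
- **Assemblages**: per-layer richness defaults to 13/28/32/42. Assembly
  modes: *neutral* draws species uniformly (with-replacement trait draws
  available for exact null-model calibration — see below); *filtered*
  samples species with Gaussian weight in Gower distance around a layer
  optimum, σ = mean pool dissimilarity / strength (default strength 4);
  *divergent* selects by greedy max–min spacing seeded from the most
  distant pair. Biomass is log-normal (μ = log 0.3 kg, σ = 1.2 —
  log-skewed, as in trawl data); hauls within a layer catch random subsets
  of the layer's species with Dirichlet mass shares, every selected
  species forced into at least one haul. Everything is deterministic under
  a master seed fanned out via `SeedSequence.spawn`.

**Calibration convention.** Under the null, the trait vectors of an
S-species assemblage are iid draws from the pool. A neutral assemblage
drawn *without* replacement is slightly under-dispersed relative to that
null (finite-pool effect: SES sd ≈ √(1−S/N)); drawing trait rows *with*
replacement is the exactly calibrated neutral condition and is what the
calibration tests use (mean SES(FDis) within ±0.2, gaussian-pathway
rejection ≈ 5 % at 999 draws). Ecological layer assemblages keep species
distinct.

**What the generator does not emulate**: hydrographic structure, diel
migration, gear selectivity, phylogenetic signal in traits beyond the
shared latent factors, and spatial (lat/lon) autocorrelation. Passing
tests therefore demonstrate the *inferential machinery* — not that real
deep-pelagic communities behave like the generator.

## Problem sizes used in the shipped analyses

The analysis scripts and acceptance run use the full reference-scale
community (42 species, 722 individuals, 68 hauls) with 999 null draws per
layer × index and 999 × 200 bootstrap draws per trait × depth; the
calibration study uses 500 neutral replicates and the mechanism-recovery
study 100 replicates per mode, each with 999 null draws. These sizes were
chosen to keep Monte-Carlo error well below the effects of interest while
completing in minutes on a single core.

## Known limitations

- The FRic-SES positive bias for distinct-species assemblages under the
  with-replacement null (above) is inherent to the method, not a bug; it
  cancels in cross-layer contrasts.
- Shapiro–Wilk at n = 999 is extremely sensitive: mild skew in a
  hull-volume or dispersion null routes inference to the percentile
  pathway. That is the intended behaviour of the decision rule, but it
  makes the *pathway* (not the decision) seed-dependent.
- PMM cannot extrapolate beyond observed donor values; with <1 %
  missingness this is immaterial, but heavy missingness in a tail would
  shrink imputed variance.
- The PCoA √d correction changes the geometry all indices are computed
  in; comparisons with hull volumes from uncorrected spaces are not
  meaningful. All shipped analyses use one correction consistently.
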