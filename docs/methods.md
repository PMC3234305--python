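# Methods

## The problem

Label-free quantification by spectral counting normally requires assigning
every MS/MS spectrum to a peptide through a database or spectral-library
search first. Spectra that the search engine cannot assign — in liver-tissue
LC-MS/MS runs that can be the large majority — are lost to quantification.
`qfish` instead clusters the experimental spectra directly against each
other: replicate acquisitions of one peptide have similar fragment patterns
and similar precursor m/z, so a cluster of mutually similar spectra is
treated as one (possibly unidentified) peptide and its abundance per run is
the number of member spectra.

## Spectrum representation and similarity

Each centroided peak list is mapped to a fixed m/z grid (default
200–2000 Da at 0.1 Da; both range and resolution configurable), intensities
within a bin summed and the bin vector scale-standardized by its maximum,
`y[i] = x[i] / max(x)`. Max-scaling removes total-ion-current differences
between acquisitions; only the relative peak pattern remains.

A moving-window average (MWA) then slides a window of `K` bins (default 30,
i.e. 3.0 Da) across the grid with stride one bin, producing a profile of
length `N = bins − K + 1`:

    m[i] = Σ_{j=0}^{K−1} w_j · y[i+j]

`N` is always derived from the grid, never hard-coded. Two kernels are
available: uniform (`w_j = 1/K`) and the default gaussian, whose weights
are the standard-normal pdf evaluated at the z-scores of the window's
bin-center m/z values (sample standard deviation), renormalized to sum to
one. Because the grid is uniform these weights are identical for every
window position, giving a fixed symmetric bell. Both kernels are convex
combinations, so profiles stay inside [0, 1].

The similarity of two spectra is the Pearson correlation `r` of their MWA
profiles. Smoothing is what buys tolerance to small m/z calibration shifts:
a one-bin shift that destroys the raw binned correlation barely moves the
smoothed profiles (this is asserted as a property test). A zero-variance
profile (near-empty spectrum) makes `r` undefined; such pairs are scored 0
with a warning rather than raising mid-pipeline, since near-empty spectra
should never merge anyway.

## Two-stage clustering

**Stage 1 — precursor grouping.** Spectra of one peptide share precursor
m/z, so spectra are first grouped so that every *pair* within a group
differs by at most the precursor tolerance (default ±1 Da, applied to the
reported m/z as printed). This pairwise (diameter) condition is enforced
exactly by complete-linkage agglomeration cut at the tolerance — simple
connected components would not bound the diameter. In one dimension
complete-linkage clusters are contiguous intervals of the sorted values,
which makes the procedure O(n log n); tied merge distances (within 1e-9 Da)
resolve toward the pair containing the lowest spectrum index, so results
are reproducible. Precursor charge is ignored by default (an optional
`--split-by-charge` pre-partition is available).

**Stage 2 — pattern clustering.** Inside each precursor group,
single-linkage hierarchical clustering on distance `d = 1 − r` is cut at
height `1 − ρ` (default ρ = 0.6). This cut is mathematically identical to
taking connected components of the graph with edges wherever `r ≥ ρ`; the
tests exploit that equivalence as an independent oracle. All samples and
replicates are clustered jointly and only counted per replicate afterwards,
so a peptide present in both groups yields one shared cluster.

Each cluster receives a **reference spectrum** (bin-wise mean of the
members' standardized binned spectra) and a **Q score**, the mean
correlation between the reference's MWA profile and each member's; 1 means
the reference represents the cluster perfectly, and singletons score 1 by
construction. Counting members per (sample, replicate) yields the
spectral-count matrix; column sums over all clusters are the per-replicate
totals `n` used downstream, computed before any filtering. Clustering is a
partition: no admitted spectrum is ever dropped or double-counted, which is
asserted at run time.

## Retention-time validation (FCR)

Replicate acquisitions of one peptide elute within a narrow LC window, so a
correct cluster has a small coefficient of variation of its members'
retention times, `CV = 100 · sd / mean` (sample sd, n−1). CV is reported in
percent — the 1–10 cutoff grid only makes sense against percent-scale CVs
of chromatographic times. Clusters of size one have no CV and are excluded
from the statistic entirely.

The false clustering rate at a CV cutoff Δ is estimated by permutation:
retention times of all multi-member clusters are pooled, shuffled, and
dealt back into the same cluster-size template, and

    FCR(Δ) = (1/P) Σ_p  #{i : CV_p(i) ≤ Δ} / #{i : CV(i) ≤ Δ}

over P permutations (default 100, seeded; an exhaustive mode enumerates all
permutations for tiny inputs). When no observed cluster passes Δ the
statistic is undefined and reported as NA; the ratio can exceed 1 in
pathological cases and is reported unclamped with a warning. Scans over a
Δ grid reuse one permutation stream so the scan is internally consistent,
and `choose_delta` / `choose_rho` pick the grid value whose FCR is closest
to the target (default 0.05) from below, ties to the smaller threshold,
falling back to closest-overall when nothing is below. The ρ scan
reclusters at every grid value; profiles, precursor groups and each group's
linkage tree are computed once, so only the cut height changes. A cluster
"passes" when its CV is at or below the chosen Δ; the global FCR certifies
the cutoff, not individual clusters.

## Differential expression

For clusters observed in both groups (and passing the CV filter), counts
`x` out of per-replicate totals `n` follow a beta-binomial model:
`x | p ~ Binomial(n, p)` with `p ~ Beta(α, β)`, reparameterized by the mean
proportion `π = α/(α+β) = h(Xb)` and overdispersion `φ = 1/(α+β+1) ∈ [0,1)`,
giving marginal mean `n·π` and variance `n·π(1−π)[1+(n−1)φ]`. The link `h`
is logit by default (complementary log-log available); `φ` is shared
between groups within a cluster. Parameters are estimated by maximizing
the marginal log-likelihood with bounded quasi-Newton on `(b, logit φ)`
from deterministic multi-starts (moment estimate of φ, a small-φ start,
and per-group observed proportions), each polished with a derivative-free
pass because finite-difference gradients are noisy near the φ boundary.
A fit pinned at the lower φ bound is reported as a binomial fit.

The group effect is tested by the likelihood ratio: `2(ℓ_alt − ℓ_null)`
floored at zero against chi-squared with one degree of freedom (a Wald
variant is provided for comparison, and `fix_phi=0` collapses the test to
the binomial LRT). p-values are Benjamini–Hochberg adjusted over the
clusters actually tested (shared, CV-passing, converged fits); failed fits
carry NA and leave the universe.

**Known limitation — small-sample calibration.** With three replicates per
group the chi-squared reference is anti-conservative: under an all-null
simulation the empirical type-I error at nominal 0.05 is roughly 0.13, and
the same inflation is produced by an independent beta-binomial
implementation (glmmTMB) on identical data, so it is a property of the
asymptotic reference with six observations and an estimated overdispersion,
not of this implementation. Power is nonetheless strictly increasing in the
effect size, and BH-significant calls at q ≤ 0.05 should be read as a
ranking with an inflated nominal level rather than a calibrated FDR at this
replicate count.

## Synthetic data

The generator emulates exactly the structure the method exploits, and
nothing else. Each peptide template has 10–40 fragment peaks uniform over
the grid range with relative intensities scaled to a maximum of 1, a
precursor m/z (spread over 400–1600 Da, at least 2 Da apart by default;
deliberate collisions are available for stress tests), and an elution time
uniform over a 600–6600 s run. Templates are rejection-sampled until all
pairwise MWA correlations are below 0.3, so ground truth is recoverable in
principle. Acquisitions are Poisson per template × replicate (default rate
3 per replicate, mirroring a two-group × three-replicate design); each
acquisition applies multiplicative lognormal intensity noise (log-sd 0.3),
Bernoulli peak dropout (0.1), Gaussian m/z jitter (0.02 Da), precursor
error (0.1 Da) and RT jitter (30 s). True differentially expressed
templates (10% at odds ratio 4) have their acquisition rate scaled in the
first group. `emit_counts` samples count tables directly from the
beta-binomial marginal (π ∈ [0.002, 0.02], φ = 0.05, n = 5000 per
replicate) for testing the statistics without spectra; its totals are the
generated `n`, not column sums. Truth labels accompany every artifact.

What the generator does *not* model: physical fragmentation chemistry,
isotope envelopes, chimeric spectra, correlated noise between peaks, or RT
drift between runs. Passing recovery tests therefore show the pipeline's
correctness under its own assumptions, not instrument-level realism. One
scale effect worth knowing: independent random templates have MWA
correlations centered on zero, so at ρ = 0 about half of colliding
template pairs still fail to merge; the fully permissive end of a ρ scan
(ρ = −1) is the appropriate "random clustering" endpoint at desk scale,
whereas on real data at full scale the ρ = 0 end already behaves randomly.

## Numerical choices

- Binning is half-open `[lo, hi)` per bin; out-of-range peaks are dropped
  and counted. Duplicate m/z values within a spectrum merge by summing.
- Correlations within 1e-9·√N of constancy are treated as zero-variance.
- Distances `1 − r` are clipped at 0 before linkage (r can exceed 1 by an
  ulp for identical profiles).
- The beta-binomial pmf is computed through log-beta functions, with the
  binomial limit below φ = 1e-10.
- Optimizer: L-BFGS-B with b ∈ [−30, 30], φ ∈ [1e-6, 0.99] on the logit
  scale, then Nelder–Mead polish; convergence tolerance 1e-11 on the
  negative log-likelihood.
- Test and example simulations use a reduced 600–1200 Da grid and 8–12
  templates; the pipeline itself defaults to the full 200–2000 Da grid.
- All randomness flows from a single root seed recorded next to every
  run's outputs; permutation streams are reused across scan grids.
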