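# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the limitations of the package. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Binding quantification

Polarization is converted to anisotropy with A = 2P/(3 − P) (inverse
P = 3A/(2 + A)); the conversion is strictly monotone on [0, 3).
Titrations are fitted by nonlinear least squares with the hyperbolic
single-site law A(c) = A_f + (A_b − A_f)·c/(K_d + c) over (K_d, A_f,
A_b), initialized at A_f = min A, A_b = max A and K_d = the
concentration nearest mid-anisotropy, with K_d bounded positive.
Ligand depletion is ignored: the fluorescent probe is used at 40 nM,
2–3 orders of magnitude below the K_d values of these reader domains,
so total ≈ free protein concentration. A series whose anisotropy
amplitude is below `flat_tol` (default 10⁻³) raises as unidentifiable
rather than returning a meaningless K_d. Fits require ≥ 4 points
spanning ≥ one decade of concentration.

Competition series are fitted with a four-parameter logistic on log10
competitor concentration. The functional form is a pragmatic standard
(the IC50 *ranking* across competitors is the contract, and it is
invariant to affine transformations of the anisotropy axis, which the
tests check); an optional Cheng–Prusoff conversion
K_i = IC50/(1 + [probe]/K_d,probe) is provided and labelled derived.
A series that does not decrease with competitor (Spearman ρ ≥ 0) or has
negligible amplitude is flagged non-competing instead of fitted.

Peptide-array spots are summarized as mean intensity per modification
combination divided by the mean of the reference combination
(invariant to global multiplicative scaling). Whether published
relative percentages were background-subtracted is generally ambiguous,
so both modes exist: optional per-slide median subtraction of designated
empty spots before ratios. Flanking-modification effects are classified
with default thresholds switch ≤ 0.5 × reference and rheostat ≥ 1.5 ×;
the source classification is qualitative, so the thresholds are exposed
parameters.

## CAGE pipeline

Coordinates are 0-based half-open everywhere internally (BED on disk);
1-based positions appear only in human-readable reports. Coverage is
the per-base count of tag 5′ ends, strand-separated. Candidate
initiation intervals are maximal runs of consecutive nonzero bases — the
simplest interval definition consistent with a genome-coverage-based
procedure — and intervals with total tags strictly greater than
`min_reads` (default 10) are retained; that threshold is depth-dependent
and therefore a parameter. The TSS is the interval's per-base maximum;
ties resolve to the 5′-most position on the annotated strand.

The quantification window ("150 bp flanking") is read as 150 bp total
centred on the TSS, i.e. [pos − 75, pos + 75); the alternative ±150
reading is available by passing `window=300`. CPM is count × 10⁶ /
library total; expression change is log2((CPM_mut + 0.5)/(CPM_wt + 0.5)).

Initiation shape uses the 10–90 % interquantile width of the tag
distribution within ±100 bp of the TSS: the smallest base span holding
the cumulative tag fraction (0.10, 0.90]; width ≤ 15 bp ⇒ focused. The
exact published criterion for the focused/dispersed dichotomy is not
reproduced anywhere accessible, so all four numbers are parameters.

Motif classes are scanned as IUPAC consensi in class-specific windows
relative to the TSS, strand-aware, first match in scan order wins
(DRE → Ohler1 → Ohler7 → TATA → Inr). Defaults (DRE = TATCGATA,
TATA = TATAAA, Inr = TCAGTY, Ohler1 = YGGTCACACTR, Ohler7 = CAKCNCTRNY)
come from the published Drosophila core-promoter literature and are
config-overridable.

## Nucleosome pipeline

Occupancy is the midpoint histogram convolved with a Gaussian kernel
(default sd 20 bp — a smoothing choice, not a measured value — truncated
at 4 sd and renormalized to unit sum). The output track is widened by
the kernel radius so total read mass is conserved exactly for any sd;
scipy's stock filters truncate mass at array edges, which would break
that invariant.

Metagene profiles are strand-oriented row matrices around anchors
(minus-strand rows flipped), averaged column-wise; the default offset
grid is −100..+450 bp around TSSs, extended downstream when counting
full arrays. Phased nucleosomes are counted from the TSS outward:
local maxima with prominence ≥ 20 % of the profile maximum whose
successive spacings stay within 120–250 bp; counting stops at the first
failure. The prominence defining "well-positioned" is nowhere
quantified in the source literature and is a parameter.

The shift statistic compares depth-normalized (reads-per-million)
tracks in sliding 50 bp windows, step 10 bp (the window is fixed by the
method description; the step is not, 10 bp chosen as a 5× oversampling),
log2((mut + 0.5)/(wt + 0.5)) per window; it is antisymmetric under
genotype swap, and unnormalized input is refused unless explicitly
requested. Which normalization basis ("normalized tag densities") was
used originally is unstated; per-million is the default with the raw
option exposed. Profile displacement is the lag maximizing normalized
cross-correlation of mean-centred profiles within ±60 bp; ties resolve
to the smallest magnitude; negative = mutant shifted toward the TSS.

Quintiles rank sites by descending signal, ties broken by genomic
coordinate (stable), remainders assigned to earlier quintiles — 5456
sites split 1092/1091/1091/1091/1091. K-means on profile rows uses
scikit-learn with a fixed seed (k default 3; the published heatmaps show
numbered clusters but never print k), rows ordered by cluster then
within-cluster mean for heatmap emission.

## Single-molecule and FRAP kinetics

Movies default to 500 ms frames, 300 frames. Fragments whose end/start
are ≤ max_gap + 1 frames and ≤ 2 px apart are merged greedily
nearest-first (distance ties to the earlier fragment id); chains are
allowed; each end/start merges at most once.

Dwell conventions: an n-frame track spans n × Δt ("inclusive", the
library default — a single detection counts one interval) or
(n − 1) × Δt ("span"). For an exponential dwell T discretized to
n = ⌈T/Δt⌉ frames, P(n ≥ k) = S_true((k−1)Δt): the inclusive-convention
empirical survival is the true survivor function shifted by one frame,
and a mixture fitted to it cannot yield a mean below one frame interval.
The span convention gives P(n − 1 ≥ k) = S_true(kΔt) — exact on the
frame grid — so the residence-time pipeline (report, acceptance script)
extracts dwells under the span convention; this follows from the
discretization algebra, not from tuning.

The uncorrected survival curve S(t) = fraction of dwells ≥ t is built on
the frame grid, extended a few frames past the longest dwell where the
empirical survivor function is exactly zero (this anchors fits for
fast-dissociating populations whose dwells span only a few frames).
Censored dwells (tracks touching the movie ends) are included at their
observed length — the "uncorrected" convention; a Kaplan–Meier-style
handling is intentionally not the default. The two-exponential fit
uses three starting points and keeps the best least-squares solution,
constrained to f ∈ [0, 1], τ > 0; it is canonicalized to τ₁ ≤ τ₂
(the mixture is label-symmetric) and collapses to a single exponential
when the two time constants agree within 5 %. The mean residence time
is the mixture mean f·τ₁ + (1 − f)·τ₂; the slow component τ₂ is also
reported since "average residence" is ambiguous between the two. No
photobleaching correction is applied (a documented limitation: real
survival curves decay faster than binding kinetics alone).

FRAP is modelled as single-exponential recovery I(t) = I_∞ − (I_∞ −
I₀)e^(−kt) — the simplest standard model, recorded in output metadata —
with t½ = ln 2/k and mobile fraction (I_∞ − I₀)/(baseline − I₀), the
baseline being the pre-bleach mean. Traces whose recovery amplitude is
within noise (2 × pre-bleach sd, floored at 10⁻⁶ of baseline for
noise-free traces) are flagged immobile.

## The synthetic-data generator

All randomness derives from one seed through named PCG64 substreams
keyed by (seed, generator name, entity index), so output is bit-identical
for a fixed seed and adding entities to one generator never reshuffles
another's draws.

Ground-truth defaults are the study conditions: binding truths 2 µM
(H3K4me3), 300 nM (H3K4me3K9AcS10p), 96 µM (H4tetraAc) with A_f = 0.05,
A_b = 0.25; array effects 0.12 (T3p), 0.30 (R2me2a), 0.60 (R2me2s),
6.0 (K9Ac) relative to H3K4me3; residence mixture f = 0.5, τ₁ = 0.5 s,
τ₂ = 14.5 s (mean 7.5 s) for the reader-competent construct and a
single exponential τ = 0.3 s for the reader-less one; FRAP t½ = 10.7 s
(WT) and 45 s (mutant, a 4.2-fold slowdown), mobile fraction 1.

The toy genome interleaves five promoter classes on one chromosome at
5 kb spacing (refused if spacing < 2× the profiling flank): DRE, Ohler
box 1 and Ohler box 7 are housekeeping — dispersed initiation (25 bp sd
kernel), high HPTM, genotype multipliers 1.08/1.10/1.10 (the Ohler 7
value is the package's own choice, grouped with the other housekeeping
classes) — while TATA and Inr are developmental: focused initiation
(2 bp sd), low HPTM, multipliers 0.72/0.74. Housekeeping promoters
carry expression weight 2.0 vs 1.0 (constitutive promoters are more
highly expressed and dominate CAGE library mass); with this mix the
read-weighted mean multiplier is ≈ 1, so per-library CPM ratios between
genotypes recover the class multipliers directly — with equal weights,
CPM (a purely relative measure) would carry a global compositional
offset of several percent. Per-promoter latent HPTM levels are the
class level times lognormal(sd 0.4) noise, the shared factor behind the
ChIP-track correlations.

Nucleosome arrays: +1 dyad at TSS + 135 bp, repeat 180 bp, 7
nucleosomes — plausible Drosophila geometry, config-overridable.
Midpoint fuzziness sd 20 bp at housekeeping and 60 bp at developmental
promoters. In the mutant, dyad n at housekeeping promoters moves
n × 10 bp toward the TSS, capped at nucleosome 7; the direction and
propagation follow the modelled biology, the magnitudes are generator
choices. MNase fragment-size selection and paired-end midpoint
inference are not modelled — the generator emits midpoints directly.

Single-molecule tracks: true dwell from the mixture, discretized to
⌈T/Δt⌉ frames (min 1), uniform start frame, truncation at movie end
recorded as censoring; interior frames drop independently with
`skip_prob` but never two in a row (single-frame gaps only, matching
the linker's contract); positions jitter (sd 0.2 px) around a
per-molecule location uniform in a 256 × 256 px field — wide enough
that 10,000 molecules per movie do not collide during re-linking.
Raw reads/FASTQ, mappability, PCR duplicates, microscope PSFs and 2-D
diffusion physics are out of scope, so passing tests demonstrate
estimator correctness under the stated statistical structure, not
robustness to those real-data artifacts.

## Problem sizes

The default test suite and demo run use deliberately small cohorts
(10–40 promoters per class, 1,500–2,000 molecules); the acceptance
script and the cohort-level tests use the study-scale sizes where the
claims require them (500 promoters/class for CAGE class changes; 10,000
dwells for residence times, simulated in long movies so movie-end
truncation is negligible; 100 seeded replicates for array-effect
accuracy). The end-to-end demo is byte-reproducible for a fixed seed,
and every output file carries a provenance header (version, config
hash, seed).

## Known limitations

* No photobleaching or tracking-error model for residence times;
  censoring is included uncorrected by default.
* The FRAP model is one exponential; reaction–diffusion models are out
  of scope.
* Motif calling is consensus matching, not PWM scoring; no de novo
  discovery.
* The competition pull-down (band densities) is inherently
  semi-quantitative and is represented only as ordinal resistance
  ranks, never fitted values.
* CPM is the only cross-library normalization; no batch correction.
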