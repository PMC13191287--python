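# nurfscape

Quantitative pipeline for studying how combinatorial histone-tail
modifications direct the NURF chromatin remodeler to promoter-proximal
(+1) nucleosomes — with a fully seeded synthetic-data generator, so every
stage is testable on a laptop without downloading any sequencing data.

## Who this is for

Chromatin and regulatory-genomics researchers who need the quantitative
machinery behind a reader-domain/remodeler study as reusable, tested
code: fitting binding constants from fluorescence-polarization (FP)
titrations, calling transcription start sites (TSSs) from CAGE tags,
mapping remodeler-dependent nucleosome shifts from MNase midpoints, and
estimating chromatin-binding kinetics from single-molecule tracks and
FRAP traces.

## The models at the core

**Reader-domain binding.** FP readings are converted to anisotropy,
*A* = 2*P*/(3 − *P*), and titrations fitted with the single-site law

    A([L]) = A_f + (A_b − A_f)·[L] / (K_d + [L])

(ligand depletion neglected: the 40 nM probe sits far below the K_d
regime of these domains).  Competition series get a four-parameter
logistic on log10 competitor concentration; peptide-array spots are
reduced to binding relative to a reference modification and classified
as **switches** (relative binding ≤ 0.5, recognition abolished) or
**rheostats** (≥ 1.5, graded enhancement).

**CAGE TSS calling.** Per-base 5′-end coverage; maximal nonzero runs are
candidate intervals; intervals with > 10 tags are kept and the per-base
maximum is the TSS.  Expression per TSS is the tag count in a 150 bp
window (±75) as counts-per-million; promoters are classified by
initiation shape (10–90 % interquantile width ≤ 15 bp ⇒ focused) and by
core motif (ordered IUPAC scan: DRE, Ohler box 1, Ohler box 7, TATA,
Inr).

**Nucleosome shifts.** MNase midpoints → Gaussian-smoothed occupancy
(mass-conserving, sd 20 bp); strand-oriented metagene profiles; phased
downstream nucleosomes counted from prominence-filtered peaks at the
expected repeat; genotype differences as log2 fold change in sliding
50 bp windows (step 10 bp, depth-normalized, pseudocount 0.5) and as a
cross-correlation displacement (negative = mutant +1 array shifted
toward the TSS).

**Single-molecule kinetics.** Track fragments split by single skipped
frames are re-linked (greedy nearest-first, ≤ 2 px); dwell times build an
uncorrected survival curve fitted with a two-exponential mixture
S(t) = f·e^(−t/τ₁) + (1−f)·e^(−t/τ₂); the mean residence time is
f·τ₁ + (1−f)·τ₂.  FRAP traces are fitted with single-exponential
recovery; the half-life is ln 2 / k.

Each fitter is a scikit-learn-style estimator
(`SingleSiteBinding`, `CompetitionCurve`, `TwoExponentialSurvival`,
`FrapRecovery`) with fitted attributes (`kd_`, `ic50_`,
`mean_residence_`, `t_half_`, …); thin functional wrappers
(`fit_single_site`, …) cover script use.

## Worked example

Run the end-to-end demo (simulate → analyze → report):

```bash
nurfscape report --seed 1 --outdir demo_run
```

or equivalently `run_end_to_end(RunConfig(seed=1, outdir="demo_run"))`
from Python.  The bundle contains, among others, `binding_fits.tsv`:

```
peptide	kd_M	af	ab	rss	converged
H3K4me3	2e-06	0.05	0.25	8.31809e-22	True
H3K4me3K9AcS10p	3e-07	0.05	0.25	4.27593e-18	True
H4tetraAc	9.6e-05	0.05	0.25	5.73526e-27	True
```

— the fitter recovers the generating affinities exactly on noise-free
titrations: 2 µM for the PHD finger on H3K4me3, 300 nM once the tail
carries the K9Ac/S10p marks (a ~7-fold affinity gain from flanking
modifications), and the much weaker 96 µM bromodomain–H4tetraAc
interaction.  `kinetics.json` reports the single-molecule fits:

```
"NURF301-A": { "f": 0.499, "tau1_s": 0.543, "tau2_s": 14.888,
               "mean_residence_s": 7.73 }
"NURF301-C": { "f": 1.0, "tau1_s": 0.304, "mean_residence_s": 0.304 }
```

— the reader-competent construct dwells ~7.5 s on chromatin while the
reader-less construct dissociates in ~0.3 s, and the FRAP section shows
the recovery half-life rising from 10.7 s (WT) to 45 s when the reader
pathway is removed.  `cage_class_change.tsv` summarizes per-promoter-
class expression changes in the remodeler mutant (housekeeping classes
slightly up, TATA/Inr classes down ~26–28 %), and `summary.json` flags
every recovered quantity against the generating truth.

## Layout

| Module | Contents |
| --- | --- |
| `nurfscape.simulate` | seeded generators for every input (genome, CAGE, MNase, ChIP-like tracks, titrations, arrays, tracks, FRAP) |
| `nurfscape.binding` | anisotropy conversion, single-site & competition fits, array quantification, switch/rheostat calls |
| `nurfscape.cage` | coverage, TSS calling, window counts/CPM/log2FC, shape & motif classification, class aggregation |
| `nurfscape.nucleosomes` | occupancy tracks, profiles, phasing counts, sliding shifts, displacement, quintiles, k-means |
| `nurfscape.imaging` | frame-skip linking, dwell times, survival fits, FRAP fits, bound/unbound ratios |
| `nurfscape.report` / `nurfscape.cli` | end-to-end orchestration and the `nurfscape` command |

See `docs/methods.md` for model assumptions, parameter defaults and
known limitations.
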