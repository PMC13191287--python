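"""Seeded synthetic-data generators for every pipeline input.

Each generator draws from an independent, named RNG substream of the
:class:`~nurfscape.config.TruthConfig` seed (PCG64 keyed by generator name
and entity index), so a fixed seed gives bit-identical output and adding
entities to one generator never reshuffles another's draws.

What is emulated — and what is not.  CAGE tag pileups are discretized
Gaussian kernels around the true TSS (narrow for focused promoters, wide
for dispersed ones) with a genotype-dependent expected depth; MNase
midpoints are Gaussian draws around phased dyads downstream of the TSS,
with the mutant displacing dyad *n* toward the TSS by ``n *
shift_increment`` at high-HPTM promoters; ChIP-like tracks are Gaussian
bumps at the +1 dyad (HPTM marks) or just upstream of it (remodeler);
single-molecule tracks carry exponential-mixture dwell truths with
single-frame detection dropouts; FRAP traces follow single-exponential
recovery.  Raw reads/FASTQ, mappability, PCR duplicates, microscope PSFs
and 2-D diffusion are all out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binding import single_site_anisotropy
from .config import TruthConfig
from .io import CoverageTrack

__all__ = [
    "gen_titration",
    "gen_competition",
    "gen_peptide_array",
    "gen_genome",
    "gen_cage_reads",
    "gen_mnase_reads",
    "gen_chip_track",
    "gen_tracks",
    "gen_frap",
    "true_dyads",
]

_BASES = np.array(list("ACGT"))
_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

FIELD_SIZE = 256.0  # pixels, synthetic camera field for particle tracks


# ---------------------------------------------------------------- binding


def gen_titration(
    truth: TruthConfig, peptide: str, concentrations, noise_sd: float = 0.0
) -> pd.DataFrame:
    """Anisotropy titration series for one probe-protein pair.

    Values follow the single-site law of the registered (Kd, Af, Ab) truth
    plus Gaussian noise; ``noise_sd=0`` gives the exact curve.  Columns:
    ``conc_M``, ``A``.
    """
    if peptide not in truth.binding_truth:
        raise KeyError(f"unknown peptide {peptide!r}; registered: {sorted(truth.binding_truth)}")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be sorted ascending and unique")
    bt = truth.binding_truth[peptide]
    A = single_site_anisotropy(conc, bt.kd, bt.af, bt.ab)
    if noise_sd > 0:
        A = A + truth.rng("titration:" + peptide).normal(0.0, noise_sd, size=len(conc))
    return pd.DataFrame({"conc_M": conc, "A": A})


def gen_competition(
    truth: TruthConfig,
    competitor: str,
    ic50: float,
    concentrations,
    hill: float = 1.0,
    top: float = 0.22,
    bottom: float = 0.06,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Four-parameter-logistic competition series with known IC50."""
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("competitor concentrations must be strictly positive")
    A = bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)
    if noise_sd > 0:
        A = A + truth.rng("competition:" + competitor).normal(0.0, noise_sd, size=len(conc))
    return pd.DataFrame({"conc_M": conc, "A": A})


def gen_peptide_array(
    truth: TruthConfig,
    n_replicates: int = 4,
    noise_cv: float = 0.10,
    base_intensity: float = 1000.0,
) -> pd.DataFrame:
    """Peptide-array spot intensities with multiplicative lognormal noise.

    Spot intensity for combination *c* is ``base_intensity *
    array_effects[c] * lognormal`` with coefficient of variation
    ``noise_cv`` and unit mean (so zero noise gives exact multiples and
    the reference stays exactly 1.0 in expectation).  Replicates model
    duplicate spots over two slides (n = 4 by default).  Columns:
    ``combo``, ``replicate``, ``slide``, ``intensity``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rows = []
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        mu = -0.5 * sigma**2  # unit-mean lognormal
    for i, (combo, mult) in enumerate(sorted(truth.array_effects.items())):
        rng = truth.rng("array", i)
        for rep in range(n_replicates):
            factor = 1.0 if noise_cv == 0 else float(rng.lognormal(mu, sigma))
            rows.append(
                {
                    "combo": combo,
                    "replicate": rep,
                    "slide": rep % 2,
                    "intensity": base_intensity * mult * factor,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- genome


def _instantiate_consensus(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        choices[int(rng.integers(len(choices)))] if len(choices) > 1 else choices
        for choices in (_IUPAC_CHOICES[c] for c in consensus.upper())
    )


def gen_genome(truth: TruthConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Random-background genome with one motif-bearing promoter per TSS.

    Promoter classes are interleaved along a single chromosome at fixed
    ``spacing`` (refused if spacing < 2x the profiling flank).  For each
    promoter, a concrete instantiation of the class consensus is embedded
    at the class motif offset on the promoter strand.  The annotation
    records the true TSS, strand, class, initiation shape, housekeeping
    flag, per-promoter latent HPTM level and the genotype expression
    multiplier.  Returned as ``(sequences, annotation)``; the annotation is
    coordinate-sorted and non-overlapping by construction.
    """
    gs = truth.genome
    if gs.spacing < 2 * gs.flank:
        raise ValueError(
            f"promoter spacing {gs.spacing} < 2x profiling flank {gs.flank}: promoters overlap"
        )
    n_total = sum(c.count for c in gs.classes)
    length = max(2 * gs.flank + n_total * gs.spacing, 1000)
    rng_seq = truth.rng("genome:sequence")
    seq = _BASES[rng_seq.integers(0, 4, size=length)]

    cls_of = np.repeat(np.arange(len(gs.classes)), [c.count for c in gs.classes])
    rng_layout = truth.rng("genome:layout")
    cls_of = cls_of[rng_layout.permutation(n_total)]

    rows = []
    for i in range(n_total):
        cls = gs.classes[cls_of[i]]
        tss = gs.flank + i * gs.spacing
        rng_p = truth.rng("genome:promoter", i)
        strand = "+" if rng_p.random() < 0.5 else "-"
        motif = _instantiate_consensus(cls.consensus, rng_p)
        if strand == "-":
            ins = motif.translate(_COMPLEMENT)[::-1]
            start = tss - cls.motif_offset - len(motif) + 1
        else:
            ins = motif
            start = tss + cls.motif_offset
        seq[start : start + len(ins)] = list(ins)
        hptm = cls.hptm_level * float(np.exp(rng_p.normal(0.0, gs.hptm_lognorm_sd)))
        rows.append(
            {
                "chrom": gs.chrom,
                "tss": tss,
                "strand": strand,
                "name": f"prom{i:05d}",
                "cls": cls.name,
                "shape": cls.shape,
                "housekeeping": cls.housekeeping,
                "hptm": hptm,
                "cage_multiplier": cls.cage_multiplier,
                "expression_weight": cls.expression_weight,
            }
        )
    annotation = pd.DataFrame(rows, columns=[
        "chrom", "tss", "strand", "name", "cls", "shape",
        "housekeeping", "hptm", "cage_multiplier", "expression_weight",
    ])
    return {gs.chrom: "".join(seq)}, annotation


def annotation_to_bed(annotation: pd.DataFrame) -> pd.DataFrame:
    """Annotation TSSs as one-bp BED6 intervals."""
    return pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["tss"],
            "end": annotation["tss"] + 1,
            "name": annotation["name"],
            "score": 0,
            "strand": annotation["strand"],
        }
    )


# ------------------------------------------------------------------- CAGE

FOCUSED_SD = 2.0  # bp, narrow initiation kernel
DISPERSED_SD = 25.0  # bp, broad initiation kernel


def gen_cage_reads(
    annotation: pd.DataFrame,
    truth: TruthConfig,
    genotype: str = "WT",
    depth: float = 200.0,
) -> pd.DataFrame:
    """CAGE tags (one-bp BED6 reads) around each annotated TSS.

    Per promoter, a Poisson number of tags with expectation ``depth *
    expression_weight`` (times the class multiplier for the mutant
    genotype) is placed at ``TSS + round(N(0, sd))`` in gene orientation,
    with sd 2 bp for focused and 25 bp for dispersed promoters.

    Expression weights make housekeeping promoters carry more library
    mass than developmental ones, as in real CAGE libraries; with the
    default class mix the read-weighted mean multiplier is ~1, so
    per-library CPM ratios between genotypes recover the class
    multipliers without a compositional offset.
    """
    if genotype not in ("WT", "mutant"):
        raise ValueError("genotype must be 'WT' or 'mutant'")
    if depth <= 0:
        raise ValueError("depth must be positive")
    chroms, starts, names, strands = [], [], [], []
    for i, prom in annotation.reset_index(drop=True).iterrows():
        rng = truth.rng(f"cage:{genotype}", i)
        mult = float(prom["cage_multiplier"]) if genotype == "mutant" else 1.0
        weight = float(prom.get("expression_weight", 1.0))
        n = int(rng.poisson(depth * weight * mult))
        if n == 0:
            continue
        sd = FOCUSED_SD if prom["shape"] == "focused" else DISPERSED_SD
        sign = 1 if prom["strand"] == "+" else -1
        offs = np.rint(rng.normal(0.0, sd, size=n)).astype(int)
        pos = int(prom["tss"]) + sign * offs
        chroms.append(np.full(n, prom["chrom"]))
        starts.append(pos)
        names.append(np.full(n, prom["name"]))
        strands.append(np.full(n, prom["strand"]))
    if not starts:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    start = np.concatenate(starts)
    return pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "start": start,
            "end": start + 1,
            "name": np.concatenate(names),
            "score": 0,
            "strand": np.concatenate(strands),
        }
    )


# ------------------------------------------------------------------ MNase


def true_dyads(prom: pd.Series, truth: TruthConfig, genotype: str) -> np.ndarray:
    """Ground-truth dyad positions for one promoter, in genome coordinates.

    WT dyads sit at ``TSS + plus1_offset + (n-1)*repeat`` downstream (gene
    orientation).  In the mutant, dyad *n* at housekeeping (high-HPTM)
    promoters moves ``min(n, shift_cap) * shift_increment`` bp toward the
    TSS; low-HPTM promoters are unchanged.
    """
    ns = truth.nucleosomes
    sign = 1 if prom["strand"] == "+" else -1
    n = np.arange(1, ns.array_len + 1)
    offsets = ns.plus1_offset + (n - 1) * ns.repeat
    if genotype == "mutant" and bool(prom["housekeeping"]):
        offsets = offsets - np.minimum(n, ns.shift_cap) * ns.shift_increment
    return int(prom["tss"]) + sign * offsets


def gen_mnase_reads(
    annotation: pd.DataFrame,
    truth: TruthConfig,
    genotype: str = "WT",
    depth: float = 50.0,
) -> pd.DataFrame:
    """Nucleosome-midpoint reads (one-bp BED6) with phased downstream arrays.

    Midpoints are Gaussian draws (sd = class fuzziness: low at high-HPTM,
    high at low-HPTM promoters) around the ground-truth dyads of
    :func:`true_dyads`; ``depth`` is the Poisson expectation per
    nucleosome.  Fragment-size selection and midpoint inference from
    paired ends are not modelled: the generator emits midpoints directly.
    """
    if genotype not in ("WT", "mutant"):
        raise ValueError("genotype must be 'WT' or 'mutant'")
    if depth <= 0:
        raise ValueError("depth must be positive")
    ns = truth.nucleosomes
    chroms, starts, names = [], [], []
    for i, prom in annotation.reset_index(drop=True).iterrows():
        rng = truth.rng(f"mnase:{genotype}", i)
        fuzz = ns.fuzziness_high if prom["housekeeping"] else ns.fuzziness_low
        for dyad in true_dyads(prom, truth, genotype):
            n = int(rng.poisson(depth))
            if n == 0:
                continue
            if fuzz == 0:
                pos = np.full(n, int(dyad))
            else:
                pos = np.rint(rng.normal(float(dyad), fuzz, size=n)).astype(int)
            chroms.append(np.full(n, prom["chrom"]))
            starts.append(pos)
            names.append(np.full(n, prom["name"]))
    if not starts:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    start = np.concatenate(starts)
    return pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "start": start,
            "end": start + 1,
            "name": np.concatenate(names),
            "score": 0,
            "strand": "+",
        }
    )


# ------------------------------------------------------------------- ChIP

CHIP_MARKS = ("H3K4me3", "H3K9Ac", "H3K9AcS10p", "H4K16Ac", "NURF")
_NURF_UPSTREAM_OFFSET = 80  # bp upstream of the +1 dyad
_CHIP_SD = 50.0  # bp


def gen_chip_track(
    annotation: pd.DataFrame,
    truth: TruthConfig,
    mark: str,
    chrom_length: int | None = None,
) -> CoverageTrack:
    """ChIP-like signal track for one histone mark or the remodeler.

    HPTM marks are Gaussian bumps centred on the +1 dyad, scaled by the
    per-promoter latent HPTM level; the remodeler ("NURF") bump is centred
    just upstream of the +1 dyad, so its signal flanks the HPTM signal on
    the TSS side with the same promoter-level scaling (shared latent
    factor — the construction behind their genome-wide correlation).
    """
    if mark not in CHIP_MARKS:
        raise ValueError(f"unknown mark {mark!r}; one of {CHIP_MARKS}")
    gs = truth.genome
    ns = truth.nucleosomes
    if chrom_length is None:
        n_total = len(annotation)
        chrom_length = max(2 * gs.flank + n_total * gs.spacing, 1000)
    values = np.zeros(chrom_length)
    x = np.arange(chrom_length)
    for _, prom in annotation.iterrows():
        level = float(prom["hptm"])
        if level == 0:
            continue
        sign = 1 if prom["strand"] == "+" else -1
        plus1 = int(prom["tss"]) + sign * ns.plus1_offset
        center = plus1 - sign * _NURF_UPSTREAM_OFFSET if mark == "NURF" else plus1
        lo = max(center - 300, 0)
        hi = min(center + 301, chrom_length)
        values[lo:hi] += level * np.exp(-0.5 * ((x[lo:hi] - center) / _CHIP_SD) ** 2)
    return CoverageTrack(gs.chrom, 0, values)


# --------------------------------------------------- single-molecule tracks


def gen_tracks(
    truth: TruthConfig,
    construct: str = "NURF301-A",
    n_molecules: int = 1000,
    frame_interval: float = 0.5,
    n_frames: int = 300,
    skip_prob: float = 0.0,
    loc_sd: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-molecule binding tracks with optional single-frame dropouts.

    Per molecule, a true dwell is drawn from the registered two-exponential
    mixture and discretized to ``ceil(dwell / frame_interval)`` frames
    (minimum one).  The binding event starts at a uniform frame; frames
    beyond the movie end are truncated (censoring recorded).  Each
    *interior* detection frame is independently dropped with probability
    ``skip_prob``, except that two consecutive drops are not allowed
    (single-frame gaps only); a dropped frame splits the track into
    fragments, as a particle tracker would.  Detections jitter around a
    per-molecule position with sd ``loc_sd`` pixels.

    Returns ``(tracks, molecules)``: tracks with columns ``track_id,
    molecule_id, frame, x, y``; molecules with the per-molecule ground
    truth (true dwell, observed frames, censoring, fragment count).
    """
    if construct not in truth.kinetics:
        raise KeyError(f"unknown construct {construct!r}")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if not 0.0 <= skip_prob < 1.0:
        raise ValueError("skip_prob must be in [0, 1)")
    mix = truth.kinetics[construct]
    rng = truth.rng("tracks:" + construct)
    rows_t, rows_m = [], []
    frag_counter = 0
    for m in range(n_molecules):
        fast = rng.random() < mix.f
        dwell = float(rng.exponential(mix.tau1 if fast else mix.tau2))
        n_det = max(1, int(np.ceil(dwell / frame_interval)))
        start = int(rng.integers(0, n_frames))
        end = min(start + n_det, n_frames)  # truncate at movie end
        frames = np.arange(start, end)
        censored = (start + n_det > n_frames) or start == 0
        keep = np.ones(len(frames), dtype=bool)
        prev_dropped = False
        for j in range(1, len(frames) - 1):
            if not prev_dropped and rng.random() < skip_prob:
                keep[j] = False
                prev_dropped = True
            else:
                prev_dropped = False
        x0 = rng.uniform(0, FIELD_SIZE)
        y0 = rng.uniform(0, FIELD_SIZE)
        kept = frames[keep]
        # split at gaps into fragments
        breaks = np.flatnonzero(np.diff(kept) > 1)
        fragments = np.split(kept, breaks + 1)
        for frag in fragments:
            tid = frag_counter
            frag_counter += 1
            for fr in frag:
                rows_t.append(
                    {
                        "track_id": tid,
                        "molecule_id": m,
                        "frame": int(fr),
                        "x": x0 + float(rng.normal(0, loc_sd)),
                        "y": y0 + float(rng.normal(0, loc_sd)),
                    }
                )
        rows_m.append(
            {
                "molecule_id": m,
                "true_dwell_s": dwell,
                "n_frames_observed": int(len(frames)),
                "censored": bool(censored),
                "n_fragments": len(fragments),
            }
        )
    tracks = pd.DataFrame(rows_t, columns=["track_id", "molecule_id", "frame", "x", "y"])
    molecules = pd.DataFrame(rows_m)
    return tracks, molecules


# ------------------------------------------------------------------- FRAP


def gen_frap(
    truth: TruthConfig,
    strain: str = "WT",
    n_prebleach: int = 10,
    duration: float = 120.0,
    interval: float = 0.5,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """FRAP trace: pre-bleach plateau, then single-exponential recovery.

    Post-bleach intensity follows ``I(t) = I_inf - (I_inf - I_0) *
    exp(-t ln2 / t_half)`` with ``I_inf`` set by the mobile fraction.
    Columns: ``time_s``, ``intensity``, ``phase`` ('pre'/'post'); bleach
    at t = 0.
    """
    if strain not in truth.frap:
        raise KeyError(f"unknown strain {strain!r}")
    if duration <= 0 or interval <= 0:
        raise ValueError("duration and interval must be positive")
    ft = truth.frap[strain]
    i0 = ft.baseline * ft.bleach_depth
    i_inf = i0 + ft.mobile_fraction * (ft.baseline - i0)
    t_pre = -interval * np.arange(n_prebleach, 0, -1)
    t_post = np.arange(0.0, duration + interval / 2, interval)
    I_pre = np.full(len(t_pre), ft.baseline)
    I_post = i_inf - (i_inf - i0) * np.exp(-t_post * np.log(2) / ft.t_half)
    t = np.concatenate([t_pre, t_post])
    I = np.concatenate([I_pre, I_post])
    if noise_sd > 0:
        I = I + truth.rng("frap:" + strain).normal(0.0, noise_sd, size=len(I))
    phase = np.where(t < 0, "pre", "post")
    return pd.DataFrame({"time_s": t, "intensity": I, "phase": phase})
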