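"""Ground-truth configuration for the synthetic-data generator.

A :class:`TruthConfig` is the single registry of everything the generator
knows to be true: dissociation constants, peptide-array effect multipliers,
the promoter landscape of the toy genome, nucleosome-array geometry and the
genotype-dependent shift rule, and the chromatin-binding kinetics of the
full-length (reader-competent) and truncated (reader-less) remodeler
constructs.  Downstream recovery tests compare fitted values against this
registry.

All randomness is derived from the single ``seed`` through named substreams
(:func:`substream`), so adding entities to one generator never reshuffles the
draws of another.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BindingTruth",
    "PromoterClass",
    "GenomeSpec",
    "NucleosomeSpec",
    "DwellMixture",
    "FrapTruth",
    "TruthConfig",
    "substream",
]


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Derive an independent RNG substream keyed by (seed, name, index).

    The key is folded through CRC32 of ``name`` into the entropy of a
    PCG64 ``Generator``; the mapping is stable across platforms and numpy
    versions that keep the PCG64 bit stream (documented guarantee).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng([int(seed), key, int(index)])


@dataclass(frozen=True)
class BindingTruth:
    """Single-site binding ground truth for one probe-protein pair."""

    kd: float  # molar
    af: float  # anisotropy of the free probe
    ab: float  # anisotropy of the bound probe

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError(f"Kd must be positive, got {self.kd}")


@dataclass(frozen=True)
class PromoterClass:
    """One core-promoter class of the toy genome.

    ``motif_offset`` is where the consensus is embedded relative to the TSS
    (promoter-strand coordinates, negative = upstream); ``motif_window`` is
    where the classifier is allowed to look for it.  ``cage_multiplier`` is
    the mutant/WT expected-depth ratio for this class; ``shape`` selects the
    initiation kernel (focused sd ~2 bp, dispersed sd ~25 bp).
    """

    name: str
    consensus: str
    motif_offset: int
    motif_window: tuple[int, int]
    shape: str  # "focused" | "dispersed"
    housekeeping: bool
    hptm_level: float
    cage_multiplier: float
    expression_weight: float = 1.0
    count: int = 20


def _default_classes() -> tuple[PromoterClass, ...]:
    # Housekeeping classes (DRE / Ohler boxes): dispersed initiation, high
    # promoter-proximal HPTM, constitutively ~2-fold more highly expressed
    # than the developmental classes (TATA / Inr: focused, low HPTM).
    # Genotype multipliers: +8% (DRE), +10% (Ohler1), -28% (TATA),
    # -26% (Inr); Ohler7 defaults to +10% alongside Ohler1.  With these
    # weights the read-weighted mean multiplier is ~1, so per-library CPM
    # ratios recover the multipliers without a compositional offset.
    return (
        PromoterClass("DRE", "TATCGATA", -60, (-100, -20), "dispersed", True, 1.0, 1.08, 2.0),
        PromoterClass("Ohler1", "YGGTCACACTR", -45, (-80, 0), "dispersed", True, 1.0, 1.10, 2.0),
        PromoterClass("Ohler7", "CAKCNCTRNY", -25, (-60, 10), "dispersed", True, 1.0, 1.10, 2.0),
        PromoterClass("TATA", "TATAAA", -30, (-40, -15), "focused", False, 0.2, 0.72, 1.0),
        PromoterClass("Inr", "TCAGTY", -2, (-10, 10), "focused", False, 0.2, 0.74, 1.0),
    )


@dataclass(frozen=True)
class GenomeSpec:
    """Geometry of the synthetic genome."""

    classes: tuple[PromoterClass, ...] = field(default_factory=_default_classes)
    spacing: int = 5000  # bp between consecutive TSSs
    flank: int = 2000  # profiling flank each promoter must own
    chrom: str = "chrSim"
    hptm_lognorm_sd: float = 0.4  # per-promoter latent HPTM spread


@dataclass(frozen=True)
class NucleosomeSpec:
    """Downstream nucleosome-array geometry and the mutant shift rule.

    The +1 dyad sits ``plus1_offset`` bp downstream of the TSS and further
    dyads follow at ``repeat`` bp.  In the remodeler mutant, dyad *n* at
    housekeeping (high-HPTM) promoters is displaced toward the TSS by
    ``n * shift_increment`` bp, capped at nucleosome ``shift_cap``.
    """

    repeat: int = 180
    plus1_offset: int = 135
    array_len: int = 7
    fuzziness_high: float = 20.0  # sd (bp) at well-phased high-HPTM promoters
    fuzziness_low: float = 60.0  # sd (bp) at poorly phased low-HPTM promoters
    shift_increment: int = 10
    shift_cap: int = 7

    def __post_init__(self):
        if self.repeat <= 0:
            raise ValueError("nucleosome repeat length must be positive")
        if self.array_len < 1:
            raise ValueError("array_len must be >= 1")


@dataclass(frozen=True)
class DwellMixture:
    """Two-exponential chromatin residence-time mixture, f*Exp(tau1) + (1-f)*Exp(tau2)."""

    f: float
    tau1: float  # s
    tau2: float  # s

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("mixture fraction f must be in [0, 1]")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("time constants must be positive")

    @property
    def mean(self) -> float:
        return self.f * self.tau1 + (1.0 - self.f) * self.tau2


@dataclass(frozen=True)
class FrapTruth:
    """Single-exponential FRAP recovery ground truth."""

    t_half: float  # s
    mobile_fraction: float = 1.0
    baseline: float = 1.0
    bleach_depth: float = 0.2  # I0 immediately after bleach, as fraction of baseline

    def __post_init__(self):
        if self.t_half <= 0:
            raise ValueError("t_half must be positive")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must be in [0, 1]")


def _default_binding() -> dict[str, BindingTruth]:
    # Reader-domain affinities: PHD finger for the singly vs triply modified
    # H3 tail, bromodomain for the tetra-acetylated H4 tail.
    return {
        "H3K4me3": BindingTruth(2.0e-6, 0.05, 0.25),
        "H3K4me3K9AcS10p": BindingTruth(3.0e-7, 0.05, 0.25),
        "H4tetraAc": BindingTruth(9.6e-5, 0.05, 0.25),
    }


def _default_array_effects() -> dict[str, float]:
    # Relative spot intensity vs the H3K4me3 reference: T3 phosphorylation is
    # a switch (12%), arginine dimethylation partial switches (30% / 60%),
    # K9 acetylation a rheostat (~6-fold enhancement).
    return {
        "H3K4me3": 1.0,
        "H3T3pK4me3": 0.12,
        "H3R2me2aK4me3": 0.30,
        "H3R2me2sK4me3": 0.60,
        "H3K4me3K9Ac": 6.0,
    }


def _default_kinetics() -> dict[str, DwellMixture]:
    # Full-length construct: mixture mean 7.5 s; reader-less construct:
    # fast single-exponential, tau 0.3 s (mean residence < 500 ms).
    return {
        "NURF301-A": DwellMixture(0.5, 0.5, 14.5),
        "NURF301-C": DwellMixture(1.0, 0.3, 0.3),
    }


def _default_frap() -> dict[str, FrapTruth]:
    # WT recovery half-life 10.7 s; reader pathway loss slows recovery by
    # >= 4-fold (modelled at 45 s).
    return {
        "WT": FrapTruth(10.7, 1.0),
        "mutant": FrapTruth(45.0, 1.0),
    }


@dataclass(frozen=True)
class TruthConfig:
    """Complete ground-truth registry for one simulated study."""

    seed: int = 0
    binding_truth: dict[str, BindingTruth] = field(default_factory=_default_binding)
    array_effects: dict[str, float] = field(default_factory=_default_array_effects)
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    nucleosomes: NucleosomeSpec = field(default_factory=NucleosomeSpec)
    kinetics: dict[str, DwellMixture] = field(default_factory=_default_kinetics)
    frap: dict[str, FrapTruth] = field(default_factory=_default_frap)

    def __post_init__(self):
        for combo, mult in self.array_effects.items():
            if mult <= 0:
                raise ValueError(f"array effect for {combo!r} must be positive")

    def rng(self, name: str, index: int = 0) -> np.random.Generator:
        """Named RNG substream; see :func:`substream`."""
        return substream(self.seed, name, index)

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthConfig":
        raw = json.loads(text)
        raw["binding_truth"] = {k: BindingTruth(**v) for k, v in raw["binding_truth"].items()}
        gen = raw["genome"]
        gen["classes"] = tuple(
            PromoterClass(**{**c, "motif_window": tuple(c["motif_window"])})
            for c in gen["classes"]
        )
        raw["genome"] = GenomeSpec(**gen)
        raw["nucleosomes"] = NucleosomeSpec(**raw["nucleosomes"])
        raw["kinetics"] = {k: DwellMixture(**v) for k, v in raw["kinetics"].items()}
        raw["frap"] = {k: FrapTruth(**v) for k, v in raw["frap"].items()}
        return cls(**raw)
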