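"""End-to-end orchestration: simulate -> analyze -> report.

:func:`run_end_to_end` drives the whole pipeline on synthetic data from a
single seeded configuration and writes a report bundle (binding tables,
TSS tables, shift tracks, profiles, kinetics fits and a recovered-vs-truth
summary).  A run is fully determined by its configuration: re-running with
the same config regenerates the bundle byte-identically.  Every output
file carries a provenance header (package version, config hash, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding, cage, imaging, io, nucleosomes, simulate
from .config import TruthConfig
from .version import __version__

__all__ = ["RunConfig", "run_end_to_end"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one end-to-end demo run.

    Sizes are deliberately small — the run is a smoke-scale integration of
    every stage, not a power analysis.
    """

    seed: int = 0
    outdir: str = "nurfscape_run"
    promoters_per_class: int = 20
    cage_depth: float = 300.0
    mnase_depth: float = 40.0
    n_molecules: int = 2000
    min_reads: int = 10
    window: int = 150
    titration_noise_sd: float = 0.0
    array_noise_cv: float = 0.10
    array_replicates: int = 4

    def truth(self) -> TruthConfig:
        base = TruthConfig(seed=self.seed)
        classes = tuple(
            dataclasses.replace(c, count=self.promoters_per_class) for c in base.genome.classes
        )
        return dataclasses.replace(
            base, genome=dataclasses.replace(base.genome, classes=classes)
        )

    def config_hash(self) -> str:
        # outdir does not influence output content, so it is excluded:
        # the same parameters regenerate the same bundle anywhere
        fields = {k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"}
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return f"nurfscape v{__version__} seed={config.seed} config={config.config_hash()}"


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def run_end_to_end(config: RunConfig) -> dict:
    """Run every pipeline stage on synthetic data and write the bundle.

    Returns the summary dictionary (also written as ``summary.json``),
    whose ``recovery`` section compares each recovered quantity against
    the generating truth with a within-tolerance flag.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = config.truth()
    prov = _provenance(config)
    manifest: list[str] = []
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "recovery": {},
        "warnings": [],
    }

    def record(name, recovered, expected, rel_tol):
        ok = (
            np.isfinite(recovered)
            and abs(recovered - expected) <= rel_tol * abs(expected) + 1e-12
        )
        summary["recovery"][name] = {
            "recovered": float(recovered),
            "truth": float(expected),
            "rel_tol": rel_tol,
            "within_tolerance": bool(ok),
        }

    # ---------------- binding ----------------
    conc = np.geomspace(1e-8, 1e-3, 16)
    fit_rows = []
    for peptide, bt in sorted(truth.binding_truth.items()):
        series = simulate.gen_titration(truth, peptide, conc, config.titration_noise_sd)
        fit = binding.fit_single_site(series["conc_M"], series["A"])
        fit_rows.append(
            {
                "peptide": peptide,
                "kd_M": fit.kd_,
                "af": fit.af_,
                "ab": fit.ab_,
                "rss": fit.rss_,
                "converged": fit.converged_,
            }
        )
        record(f"binding_kd[{peptide}]", fit.kd_, bt.kd, 1e-4 if config.titration_noise_sd == 0 else 0.2)
    _write_tsv(pd.DataFrame(fit_rows), outdir / "binding_fits.tsv", prov)
    manifest.append("binding_fits.tsv")

    array = simulate.gen_peptide_array(truth, config.array_replicates, config.array_noise_cv)
    quant = binding.quantify_array(array, reference="H3K4me3")
    _write_tsv(quant, outdir / "array_quant.tsv", prov)
    manifest.append("array_quant.tsv")
    for _, row in quant.iterrows():
        record(
            f"array_relative[{row['combo']}]",
            row["relative_binding"],
            truth.array_effects[row["combo"]],
            0.25,
        )

    # ---------------- genomics ----------------
    if config.promoters_per_class > 0:
        genome, annotation = simulate.gen_genome(truth)
        chrom = truth.genome.chrom
        length = len(genome[chrom])
        io.write_fasta(genome, outdir / "genome.fa")
        io.write_bed(simulate.annotation_to_bed(annotation), outdir / "true_tss.bed")
        manifest += ["genome.fa", "true_tss.bed"]

        cage_reads = {
            g: simulate.gen_cage_reads(annotation, truth, g, config.cage_depth)
            for g in ("WT", "mutant")
        }
        tss_tables = []
        for strand in ("+", "-"):
            track = cage.compute_coverage(cage_reads["WT"], length, chrom, strand)
            called = cage.call_tss(track, min_reads=config.min_reads)
            if called.empty:
                continue
            lib = {g: len(r) for g, r in cage_reads.items()}
            counts = {
                g: cage.window_counts_batch(r, called["pos"], strand, config.window)
                for g, r in cage_reads.items()
            }
            called["count_wt"] = counts["WT"]
            called["count_mut"] = counts["mutant"]
            called["cpm_wt"] = [cage.normalize_cpm(c, lib["WT"]) for c in called["count_wt"]]
            called["cpm_mut"] = [cage.normalize_cpm(c, lib["mutant"]) for c in called["count_mut"]]
            called["log2fc"] = [
                cage.expression_log2fc(w, m) for w, m in zip(called["cpm_wt"], called["cpm_mut"])
            ]
            shapes = [cage.classify_shape(track, p) for p in called["pos"]]
            called["shape"] = [s for s, _ in shapes]
            called["iq_width"] = [w for _, w in shapes]
            called["motif"] = [
                cage.classify_motif(genome[chrom], p, strand) for p in called["pos"]
            ]
            tss_tables.append(called)
        tss_table = pd.concat(tss_tables, ignore_index=True) if tss_tables else pd.DataFrame()
        _write_tsv(tss_table, outdir / "tss_table.tsv", prov)
        manifest.append("tss_table.tsv")

        if not tss_table.empty:
            class_change = cage.aggregate_class_change(tss_table, class_key="motif")
            _write_tsv(class_change, outdir / "cage_class_change.tsv", prov)
            manifest.append("cage_class_change.tsv")
            mult_by_class = {c.name: c.cage_multiplier for c in truth.genome.classes}
            for _, row in class_change.iterrows():
                cls = row["motif"]
                if cls in mult_by_class:
                    record(
                        f"cage_pct_change[{cls}]",
                        row["mean_pct_change"] / 100.0 + 1.0,
                        mult_by_class[cls],
                        0.1,
                    )

        # nucleosomes
        mnase = {
            g: simulate.gen_mnase_reads(annotation, truth, g, config.mnase_depth)
            for g in ("WT", "mutant")
        }
        occ = {g: nucleosomes.occupancy_track(r, length) for g, r in mnase.items()}
        shift = nucleosomes.sliding_shift(occ["WT"], occ["mutant"])
        with open(outdir / "shift_track.bedgraph", "w") as fh:
            fh.write(f"# {prov} (window={shift.window} step={shift.step})\n")
            for s, v in zip(shift.starts, shift.log2fc):
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{s + shift.step}\t{v:.4g}\n")
        _write_tsv(shift.to_frame(), outdir / "shift_track.tsv", prov)
        manifest += ["shift_track.bedgraph", "shift_track.tsv"]

        hk = annotation[annotation["housekeeping"]].rename(columns={"tss": "pos"})
        profile_rows = []
        if len(hk):
            flank_down = truth.nucleosomes.plus1_offset + truth.nucleosomes.repeat * truth.nucleosomes.array_len
            offs, prof_wt = nucleosomes.averaged_profile(occ["WT"], hk, 100, flank_down)
            _, prof_mut = nucleosomes.averaged_profile(occ["mutant"], hk, 100, flank_down)
            n_phased = nucleosomes.count_phased_nucleosomes(offs, prof_wt)
            record("phased_nucleosome_count", n_phased, truth.nucleosomes.array_len, 0.0)
            profile_rows = pd.DataFrame(
                {"offset": offs, "wt": prof_wt, "mutant": prof_mut}
            )
            _write_tsv(profile_rows, outdir / "housekeeping_profile.tsv", prov)
            manifest.append("housekeeping_profile.tsv")
    else:
        msg = "zero promoters configured: genomics sections empty"
        warnings.warn(msg, stacklevel=2)
        summary["warnings"].append(msg)
        for name in ("tss_table.tsv", "shift_track.tsv"):
            _write_tsv(pd.DataFrame(), outdir / name, prov + " (empty: zero promoters)")
            manifest.append(name)

    # ---------------- kinetics ----------------
    kin = {}
    for construct, mix in sorted(truth.kinetics.items()):
        tracks, _ = simulate.gen_tracks(
            truth, construct, n_molecules=config.n_molecules, n_frames=3000, skip_prob=0.1
        )
        linked, n_merged = imaging.link_skipped_frames(tracks)
        dwells = imaging.dwell_times(linked, 0.5, n_frames=3000, convention="span")
        t, S = imaging.survival_curve(dwells, 0.5)
        fit = imaging.fit_two_exponential(t, S)
        kin[construct] = {
            "n_tracks": int(dwells.shape[0]),
            "n_merged": int(n_merged),
            "f": fit.f_,
            "tau1_s": fit.tau1_,
            "tau2_s": fit.tau2_,
            "mean_residence_s": fit.mean_residence_,
            "dwell_convention": "span",
        }
        record(f"mean_residence[{construct}]", fit.mean_residence_, mix.mean, 0.15)

    frap_fits = {}
    for strain, ft in sorted(truth.frap.items()):
        trace = simulate.gen_frap(truth, strain)
        fit = imaging.fit_frap(trace["time_s"], trace["intensity"])
        frap_fits[strain] = {
            "t_half_s": fit.t_half_,
            "mobile_fraction": fit.mobile_fraction_,
            "model": "single-exponential recovery",
        }
        record(f"frap_t_half[{strain}]", fit.t_half_, ft.t_half, 1e-4)
    kinetics_out = {"provenance": prov, "single_molecule": kin, "frap": frap_fits}
    (outdir / "kinetics.json").write_text(json.dumps(kinetics_out, indent=2, sort_keys=True))
    manifest.append("kinetics.json")

    summary["all_within_tolerance"] = all(
        v["within_tolerance"] for v in summary["recovery"].values()
    )
    summary["manifest"] = sorted(manifest + ["summary.json"])
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
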