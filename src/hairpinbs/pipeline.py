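"""End-to-end orchestration: simulate -> recover -> call -> annotate.

A single top-level seed derives per-stage seeds deterministically, so a run
is reproducible end to end. All outputs are plain text (FASTA/FASTQ/TSV/BED/
bedGraph/JSON) with 0-based half-open coordinates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import methylation as mc
from . import recover as rc
from . import simulate as sg

logger = logging.getLogger("hairpinbs")

REJECTION_REASONS = (rc.SHORT, rc.LOW_IDENTITY, rc.UNCONVERTED, rc.UNMAPPED, rc.MULTIMAPPED)


@dataclass
class PipelineConfig:
    outdir: str = "hairpinbs_run"
    seed: int = 0
    # reference
    ref_length: int = 50000
    gc_fraction: float = 0.42
    cgi_count: int = 4
    cgi_length: int = 500
    cgi_boost: float = 4.0
    n_transcripts: int = 6
    transcript_length: int = 2000
    # ground truth: background mostly-methylated mixture, hypomethylated CGIs
    background_state: tuple[float, float, float, float] = (0.83, 0.05, 0.05, 0.07)
    cgi_state: tuple[float, float, float, float] = (0.02, 0.02, 0.02, 0.94)
    noncpg_rate: float = 0.004
    # library
    n_pairs: int = 2000
    arm_length: int = 70
    fragment_mean: float = 200.0
    fragment_sd: float = 50.0
    nonconversion_cpg: float = 0.0103
    nonconversion_chg: float = 0.0118
    nonconversion_chh: float = 0.0112
    sequencing_error: float = 0.001
    lambda_fraction: float = 0.0001
    # recovery
    min_identity: float = 0.90
    min_arm_length: int = 40
    max_meth_noncpg: int = 3
    # calling
    fdr: float = 0.01
    min_pairs: int = 5
    min_control_calls: int = 1000
    # stage toggles
    run_annotate: bool = True
    log_level: str = "INFO"

    def library_config(self, seed: int) -> sg.LibraryConfig:
        return sg.LibraryConfig(
            n_pairs=self.n_pairs,
            arm_length=self.arm_length,
            fragment_length=(self.fragment_mean, self.fragment_sd),
            nonconversion_rate={
                "CpG": self.nonconversion_cpg,
                "CHG": self.nonconversion_chg,
                "CHH": self.nonconversion_chh,
            },
            sequencing_error=self.sequencing_error,
            lambda_fraction=self.lambda_fraction,
            seed=seed,
        )

    def recovery_config(self) -> rc.RecoveryConfig:
        return rc.RecoveryConfig(
            min_identity=self.min_identity,
            min_arm_length=self.min_arm_length,
            max_meth_noncpg=self.max_meth_noncpg,
        )


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage seeds derived from one top-level seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def load_config(path) -> PipelineConfig:
    """Flat key-value config file: ``key = value`` lines, '#' comments.

    Values are coerced to the type of the corresponding default field;
    probability 4-tuples are comma-separated."""
    cfg = PipelineConfig()
    fields = {f.name: f for f in dataclasses.fields(cfg)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, bool):
            parsed = value.lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            parsed = int(value)
        elif isinstance(current, float):
            parsed = float(value)
        elif isinstance(current, tuple):
            parsed = tuple(float(x) for x in value.split(","))
        else:
            parsed = value
        setattr(cfg, key, parsed)
    return cfg


# ---------------------------------------------------------------------------
# track / table writers


def write_tracks(dyad_stats: pd.DataFrame, outdir, groups: pd.Series | None = None) -> None:
    """bedGraph tracks for ML and MF (each dyad spans its CG dinucleotide,
    [pos, pos+2)), and a BED of dyad groups when given. Values to 4 decimals."""
    outdir = Path(outdir)
    for col, fname in (("ml_corrected", "ml.bedGraph"), ("mf", "mf.bedGraph")):
        with open(outdir / fname, "w") as fh:
            fh.write(f'track type=bedGraph name="{col}"\n')
            for row in dyad_stats.itertuples(index=False):
                fh.write(
                    f"{row.reference}\t{row.position}\t{row.position + 2}\t"
                    f"{round(getattr(row, col), 4)}\n"
                )
    if groups is not None:
        with open(outdir / "dyad_groups.bed", "w") as fh:
            fh.write('track name="dyad_groups"\n')
            for row, grp in zip(dyad_stats.itertuples(index=False), groups):
                fh.write(f"{row.reference}\t{row.position}\t{row.position + 2}\t{grp}\n")


def write_significant_bed(site_stats: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write('track name="significant_sites"\n')
        sub = site_stats[site_stats["significant"]]
        for row in sub.itertuples(index=False):
            fh.write(
                f"{row.reference}\t{row.position}\t{row.position + 1}\t"
                f"{row.context}\t{round(row.pvalue, 4)}\t{row.strand}\n"
            )


def read_bed_regions(path, reference: str = "chrSim") -> list[ann.Region]:
    regions = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "#", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: malformed BED line")
        cls = parts[3] if len(parts) > 3 else "region"
        strand = parts[5] if len(parts) > 5 else "+"
        regions.append(ann.Region(parts[0] or reference, int(parts[1]), int(parts[2]), cls, strand))
    return regions


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full simulate -> recover -> call -> annotate chain.

    Writes all declared outputs under ``cfg.outdir`` and returns (and writes)
    a machine-readable summary in which every input read pair is accounted
    for exactly once.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(name)s %(levelname)s %(message)s")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)

    # --- simulate
    ref = sg.generate_reference(
        cfg.ref_length,
        cfg.gc_fraction,
        (cfg.cgi_count, cfg.cgi_length, cfg.cgi_boost) if cfg.cgi_count else None,
        seed=seeds[0],
        transcript_spec=(cfg.n_transcripts, cfg.transcript_length) if cfg.n_transcripts else None,
    )
    regimes = [((s, e), cfg.cgi_state) for s, e in ref.cgi_intervals]
    truth = sg.assign_truth(
        ref, regimes, noncpg_rate=cfg.noncpg_rate, default_state=cfg.background_state
    )
    lib = sg.simulate_library(ref, truth, cfg.library_config(seeds[1]))
    sg.write_fasta(ref, outdir / "reference.fa")
    if lib.control is not None:
        sg.write_fasta(lib.control, outdir / "control.fa")
    sg.write_fastq_pairs(lib.pairs, outdir / "reads_R1.fastq", outdir / "reads_R2.fastq")
    lib.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    logger.info("stage=simulate n_pairs=%d", len(lib.pairs))

    # --- recover
    rcfg = cfg.recovery_config()
    refs = [ref] + ([lib.control] if lib.control is not None else [])
    matcher = rc.ReferenceMatcher(refs)
    molecules, rejections, counts = rc.process_library(lib.pairs, rcfg, matcher)
    rc.write_molecules_tsv(molecules, outdir / "molecules.tsv")
    rejections.to_csv(outdir / "rejections.tsv", sep="\t", index=False)
    for reason in REJECTION_REASONS + (rc.ACCEPTED,):
        logger.info("stage=recover %s=%d", reason, counts.get(reason, 0))

    # --- call
    genome_mols = [m for m in molecules if m.locus and m.locus[0] == ref.name]
    control_mols = [m for m in molecules if m.locus and m.locus[0] != ref.name]
    site_df, dyad_df = mc.tally_calls(genome_mols, ref)
    r_est = {}
    if control_mols and lib.control is not None:
        csites, _ = mc.tally_calls(control_mols, lib.control)
        r_est = mc.estimate_nonconversion(csites)
    r_cfg = {"CpG": cfg.nonconversion_cpg, "CHG": cfg.nonconversion_chg,
             "CHH": cfg.nonconversion_chh}
    n_control_calls = sum(
        len(m.sequence) for m in control_mols
    )
    r_used = {
        ctx: (r_est[ctx] if r_est and np.isfinite(r_est.get(ctx, np.nan))
              and n_control_calls >= cfg.min_control_calls else r_cfg[ctx])
        for ctx in r_cfg
    }
    dyad_stats = mc.add_dyad_stats(dyad_df, r=r_used["CpG"])
    dyad_pass = mc.depth_filter(dyad_stats, cfg.min_pairs)
    site_stats = mc.add_site_stats(site_df, r_used)
    caller_cfg = mc.CallerConfig(
        p_null={ctx: min(0.099, max(1e-6, r_used[ctx] + cfg.sequencing_error)) for ctx in r_used},
        fdr=cfg.fdr,
        min_pairs=cfg.min_pairs,
    )
    site_stats = mc.binomial_caller(site_stats, caller_cfg)
    dyad_stats.to_csv(outdir / "dyads.tsv", sep="\t", index=False)
    site_stats.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    logger.info("stage=call dyads=%d dyads_pass=%d sites=%d",
                len(dyad_stats), len(dyad_pass), len(site_stats))

    # --- annotate
    groups = None
    if cfg.run_annotate:
        groups = ann.classify_dyads(dyad_pass, tol=0.05)
        regions = ann.define_regions(ref.transcript_models, ref.cgi_intervals, len(ref.sequence),
                                     reference=ref.name)
        with open(outdir / "regions.bed", "w") as fh:
            for rg in regions:
                fh.write(f"{rg.reference}\t{rg.start}\t{rg.end}\t{rg.cls}\t0\t{rg.strand}\n")
        hist, summary = ann.ml_mf_joint(dyad_pass)
        hist.to_csv(outdir / "ml_mf_hist.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "ml_mf_summary.tsv", sep="\t", index=False)
        write_tracks(dyad_pass, outdir, groups)
        write_significant_bed(site_stats, outdir / "significant_sites.bed")

    genome_region = (
        mc.region_stats(dyad_pass, 0, len(ref.sequence)) if len(dyad_pass) else (np.nan, np.nan, 0)
    )
    summary = {
        "seed": cfg.seed,
        "n_pairs": len(lib.pairs),
        "counts": {reason: int(counts.get(reason, 0)) for reason in REJECTION_REASONS + (rc.ACCEPTED,)},
        "n_dyads": int(len(dyad_stats)),
        "n_dyads_depth_pass": int(len(dyad_pass)),
        "n_sites": int(len(site_stats)),
        "n_significant_sites": int(site_stats["significant"].sum()) if len(site_stats) else 0,
        "nonconversion_used": {k: float(v) for k, v in r_used.items()},
        "mean_ml": float(genome_region[0]),
        "mean_mf": float(genome_region[1]),
        "dyad_groups": {g: int((groups == g).sum()) for g in ann.DYAD_GROUPS} if groups is not None else {},
    }
    assert sum(summary["counts"].values()) == len(lib.pairs)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("stage=done accepted=%d mean_ml=%.4f mean_mf=%.4f",
                summary["counts"][rc.ACCEPTED], summary["mean_ml"], summary["mean_mf"])
    return summary
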