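"""Methylation level and fidelity statistics from strand-resolved calls.

Definitions (per cytosine site, or per CpG dyad after merging the two
strand observations of each molecule):

* ML (methylation level) = reads(mC) / (reads(mC) + reads(C)); for dyads
  ML = (2*nMM + nMU + nUM) / (2 * depth) with depth = nMM+nMU+nUM+nUU.
* Corrected ML = max(0, (ML - r) / (1 - r)) where r is the per-context
  bisulfite non-conversion rate estimated from the unmethylated spike-in.
* MF (methylation fidelity) = (nMM + nUU) / depth, the fraction of molecules
  at a dyad that are symmetrically methylated or symmetrically unmethylated.
* The theoretical minimum MF at methylation level m is |2m - 1| (every
  possible strand observation paired hemi first).

Significantly methylated cytosines are called against Binomial(n, p_null)
with p_null the non-conversion-plus-error rate, Benjamini-Hochberg corrected
within each context.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .recover import METH, RecoveredMolecule
from .seqops import crick_context, watson_context
from .simulate import ReferenceModel

DYAD_COUNT_COLS = ["nMM", "nMU", "nUM", "nUU"]


@dataclass
class CallerConfig:
    """Binomial caller and depth-filter settings.

    ``p_null`` is the per-context null methylation probability (non-conversion
    plus sequencing error); a scalar applies to all contexts. ``min_pairs``
    read-pair observations per dyad equals 2*min_pairs strand observations,
    i.e. the default 5 pairs is a 10x depth requirement.
    """

    p_null: float | dict[str, float] = 0.012
    fdr: float = 0.01
    min_pairs: int = 5

    def __post_init__(self) -> None:
        if isinstance(self.p_null, (int, float)):
            self.p_null = {ctx: float(self.p_null) for ctx in ("CpG", "CHG", "CHH")}
        for ctx, p in self.p_null.items():
            if not 0.0 < p < 0.1:
                raise ValueError(f"p_null[{ctx}]={p} outside (0, 0.1)")
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr outside (0, 1)")


# ---------------------------------------------------------------------------
# tallying


def tally_calls(
    molecules: list[RecoveredMolecule],
    refs: ReferenceModel | dict[str, ReferenceModel] | list[ReferenceModel],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accumulate per-site and per-dyad count tables from mapped molecules.

    Recovered bases that disagree with the reference are masked (SNP masking:
    no call contributes at that position). Site tallies are keyed by
    (reference, position, strand) with context taken from the reference;
    dyad tallies merge the Watson and Crick observation of each molecule at
    reference CG dinucleotides into one of nMM/nMU/nUM/nUU.
    """
    if isinstance(refs, ReferenceModel):
        refs = {refs.name: refs}
    elif isinstance(refs, list):
        refs = {r.name: r for r in refs}

    sites: dict[tuple, list] = {}  # (ref, pos, strand) -> [context, n_meth, n_unmeth]
    dyads: dict[tuple, list] = {}  # (ref, pos) -> [nMM, nMU, nUM, nUU]

    for mol in molecules:
        if mol.locus is None:
            raise ValueError(f"molecule {mol.read_id} is not mapped")
        refname, start, _strand = mol.locus
        ref = refs[refname]
        rseq = ref.sequence
        seq = mol.sequence
        if start < 0 or start + len(seq) > len(rseq):
            raise ValueError(f"locus of {mol.read_id} outside reference {refname}")

        ok = [seq[i] == rseq[start + i] for i in range(len(seq))]  # N never matches: masked

        for i in range(len(seq)):
            if not ok[i]:
                continue
            p = start + i
            call = mol.watson_calls[i]
            if call != "." and rseq[p] == "C":
                key = (refname, p, "+")
                rec = sites.get(key)
                if rec is None:
                    rec = sites[key] = [watson_context(rseq, p), 0, 0]
                rec[1 if call == METH else 2] += 1
            call = mol.crick_calls[i]
            if call != "." and rseq[p] == "G":
                key = (refname, p, "-")
                rec = sites.get(key)
                if rec is None:
                    rec = sites[key] = [crick_context(rseq, p), 0, 0]
                rec[1 if call == METH else 2] += 1

        for i in range(len(seq) - 1):
            p = start + i
            if rseq[p] == "C" and rseq[p + 1] == "G" and ok[i] and ok[i + 1]:
                w = mol.watson_calls[i]
                c = mol.crick_calls[i + 1]
                if w == "." or c == ".":
                    continue
                key = (refname, p)
                rec = dyads.get(key)
                if rec is None:
                    rec = dyads[key] = [0, 0, 0, 0]
                idx = {"MM": 0, "MU": 1, "UM": 2, "UU": 3}[w + c]
                rec[idx] += 1

    site_df = pd.DataFrame(
        [(k[0], k[1], k[2], v[0], v[1], v[2]) for k, v in sorted(sites.items())],
        columns=["reference", "position", "strand", "context", "n_meth", "n_unmeth"],
    )
    dyad_df = pd.DataFrame(
        [(k[0], k[1], *v) for k, v in sorted(dyads.items())],
        columns=["reference", "position"] + DYAD_COUNT_COLS,
    )
    return site_df, dyad_df


def estimate_nonconversion(control_sites: pd.DataFrame) -> dict[str, float]:
    """Per-context non-conversion rate from an unmethylated control.

    r_context = sum(n_meth) / sum(n_meth + n_unmeth) over control cytosines of
    that context; contexts without coverage come back NaN.
    """
    out: dict[str, float] = {}
    for ctx in ("CpG", "CHG", "CHH"):
        sub = control_sites[control_sites["context"] == ctx] if len(control_sites) else control_sites
        total = int(sub["n_meth"].sum() + sub["n_unmeth"].sum()) if len(sub) else 0
        out[ctx] = float(sub["n_meth"].sum()) / total if total else float("nan")
    return out


# ---------------------------------------------------------------------------
# the two statistics


def correct_ml(ml_raw, r: float):
    """Non-conversion correction (ML - r)/(1 - r), floored at zero."""
    return np.maximum(0.0, (np.asarray(ml_raw, dtype=float) - r) / (1.0 - r))


def methylation_level(n_meth, n_unmeth, r: float = 0.0):
    """(ml_raw, ml_corrected) for site counts; NaN at zero depth."""
    n_meth = np.asarray(n_meth, dtype=float)
    depth = n_meth + np.asarray(n_unmeth, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(depth > 0, n_meth / np.where(depth > 0, depth, 1), np.nan)
    return raw, correct_ml(raw, r)


def dyad_methylation_level(nMM, nMU, nUM, nUU, r: float = 0.0):
    """(ml_raw, ml_corrected) for dyad counts; each pair carries two strand
    observations, so the denominator is 2*depth."""
    nMM, nMU, nUM, nUU = (np.asarray(x, dtype=float) for x in (nMM, nMU, nUM, nUU))
    depth = nMM + nMU + nUM + nUU
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(depth > 0, (2 * nMM + nMU + nUM) / np.where(depth > 0, 2 * depth, 1), np.nan)
    return raw, correct_ml(raw, r)


def methylation_fidelity(nMM, nMU, nUM, nUU):
    """MF = (nMM + nUU) / depth; NaN at zero depth."""
    nMM, nMU, nUM, nUU = (np.asarray(x, dtype=float) for x in (nMM, nMU, nUM, nUU))
    depth = nMM + nMU + nUM + nUU
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(depth > 0, (nMM + nUU) / np.where(depth > 0, depth, 1), np.nan)


def theoretical_min_mf(ml):
    """Lowest fidelity achievable at methylation level ``ml``: |2*ml - 1|
    (pair every methylated strand observation with an unmethylated one
    first; the surplus is forced into symmetric dyads)."""
    return np.abs(2.0 * np.asarray(ml, dtype=float) - 1.0)


def add_dyad_stats(dyad_df: pd.DataFrame, r: float = 0.0) -> pd.DataFrame:
    """Append depth, ml_raw, ml_corrected and mf columns to a dyad tally."""
    out = dyad_df.copy()
    out["depth"] = out[DYAD_COUNT_COLS].sum(axis=1)
    raw, corr = dyad_methylation_level(out.nMM, out.nMU, out.nUM, out.nUU, r)
    out["ml_raw"] = raw
    out["ml_corrected"] = corr
    out["mf"] = methylation_fidelity(out.nMM, out.nMU, out.nUM, out.nUU)
    return out


def add_site_stats(site_df: pd.DataFrame, r_by_context: dict[str, float] | float = 0.0) -> pd.DataFrame:
    out = site_df.copy()
    out["depth"] = out["n_meth"] + out["n_unmeth"]
    if isinstance(r_by_context, (int, float)):
        r_by_context = {ctx: float(r_by_context) for ctx in ("CpG", "CHG", "CHH")}
    raw = np.where(out["depth"] > 0, out["n_meth"] / out["depth"].clip(lower=1), np.nan)
    out["ml_raw"] = raw
    r = out["context"].map(r_by_context).to_numpy(dtype=float)
    out["ml_corrected"] = np.maximum(0.0, (raw - r) / (1.0 - r))
    return out


def depth_filter(dyad_stats: pd.DataFrame, min_pairs: int = 5) -> pd.DataFrame:
    """Keep dyads with >= min_pairs read-pair observations (2*min_pairs
    strand observations, so the default is the 10x rule)."""
    if len(dyad_stats) == 0:
        return dyad_stats
    depth = (
        dyad_stats["depth"]
        if "depth" in dyad_stats.columns
        else dyad_stats[DYAD_COUNT_COLS].sum(axis=1)
    )
    return dyad_stats[depth >= min_pairs].reset_index(drop=True)


# ---------------------------------------------------------------------------
# binomial methylation caller


def binomial_caller(site_df: pd.DataFrame, cfg: CallerConfig) -> pd.DataFrame:
    """Flag significantly methylated cytosines.

    Per site, p-value = P(X >= n_meth) for X ~ Binomial(depth, p_null of its
    context); Benjamini-Hochberg within each context at ``cfg.fdr``.
    """
    out = site_df.copy()
    depth = (out["n_meth"] + out["n_unmeth"]).to_numpy()
    p_null = out["context"].map(cfg.p_null).to_numpy(dtype=float)
    out["pvalue"] = sps.binom.sf(out["n_meth"].to_numpy() - 1, depth, p_null)
    out["qvalue"] = np.nan
    out["significant"] = False
    for ctx in out["context"].unique():
        mask = (out["context"] == ctx).to_numpy()
        if mask.sum() == 0:
            continue
        reject, qvals, _, _ = multipletests(
            out.loc[mask, "pvalue"].to_numpy(), alpha=cfg.fdr, method="fdr_bh"
        )
        out.loc[mask, "qvalue"] = qvals
        out.loc[mask, "significant"] = reject
    return out


# ---------------------------------------------------------------------------
# regional statistics, concordance, sample comparison


def region_stats(
    dyad_df: pd.DataFrame,
    start: int,
    end: int,
    r: float = 0.0,
    reference: str | None = None,
) -> tuple[float, float, int]:
    """Count-weighted (pooled) regional ML and MF over [start, end).

    Counts are pooled across dyads before applying the formulas, so deep
    dyads weigh more than shallow ones (weighted, not mean-of-fractions).
    Returns (ml_corrected, mf, n_sites); NaNs when no dyad is covered.
    """
    sub = dyad_df[(dyad_df["position"] >= start) & (dyad_df["position"] < end)]
    if reference is not None:
        sub = sub[sub["reference"] == reference]
    if len(sub) == 0:
        return float("nan"), float("nan"), 0
    nMM, nMU, nUM, nUU = (int(sub[c].sum()) for c in DYAD_COUNT_COLS)
    _, ml = dyad_methylation_level(nMM, nMU, nUM, nUU, r)
    mf = methylation_fidelity(nMM, nMU, nUM, nUU)
    return float(ml), float(mf), len(sub)


def strand_concordance(nMM: int, nMU: int, nUM: int, nUU: int) -> float:
    """Phi (Pearson) correlation between the binary Watson and Crick calls of
    paired strand observations, from their pooled 2x2 table. NaN when either
    margin has zero variance."""
    a, b, c, d = float(nMM), float(nMU), float(nUM), float(nUU)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    return (a * d - b * c) / np.sqrt(denom)


def cpg_concordance(dyad_df: pd.DataFrame) -> float:
    """Genome-wide Watson/Crick concordance of CpG calls (pooled dyads)."""
    return strand_concordance(*(int(dyad_df[c].sum()) for c in DYAD_COUNT_COLS))


def paired_noncpg_table(
    molecules: list[RecoveredMolecule],
    refs: ReferenceModel | dict[str, ReferenceModel],
    context: str = "CHG",
) -> tuple[int, int, int, int]:
    """2x2 table of paired strand calls at strand-symmetric non-CpG sites.

    Only CHG has a strand-symmetric cytosine (Watson C at i pairs the Crick C
    at i+2 when both sides read CHG); CHH has no counterpart on the opposite
    strand, so requesting it is an error.
    """
    if context != "CHG":
        raise ValueError("only CHG has a strand-symmetric non-CpG counterpart")
    if isinstance(refs, ReferenceModel):
        refs = {refs.name: refs}
    counts = [0, 0, 0, 0]
    for mol in molecules:
        if mol.locus is None:
            continue
        refname, start, _ = mol.locus
        rseq = refs[refname].sequence
        seq = mol.sequence
        for i in range(len(seq) - 2):
            p = start + i
            if (
                rseq[p] == "C"
                and watson_context(rseq, p) == "CHG"
                and crick_context(rseq, p + 2) == "CHG"
                and seq[i] == rseq[p]
                and seq[i + 2] == rseq[p + 2]
            ):
                w = mol.watson_calls[i]
                c = mol.crick_calls[i + 2]
                if w == "." or c == ".":
                    continue
                counts[{"MM": 0, "MU": 1, "UM": 2, "UU": 3}[w + c]] += 1
    return tuple(counts)  # type: ignore[return-value]


def compare_samples(
    stats_a: pd.DataFrame, stats_b: pd.DataFrame, delta: float = 0.2
) -> dict[str, float]:
    """Fractions of shared dyads whose ML / MF change by more than ``delta``
    between two depth-filtered samples (B relative to A)."""
    merged = stats_a.merge(
        stats_b, on=["reference", "position"], suffixes=("_a", "_b"), how="inner"
    )
    if len(merged) == 0:
        raise ValueError("no shared dyads between samples")
    n = len(merged)
    d_ml = merged["ml_corrected_b"] - merged["ml_corrected_a"]
    d_mf = merged["mf_b"] - merged["mf_a"]
    return {
        "frac_ml_up": float((d_ml > delta).sum()) / n,
        "frac_ml_down": float((d_ml < -delta).sum()) / n,
        "frac_mf_up": float((d_mf > delta).sum()) / n,
        "frac_mf_down": float((d_mf < -delta).sum()) / n,
        "n_shared": n,
    }
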