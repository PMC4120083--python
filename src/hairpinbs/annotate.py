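"""Genomic-context analyses of dyad methylation level and fidelity.

Coordinates are 0-based half-open throughout; BED exports are native,
TSV exports add 1-based columns where labelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylation import theoretical_min_mf
from .simulate import ReferenceModel

logger = logging.getLogger(__name__)

DYAD_GROUPS = ("UNMETH_FULL", "METH_FULL", "HALF_MF0", "HALF_MF100", "OTHER")


@dataclass
class Region:
    reference: str
    start: int
    end: int
    cls: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region [{self.start}, {self.end})")


# ---------------------------------------------------------------------------
# region definitions


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def define_regions(
    transcripts: list[tuple[int, int, str]],
    cgis: list[tuple[int, int]],
    reference_length: int,
    reference: str = "chrSim",
    promoter_size: int = 1000,
    shore_size: int = 2000,
    intergenic_pad: int = 10000,
) -> list[Region]:
    """Promoters (1 kb upstream of the TSS, strand-aware), CGIs and their
    shores, genic intervals, and intergenic space (outside the 10-kb genic
    flanks). Intervals are clipped at contig edges."""
    regions: list[Region] = []
    genic: list[tuple[int, int]] = []
    for start, end, strand in transcripts:
        genic.append((start, end))
        if strand == "+":
            p0, p1 = start - promoter_size, start
        else:
            p0, p1 = end, end + promoter_size
        p0, p1 = max(0, p0), min(reference_length, p1)
        if p0 < p1:
            regions.append(Region(reference, p0, p1, "promoter", strand))
        regions.append(Region(reference, start, end, "genic", strand))

    for s, e in cgis:
        regions.append(Region(reference, s, e, "CGI"))
        for f0, f1 in ((s - shore_size, s), (e, e + shore_size)):
            f0, f1 = max(0, f0), min(reference_length, f1)
            if f0 < f1:
                regions.append(Region(reference, f0, f1, "CGI_shore"))

    padded = _merge_intervals(
        [(max(0, s - intergenic_pad), min(reference_length, e + intergenic_pad)) for s, e in genic]
    )
    cursor = 0
    for s, e in padded:
        if cursor < s:
            regions.append(Region(reference, cursor, s, "intergenic"))
        cursor = max(cursor, e)
    if cursor < reference_length:
        regions.append(Region(reference, cursor, reference_length, "intergenic"))
    return regions


# ---------------------------------------------------------------------------
# profiles


def element_profile(
    elements: list[Region],
    stats: pd.DataFrame,
    mode: str = "bins20",
    n_bins: int = 20,
    window_width: int = 200,
    span: int = 2000,
) -> pd.DataFrame:
    """Mean ML/MF profile across a set of elements.

    ``bins20`` mode divides each element into ``n_bins`` equal bins (bin order
    flipped for minus-strand elements), pools dyad counts within each
    element-bin, and averages the per-element values bin-wise. ``window``
    mode pools counts in ``window_width``-bp windows tiled over +/-``span``
    around each element's midpoint. Returns a frame with bin_index, mean_ml,
    mean_mf, n_sites. ``stats`` must carry nMM..nUU plus position/reference.
    """
    from .methylation import DYAD_COUNT_COLS, dyad_methylation_level, methylation_fidelity

    if mode == "bins20":
        acc_ml: dict[int, list[float]] = {b: [] for b in range(n_bins)}
        acc_mf: dict[int, list[float]] = {b: [] for b in range(n_bins)}
        nsites = {b: 0 for b in range(n_bins)}
        for el in elements:
            if el.end - el.start < n_bins:
                logger.info("skipping element [%d,%d): shorter than %d bins", el.start, el.end, n_bins)
                continue
            sub = stats[
                (stats["reference"] == el.reference)
                & (stats["position"] >= el.start)
                & (stats["position"] < el.end)
            ]
            if len(sub) == 0:
                continue
            rel = (sub["position"] - el.start) / (el.end - el.start)
            bins = np.minimum((rel * n_bins).astype(int), n_bins - 1)
            if el.strand == "-":
                bins = n_bins - 1 - bins
            for b in np.unique(bins):
                grp = sub[bins == b]
                counts = [int(grp[c].sum()) for c in DYAD_COUNT_COLS]
                _, ml = dyad_methylation_level(*counts)
                acc_ml[int(b)].append(float(ml))
                acc_mf[int(b)].append(float(methylation_fidelity(*counts)))
                nsites[int(b)] += len(grp)
        rows = [
            {
                "bin_index": b,
                "mean_ml": float(np.mean(acc_ml[b])) if acc_ml[b] else np.nan,
                "mean_mf": float(np.mean(acc_mf[b])) if acc_mf[b] else np.nan,
                "n_sites": nsites[b],
            }
            for b in range(n_bins)
        ]
        return pd.DataFrame(rows)

    if mode == "window":
        k_max = span // window_width
        offsets = range(-k_max, k_max + 1)
        rows = []
        for k in offsets:
            counts = np.zeros(4, dtype=int)
            n_sites = 0
            for el in elements:
                center = (el.start + el.end) // 2
                w0 = center + k * window_width - window_width // 2
                w1 = w0 + window_width
                sub = stats[
                    (stats["reference"] == el.reference)
                    & (stats["position"] >= w0)
                    & (stats["position"] < w1)
                ]
                counts += sub[DYAD_COUNT_COLS].sum().to_numpy(dtype=int)
                n_sites += len(sub)
            if counts.sum() > 0:
                _, ml = dyad_methylation_level(*counts)
                mf = methylation_fidelity(*counts)
            else:
                ml = mf = np.nan
            rows.append(
                {"bin_index": k, "mean_ml": float(ml), "mean_mf": float(mf), "n_sites": n_sites}
            )
        return pd.DataFrame(rows)

    raise ValueError(f"unknown profile mode {mode!r}")


# ---------------------------------------------------------------------------
# dyad groups and the joint ML x MF distribution


def classify_dyads(
    stats: pd.DataFrame,
    ml_half_band: tuple[float, float] = (0.4, 0.6),
    tol: float = 0.0,
) -> pd.Series:
    """Assign each depth-filtered dyad to one of five groups: fully
    unmethylated, fully methylated, half-methylated with 0% or 100% fidelity
    (within ``tol``), or OTHER."""
    ml = stats["ml_corrected"].to_numpy(dtype=float)
    mf = stats["mf"].to_numpy(dtype=float)
    lo, hi = ml_half_band
    in_band = (ml >= lo) & (ml <= hi)
    out = np.full(len(stats), "OTHER", dtype=object)
    out[(ml <= tol) & (mf >= 1 - tol)] = "UNMETH_FULL"
    out[(ml >= 1 - tol) & (mf >= 1 - tol)] = "METH_FULL"
    out[in_band & (mf <= tol)] = "HALF_MF0"
    out[in_band & (mf >= 1 - tol)] = "HALF_MF100"
    return pd.Series(out, index=stats.index, name="group")


def ml_mf_joint(
    stats: pd.DataFrame, n_ml_intervals: int = 10, n_mf_bins: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Joint distribution of fidelity across methylation-level intervals.

    Dyads are partitioned into ``n_ml_intervals`` ML intervals ([0.9, 1.0]
    closed at the top); within each, an MF histogram plus summary fractions:
    dyads with MF >= 0.9 and dyads within 0.1 of the theoretical minimum.
    Returns (histogram, summary)."""
    ml = stats["ml_corrected"].to_numpy(dtype=float)
    mf = stats["mf"].to_numpy(dtype=float)
    iv = np.minimum((ml * n_ml_intervals).astype(int), n_ml_intervals - 1)
    hist_rows = []
    summary_rows = []
    edges = np.linspace(0, 1, n_mf_bins + 1)
    for k in range(n_ml_intervals):
        mask = iv == k
        sub_mf = mf[mask]
        counts, _ = np.histogram(sub_mf, bins=edges)
        hist_rows.append({"ml_interval": k, **{f"mf_bin{b}": int(c) for b, c in enumerate(counts)}})
        n = int(mask.sum())
        if n:
            near_min = np.mean(sub_mf <= theoretical_min_mf(ml[mask]) + 0.1)
            high = np.mean(sub_mf >= 0.9)
        else:
            near_min = high = np.nan
        summary_rows.append(
            {
                "ml_interval": k,
                "ml_lo": k / n_ml_intervals,
                "ml_hi": (k + 1) / n_ml_intervals,
                "n_dyads": n,
                "frac_mf_ge_0.9": float(high),
                "frac_mf_near_min": float(near_min),
            }
        )
    return pd.DataFrame(hist_rows), pd.DataFrame(summary_rows)


# ---------------------------------------------------------------------------
# sequence context of sites


def cpg_obs_exp(
    ref: ReferenceModel, center: int, flank: int = 100
) -> tuple[float, float]:
    """CpG density and observed/expected ratio of the window around a site.

    density = #CG / L; obs_exp = (#CG * L) / (#C * #G) over the window of
    length L (clipped at contig edges). obs_exp is NaN when #C or #G is 0,
    and 0 when the window has no CG."""
    seq = ref.sequence[max(0, center - flank) : min(len(ref.sequence), center + flank)]
    length = len(seq)
    n_cg = sum(1 for i in range(length - 1) if seq[i] == "C" and seq[i + 1] == "G")
    n_c = seq.count("C")
    n_g = seq.count("G")
    density = n_cg / length if length else float("nan")
    if n_c == 0 or n_g == 0:
        return density, float("nan")
    return density, (n_cg * length) / (n_c * n_g)


def flanking_base_freqs(
    sites: list[int], ref: ReferenceModel, flank: int
) -> pd.DataFrame:
    """Base frequency matrix over offsets -flank..+flank across sites.

    Rows sum to 1; offsets that run off the contig for some sites are
    computed over the sites that remain (frequency-matrix form of a sequence
    logo)."""
    if not sites:
        raise ValueError("no sites given")
    seq = ref.sequence
    n = len(seq)
    rows = []
    for off in range(-flank, flank + 1):
        counts = {b: 0 for b in "ACGT"}
        total = 0
        for s in sites:
            p = s + off
            if 0 <= p < n and seq[p] in counts:
                counts[seq[p]] += 1
                total += 1
        freq = {b: (counts[b] / total if total else float("nan")) for b in "ACGT"}
        rows.append({"offset": off, **freq, "n_sites": total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enrichment and expression groups


def overlap_enrichment(
    group_sites: list[int],
    regions: list[Region] | list[tuple[int, int]],
    background_sites: list[int],
) -> tuple[float, int, float]:
    """Fold enrichment of a site group inside a region set relative to a
    background site set. Returns (fold, observed, expected); fold is NaN when
    the background never overlaps the regions."""
    ivs = [
        (r.start, r.end) if isinstance(r, Region) else (r[0], r[1]) for r in regions
    ]
    merged = _merge_intervals(ivs)
    if not merged or not group_sites or not background_sites:
        raise ValueError("empty input")
    starts = np.array([s for s, _ in merged])
    ends = np.array([e for _, e in merged])

    def inside(points: list[int]) -> int:
        p = np.asarray(points)
        idx = np.searchsorted(starts, p, side="right") - 1
        ok = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
        return int(ok.sum())

    obs = inside(group_sites)
    frac_bg = inside(background_sites) / len(background_sites)
    expected = frac_bg * len(group_sites)
    if frac_bg == 0:
        return float("nan"), obs, expected
    fold = (obs / len(group_sites)) / frac_bg
    return fold, obs, expected


def expression_groups(expression: dict[str, float] | pd.Series, k: int = 5) -> dict[str, int]:
    """Rank genes into ``k`` expression groups: group 1 = no detectable
    expression; the remaining genes split into k-1 quantile groups of sizes
    differing by at most one (ties broken by gene identifier)."""
    if isinstance(expression, pd.Series):
        expression = expression.to_dict()
    if not expression:
        raise ValueError("empty expression table")
    if any(v < 0 for v in expression.values()):
        raise ValueError("expression scores must be >= 0")
    groups: dict[str, int] = {}
    nonzero = sorted(
        (g for g, v in expression.items() if v > 0), key=lambda g: (expression[g], g)
    )
    for g, v in expression.items():
        if v == 0:
            groups[g] = 1
    chunks = np.array_split(np.array(nonzero, dtype=object), k - 1) if nonzero else []
    for gi, chunk in enumerate(chunks, start=2):
        for g in chunk:
            groups[g] = gi
    return groups
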