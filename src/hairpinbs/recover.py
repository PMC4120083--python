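"""Recover original molecules from hairpin bisulfite read pairs.

The two arms of a hairpin read pair are bisulfite images of the two strands
of one DNA fragment. Processing runs trim -> reduce -> align -> filter ->
recover -> map:

1. locate and trim the hairpin adaptor (and its converted variants) from both
   reads; arms shorter than ``min_arm_length`` are rejected (SHORT);
2. collapse both arms to the reduced bisulfite alphabet (C->T on the Watson
   arm view, i.e. every C becomes T and every G becomes A) so that conversion
   differences do not count as mismatches;
3. align the reduced arms with a global Needleman-Wunsch/Gotoh affine-gap
   alignment, trim terminal-gap overhangs, and reject pairs whose reduced
   identity over the aligned core is below ``min_identity`` (LOW_IDENTITY);
4. recover the original sequence column by column: each (arm1, arm2) base
   combination identifies the original base and, at cytosines, the
   strand-resolved methylation state; inconsistent columns become N;
5. reject molecules with more than ``max_meth_noncpg`` methylated non-CpG
   cytosines on either strand arm — the signature of failed bisulfite
   conversion (UNCONVERTED);
6. map the recovered sequence uniquely to the reference (UNMAPPED /
   MULTIMAPPED otherwise).

Each read pair receives exactly one terminal status, in that order.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .seqops import c_to_t, g_to_a, revcomp
from .simulate import DEFAULT_HAIRPIN, ReferenceModel

# terminal statuses
ACCEPTED = "ACCEPTED"
SHORT = "SHORT"
LOW_IDENTITY = "LOW_IDENTITY"
UNCONVERTED = "UNCONVERTED"
UNMAPPED = "UNMAPPED"
MULTIMAPPED = "MULTIMAPPED"

# per-position call codes
METH = "M"
UNMETH = "U"
NOCALL = "."


@dataclass
class RecoveryConfig:
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    min_identity: float = 0.90
    min_arm_length: int = 40
    max_meth_noncpg: int = 3
    hairpin_sequence: str = DEFAULT_HAIRPIN
    max_hairpin_mismatches: int = 2
    min_hairpin_overlap: int = 8
    max_map_mismatches: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        for name in ("min_arm_length", "max_meth_noncpg", "max_hairpin_mismatches",
                     "min_hairpin_overlap", "max_map_mismatches"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Rejection:
    read_id: str
    reason: str


@dataclass
class ArmPair:
    read_id: str
    arm1: str  # Watson bisulfite arm
    arm2: str  # Crick bisulfite arm, Watson orientation


@dataclass
class ArmAlignment:
    read_id: str
    columns: list[tuple[str, str]]  # original bases, '-' for gaps; overhangs trimmed
    score: float
    identity: float


@dataclass
class RecoveredMolecule:
    read_id: str
    sequence: str
    watson_calls: str  # per position: M / U / .
    crick_calls: str
    locus: Optional[tuple[str, int, str]] = None  # (reference, start, strand)


# ---------------------------------------------------------------------------
# hairpin trimming


def _hamming_at_most(a: str, b: str, limit: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def hairpin_variants(hairpin: str) -> list[str]:
    """Forms the adaptor can take in a read: raw, C->T and G->A converted,
    for both the adaptor and its reverse complement (read 2 traverses the
    complementary PCR strand)."""
    rc = revcomp(hairpin)
    seen: list[str] = []
    for v in (hairpin, c_to_t(hairpin), g_to_a(hairpin), rc, c_to_t(rc), g_to_a(rc)):
        if v not in seen:
            seen.append(v)
    return seen


def _trim_read(read: str, variants: list[str], cfg: RecoveryConfig) -> str:
    cut = len(read)
    for v in variants:
        lv = len(v)
        for start in range(0, len(read) - lv + 1):
            if start >= cut:
                break
            if _hamming_at_most(read[start : start + lv], v, cfg.max_hairpin_mismatches):
                cut = start
                break
        # partial adaptor prefix hanging off the 3' end: exact match in the
        # converted alphabet, minimum overlap enforced
        max_k = min(lv, len(read), cut)
        for k in range(max_k, cfg.min_hairpin_overlap - 1, -1):
            pos = len(read) - k
            if pos >= cut:
                continue
            if c_to_t(g_to_a(read[pos:])) == c_to_t(g_to_a(v[:k])):
                cut = pos
                break
    return read[:cut]


def find_and_trim_hairpin(
    raw_read1: str, raw_read2: str, cfg: RecoveryConfig, read_id: str = ""
) -> ArmPair | Rejection:
    """Trim adaptor/hairpin sequence from both reads; reject short arms."""
    if not raw_read1 or not raw_read2:
        raise ValueError("empty read")
    variants = hairpin_variants(cfg.hairpin_sequence)
    arm1 = _trim_read(raw_read1, variants, cfg)
    arm2 = _trim_read(raw_read2, variants, cfg)
    if len(arm1) < cfg.min_arm_length or len(arm2) < cfg.min_arm_length:
        return Rejection(read_id, SHORT)
    return ArmPair(read_id=read_id, arm1=arm1, arm2=arm2)


# ---------------------------------------------------------------------------
# reduced-alphabet global alignment (Gotoh affine gaps)


def reduce_alphabet(seq: str) -> str:
    """Collapse bisulfite ambiguity: C->T and G->A; N passes through."""
    return c_to_t(g_to_a(seq))


_NEG = float("-inf")


def _gotoh(a: str, b: str, cfg: RecoveryConfig):
    """Global affine-gap alignment of ``a`` vs ``b``.

    A gap run of length L costs gap_open + (L-1)*gap_extend. Returns
    (score, moves) where moves is the traceback path as 'D' (diagonal),
    'U' (consume a), 'L' (consume b), tie-broken in that order.
    """
    n, m = len(a), len(b)
    go, ge = cfg.gap_open, cfg.gap_extend
    ms, mx = cfg.match_score, cfg.mismatch_score

    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0][j] = go + (j - 1) * ge

    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = ms if ai == b[j - 1] else mx
            Mi[j] = s + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mp[j] + go, Xp[j] + ge, Yp[j] + go)
            Yi[j] = max(Mi[j - 1] + go, Xi[j - 1] + go, Yi[j - 1] + ge)

    end_scores = (M[n][m], X[n][m], Y[n][m])
    score = max(end_scores)
    state = "MXY"[end_scores.index(score)]

    moves: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            moves.append("D")
            prev = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            state = "MXY"[prev.index(max(prev))]
            i -= 1
            j -= 1
        elif state == "X":
            moves.append("U")
            cand = (M[i - 1][j] + go, X[i - 1][j] + ge, Y[i - 1][j] + go)
            state = "MXY"[cand.index(max(cand))]
            i -= 1
        else:
            moves.append("L")
            cand = (M[i][j - 1] + go, X[i][j - 1] + go, Y[i][j - 1] + ge)
            state = "MXY"[cand.index(max(cand))]
            j -= 1
    moves.reverse()
    return score, moves


def align_arms(pair: ArmPair, cfg: RecoveryConfig) -> ArmAlignment | Rejection:
    """Align the reduced arms globally; trim overhangs; apply identity filter.

    Identity is computed in the reduced alphabet over columns of the trimmed
    core where both arms contribute a base; the columns themselves carry the
    original bases for downstream recovery.
    """
    ra, rb = reduce_alphabet(pair.arm1), reduce_alphabet(pair.arm2)
    score, moves = _gotoh(ra, rb, cfg)

    columns: list[tuple[str, str]] = []
    i = j = 0
    for mv in moves:
        if mv == "D":
            columns.append((pair.arm1[i], pair.arm2[j]))
            i += 1
            j += 1
        elif mv == "U":
            columns.append((pair.arm1[i], "-"))
            i += 1
        else:
            columns.append(("-", pair.arm2[j]))
            j += 1

    lo, hi = 0, len(columns)
    while lo < hi and ("-" in columns[lo]):
        lo += 1
    while hi > lo and ("-" in columns[hi - 1]):
        hi -= 1
    core = columns[lo:hi]

    matches = paired = 0
    for x, y in core:
        if x != "-" and y != "-":
            paired += 1
            if reduce_alphabet(x) == reduce_alphabet(y):
                matches += 1
    identity = matches / paired if paired else 0.0
    if identity < cfg.min_identity:
        return Rejection(pair.read_id, LOW_IDENTITY)
    return ArmAlignment(read_id=pair.read_id, columns=core, score=score, identity=identity)


# ---------------------------------------------------------------------------
# sequence recovery

# (arm1 base, arm2 base) -> (original base, watson call, crick call).
# arm1 is the converted Watson strand, arm2 the converted Crick strand in
# Watson orientation; every consistent combination has a unique pre-image.
_RECOVERY_TABLE = {
    ("A", "A"): ("A", NOCALL, NOCALL),
    ("T", "T"): ("T", NOCALL, NOCALL),
    ("C", "C"): ("C", METH, NOCALL),    # Watson C resisted conversion
    ("T", "C"): ("C", UNMETH, NOCALL),  # Watson C converted; Crick G untouched
    ("G", "G"): ("G", NOCALL, METH),    # Crick C resisted conversion
    ("G", "A"): ("G", NOCALL, UNMETH),  # Crick C converted
}


def recover_original(aln: ArmAlignment) -> RecoveredMolecule:
    """Apply the recovery table column-wise; inconsistent columns become N."""
    seq = []
    wcalls = []
    ccalls = []
    for col in aln.columns:
        base, w, c = _RECOVERY_TABLE.get(col, ("N", NOCALL, NOCALL))
        seq.append(base)
        wcalls.append(w)
        ccalls.append(c)
    return RecoveredMolecule(
        read_id=aln.read_id,
        sequence="".join(seq),
        watson_calls="".join(wcalls),
        crick_calls="".join(ccalls),
    )


def nonconversion_filter(mol: RecoveredMolecule, cfg: RecoveryConfig) -> Optional[Rejection]:
    """Reject molecules whose either strand arm shows more than
    ``max_meth_noncpg`` methylated non-CpG cytosines (incomplete conversion).
    Context is taken from the recovered sequence."""
    seq = mol.sequence
    n = len(seq)
    watson = sum(
        1
        for i in range(n)
        if seq[i] == "C"
        and mol.watson_calls[i] == METH
        and not (i + 1 < n and seq[i + 1] == "G")
    )
    crick = sum(
        1
        for i in range(n)
        if seq[i] == "G"
        and mol.crick_calls[i] == METH
        and not (i - 1 >= 0 and seq[i - 1] == "C")
    )
    if watson > cfg.max_meth_noncpg or crick > cfg.max_meth_noncpg:
        return Rejection(mol.read_id, UNCONVERTED)
    return None


# ---------------------------------------------------------------------------
# unique mapping


class ReferenceMatcher:
    """Exhaustive forward-strand matcher with mismatch tolerance.

    Finds every occurrence of a query on the forward strand of one or more
    desk-scale references, treating N in the query as a wildcard. Stands in
    for an external short-read aligner; externally produced alignments can be
    ingested by setting ``RecoveredMolecule.locus`` directly.
    """

    def __init__(self, refs: ReferenceModel | Iterable[ReferenceModel]):
        if isinstance(refs, ReferenceModel):
            refs = [refs]
        self._refs = [(r.name, np.frombuffer(r.sequence.encode(), dtype=np.uint8)) for r in refs]

    def locate(self, seq: str, max_mismatches: int = 2) -> list[tuple[str, int]]:
        q = np.frombuffer(seq.encode(), dtype=np.uint8)
        valid = q != ord("N")
        if not valid.any():
            return []
        hits: list[tuple[str, int]] = []
        for name, arr in self._refs:
            if arr.size < q.size:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, q.size)[:, valid]
            mism = (windows != q[valid]).sum(axis=1)
            for pos in np.nonzero(mism <= max_mismatches)[0]:
                hits.append((name, int(pos)))
        return hits


def map_to_reference(
    mol: RecoveredMolecule, matcher: ReferenceMatcher | ReferenceModel, cfg: RecoveryConfig
) -> RecoveredMolecule | Rejection:
    """Place the recovered sequence uniquely on the reference forward strand."""
    if isinstance(matcher, ReferenceModel):
        matcher = ReferenceMatcher(matcher)
    hits = matcher.locate(mol.sequence, cfg.max_map_mismatches)
    if not hits:
        return Rejection(mol.read_id, UNMAPPED)
    if len(hits) > 1:
        return Rejection(mol.read_id, MULTIMAPPED)
    name, pos = hits[0]
    return dataclasses.replace(mol, locus=(name, pos, "+"))


# ---------------------------------------------------------------------------
# pipeline over a library


def process_pair(
    read_id: str,
    read1: str,
    read2: str,
    cfg: RecoveryConfig,
    matcher: Optional[ReferenceMatcher] = None,
) -> RecoveredMolecule | Rejection:
    """Run one read pair through the full recovery chain.

    Filter order is fixed: SHORT -> LOW_IDENTITY -> UNCONVERTED -> mapping.
    """
    trimmed = find_and_trim_hairpin(read1, read2, cfg, read_id)
    if isinstance(trimmed, Rejection):
        return trimmed
    aln = align_arms(trimmed, cfg)
    if isinstance(aln, Rejection):
        return aln
    mol = recover_original(aln)
    rej = nonconversion_filter(mol, cfg)
    if rej is not None:
        return rej
    if matcher is not None:
        return map_to_reference(mol, matcher, cfg)
    return mol


def process_library(
    pairs: Iterable[tuple[str, str, str]],
    cfg: RecoveryConfig,
    matcher: Optional[ReferenceMatcher] = None,
) -> tuple[list[RecoveredMolecule], pd.DataFrame, Counter]:
    """Process (read_id, read1, read2) tuples; return surviving molecules,
    a rejection log and a status counter (every pair counted exactly once)."""
    molecules: list[RecoveredMolecule] = []
    rejections: list[Rejection] = []
    counts: Counter = Counter()
    for read_id, r1, r2 in pairs:
        result = process_pair(read_id, r1, r2, cfg, matcher)
        if isinstance(result, Rejection):
            rejections.append(result)
            counts[result.reason] += 1
        else:
            molecules.append(result)
            counts[ACCEPTED] += 1
    log = pd.DataFrame(
        [(r.read_id, r.reason) for r in rejections], columns=["read_id", "reason"]
    )
    return molecules, log, counts


# ---------------------------------------------------------------------------
# FASTQ / TSV plumbing


def read_fastq_pairs(path_r1, path_r2) -> list[tuple[str, str, str]]:
    from Bio import SeqIO

    out = []
    for rec1, rec2 in zip(
        SeqIO.parse(str(path_r1), "fastq"), SeqIO.parse(str(path_r2), "fastq"), strict=True
    ):
        if rec1.id != rec2.id:
            raise ValueError(f"read pair mismatch: {rec1.id} vs {rec2.id}")
        out.append((rec1.id, str(rec1.seq).upper(), str(rec2.seq).upper()))
    return out


def write_molecules_tsv(molecules: list[RecoveredMolecule], path) -> None:
    rows = []
    for m in molecules:
        ref, start, strand = m.locus if m.locus else ("", -1, "")
        rows.append(
            {
                "read_id": m.read_id,
                "reference": ref,
                "start": start,
                "strand": strand,
                "sequence": m.sequence,
                "watson_calls": m.watson_calls,
                "crick_calls": m.crick_calls,
            }
        )
    pd.DataFrame(
        rows,
        columns=["read_id", "reference", "start", "strand", "sequence",
                 "watson_calls", "crick_calls"],
    ).to_csv(path, sep="\t", index=False)


def read_molecules_tsv(path) -> list[RecoveredMolecule]:
    df = pd.read_csv(path, sep="\t", dtype={"reference": str})
    out = []
    for row in df.itertuples(index=False):
        locus = (row.reference, int(row.start), row.strand) if row.start >= 0 else None
        out.append(
            RecoveredMolecule(
                read_id=str(row.read_id),
                sequence=row.sequence,
                watson_calls=row.watson_calls,
                crick_calls=row.crick_calls,
                locus=locus,
            )
        )
    return out
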