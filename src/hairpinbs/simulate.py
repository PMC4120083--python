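"""Synthetic hairpin bisulfite libraries with known double-strand ground truth.

A hairpin library reads both strands of a single DNA fragment: an adaptor
covalently links the Watson 3' end to the Crick 5' end, so after bisulfite
conversion and paired-end sequencing, read 1 carries the converted Watson arm
and read 2 carries the converted Crick arm over the same genomic interval.
Because the two arms come from one molecule, every CpG dyad is observed on
both strands simultaneously, which is what makes per-molecule methylation
fidelity measurable.

The generative model:

* each molecule draws a fragment from the reference (or, with probability
  ``lambda_fraction``, from a fully unmethylated spike-in control, the
  simulated analogue of unmethylated lambda phage DNA);
* each CpG dyad overlapping the fragment draws one of four molecule states
  (M = methylated on both strands, H = Watson-only, h = Crick-only,
  U = unmethylated) from the per-dyad mixture in :class:`MethylomeTruth`,
  independently per molecule;
* each non-CpG cytosine is methylated independently per strand at
  ``noncpg_rate``;
* bisulfite chemistry converts each unmethylated C to T with probability
  ``1 - r`` (so it survives as C with the non-conversion probability ``r``,
  resolved per context), while methylated Cs always survive;
* read 2 is emitted in Watson orientation: Watson-C positions appear as C,
  Watson-G positions appear as G when the paired Crick cytosine survived
  conversion and as A otherwise;
* fragments shorter than the arm length read through the (unmethylated,
  converted) hairpin adaptor into the opposite arm;
* uniform substitution sequencing error is applied last.

Dyad states are independent across molecules and across dyads; within-
molecule correlation of neighbouring dyads is deliberately not modelled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqops import c_to_t, crick_context, find_cpgs, revcomp, watson_context

#: Hairpin adaptor sequence (stem-loop oligo, biotin-dT written as plain T).
DEFAULT_HAIRPIN = "CGCCGGCGGCAAGTGAAGCCGCCGGCGT"

#: Per-context bisulfite non-conversion defaults (unmethylated C read as C).
DEFAULT_NONCONVERSION = {"CpG": 0.0103, "CHG": 0.0118, "CHH": 0.0112}

DYAD_STATE_CODES = ("M", "H", "h", "U")  # MM, MU, UM, UU


@dataclass
class ReferenceModel:
    """A reference contig plus the annotation intervals tests need.

    ``cgi_intervals`` are 0-based half-open, sorted, non-overlapping.
    ``transcript_models`` are (start, end, strand) tuples.
    """

    name: str
    sequence: str
    cgi_intervals: list[tuple[int, int]] = field(default_factory=list)
    transcript_models: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        prev_end = -1
        for start, end in self.cgi_intervals:
            if not (0 <= start < end <= n):
                raise ValueError(f"CGI interval ({start}, {end}) outside [0, {n})")
            if start < prev_end:
                raise ValueError("CGI intervals must be sorted and non-overlapping")
            prev_end = end
        for start, end, strand in self.transcript_models:
            if not (0 <= start < end <= n) or strand not in "+-":
                raise ValueError(f"bad transcript model ({start}, {end}, {strand})")

    def cpg_positions(self) -> list[int]:
        return find_cpgs(self.sequence)


@dataclass
class MethylomeTruth:
    """Ground-truth double-strand methylome.

    ``dyad_states`` maps each Watson-strand C position of a CG dinucleotide to
    the probabilities (pMM, pMU, pUM, pUU) of the four molecule states. A pure
    (0, .5, .5, 0) mixture is strand-asymmetric hemi-methylation (lowest
    possible fidelity); (.5, 0, 0, .5) is an allelic/cell-to-cell mixture
    (full fidelity at 50% methylation).
    """

    dyad_states: dict[int, tuple[float, float, float, float]]
    noncpg_rate: float = 0.0
    hmc_as_mc: bool = True  # 5-hmC indistinguishable from 5-mC under bisulfite

    def __post_init__(self) -> None:
        if not 0.0 <= self.noncpg_rate <= 1.0:
            raise ValueError("noncpg_rate must be in [0, 1]")
        for pos, probs in self.dyad_states.items():
            if abs(sum(probs) - 1.0) > 1e-12 or min(probs) < 0:
                raise ValueError(f"dyad state probabilities at {pos} do not sum to 1")


@dataclass
class LibraryConfig:
    """Parameters of one simulated hairpin sequencing library."""

    n_pairs: int = 2000
    arm_length: int = 70
    fragment_length: tuple[float, float] = (200.0, 50.0)  # mean, sd (bp)
    #: size-selection floor: sonication fragments below this are discarded by
    #: the library prep (the real protocol size-selects well above read
    #: length); lower it to exercise hairpin read-through
    min_fragment_length: int = 100
    nonconversion_rate: float | dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NONCONVERSION)
    )
    sequencing_error: float = 0.001
    lambda_fraction: float = 0.0001
    hairpin_sequence: str = DEFAULT_HAIRPIN
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.nonconversion_rate, (int, float)):
            self.nonconversion_rate = {
                ctx: float(self.nonconversion_rate) for ctx in ("CpG", "CHG", "CHH")
            }
        for ctx, r in self.nonconversion_rate.items():
            if not 0.0 <= r <= 0.05:
                raise ValueError(f"nonconversion_rate[{ctx}]={r} outside [0, 0.05]")
        if not 0.0 <= self.sequencing_error <= 0.1:
            raise ValueError("sequencing_error outside [0, 0.1]")
        if not 0.0 <= self.lambda_fraction <= 1.0:
            raise ValueError("lambda_fraction outside [0, 1]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.min_fragment_length < 30:
            raise ValueError("min_fragment_length must be >= 30")


@dataclass
class SimulatedLibrary:
    """Read pairs plus the per-molecule truth table."""

    pairs: list[tuple[str, str, str]]  # (read_id, read1, read2)
    truth: pd.DataFrame
    reference: ReferenceModel
    control: ReferenceModel | None


# ---------------------------------------------------------------------------
# reference generation


def generate_reference(
    length: int,
    gc_fraction: float,
    cgi_spec: tuple[int, int, float] | None = None,
    seed: int = 0,
    name: str = "chrSim",
    transcript_spec: tuple[int, int] | None = None,
) -> ReferenceModel:
    """Random reference with optional CpG islands and transcript models.

    ``cgi_spec`` is (count, island_length, cpg_boost): islands get elevated GC
    and extra planted CG dinucleotides so their CpG observed/expected ratio
    exceeds the background by roughly ``cpg_boost``. ``transcript_spec`` is
    (count, typical_length) for annotation plumbing.
    """
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    p_bg = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seq = rng.choice(bases, size=length, p=p_bg)

    cgi_intervals: list[tuple[int, int]] = []
    if cgi_spec is not None:
        count, cgi_len, boost = cgi_spec
        if count * cgi_len > length:
            raise ValueError("total CGI length exceeds reference length")
        gc_cgi = min(0.85, gc_fraction + 0.18)
        p_cgi = np.array([(1 - gc_cgi) / 2, gc_cgi / 2, gc_cgi / 2, (1 - gc_cgi) / 2])
        # one island per equal segment keeps them disjoint and sorted
        seg = length // count
        for k in range(count):
            lo = k * seg
            hi = min((k + 1) * seg, length) - cgi_len
            start = int(rng.integers(lo, max(lo + 1, hi)))
            end = start + cgi_len
            seq[start:end] = rng.choice(bases, size=cgi_len, p=p_cgi)
            n_plant = int(round(boost * (gc_cgi / 2) ** 2 * cgi_len))
            slots = rng.choice(cgi_len // 2 - 1, size=min(n_plant, cgi_len // 2 - 1), replace=False)
            for s in slots:
                seq[start + 2 * s] = "C"
                seq[start + 2 * s + 1] = "G"
            cgi_intervals.append((start, end))

    transcripts: list[tuple[int, int, str]] = []
    if transcript_spec is not None:
        count, tlen = transcript_spec
        for _ in range(count):
            tl = int(rng.integers(max(200, tlen // 2), tlen * 2))
            start = int(rng.integers(0, max(1, length - tl)))
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append((start, start + tl, strand))
        transcripts.sort()

    return ReferenceModel(
        name=name,
        sequence="".join(seq),
        cgi_intervals=cgi_intervals,
        transcript_models=transcripts,
    )


def assign_truth(
    ref: ReferenceModel,
    regime_map: list[tuple[tuple[int, int], tuple[float, float, float, float]]],
    noncpg_rate: float = 0.0,
    seed: int = 0,
    default_state: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0),
) -> MethylomeTruth:
    """Assign a dyad-state mixture to every CG dyad of the reference.

    Regimes are ((start, end), (pMM, pMU, pUM, pUU)) intervals; dyads outside
    all regimes get ``default_state``. Overlapping regimes with conflicting
    tuples are an error. ``seed`` is accepted for interface symmetry (the
    assignment itself is deterministic).
    """
    del seed
    n = len(ref.sequence)
    for (start, end), probs in regime_map:
        if not (0 <= start < end <= n):
            raise ValueError(f"regime interval ({start}, {end}) outside reference")
        if abs(sum(probs) - 1.0) > 1e-12 or min(probs) < 0:
            raise ValueError(f"regime probabilities {probs} do not sum to 1")
    states: dict[int, tuple[float, float, float, float]] = {}
    for pos in ref.cpg_positions():
        assigned = None
        for (start, end), probs in regime_map:
            if start <= pos < end:
                if assigned is not None and assigned != probs:
                    raise ValueError(f"conflicting regimes overlap dyad at {pos}")
                assigned = probs
        states[pos] = assigned if assigned is not None else default_state
    return MethylomeTruth(dyad_states=states, noncpg_rate=noncpg_rate)


# ---------------------------------------------------------------------------
# library simulation


def _draw_state(rng: np.random.Generator, probs) -> str:
    u = rng.random()
    acc = 0.0
    for code, p in zip(DYAD_STATE_CODES, probs):
        acc += p
        if u < acc:
            return code
    return "U"


def _apply_sequencing_error(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return read
    chars = list(read)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    alphabet = "ACGT"
    for i in hits:
        choices = [b for b in alphabet if b != chars[i]]
        chars[i] = choices[int(rng.integers(3))]
    return "".join(chars)


def simulate_library(
    ref: ReferenceModel,
    truth: MethylomeTruth,
    cfg: LibraryConfig,
    control_ref: ReferenceModel | None = None,
) -> SimulatedLibrary:
    """Simulate a hairpin bisulfite library; see the module docstring.

    Returns the read pairs (read 2 already in Watson orientation), a
    per-molecule truth table, and the control reference used for the
    unmethylated spike-in. Deterministic given ``cfg.seed``.
    """
    if not ref.sequence:
        raise ValueError("empty reference")
    rng = np.random.default_rng(cfg.seed)
    if control_ref is None and cfg.lambda_fraction > 0:
        control_ref = generate_reference(
            8000, 0.5, None, seed=(cfg.seed * 7919 + 1) % (2**31), name="lambda_control"
        )
    r_ctx = cfg.nonconversion_rate
    hp_ct = c_to_t(cfg.hairpin_sequence)  # converted hairpin as read 1 sees it
    mean_len, sd_len = cfg.fragment_length

    pairs: list[tuple[str, str, str]] = []
    rows = []
    for i in range(cfg.n_pairs):
        is_control = bool(cfg.lambda_fraction > 0 and rng.random() < cfg.lambda_fraction)
        src = control_ref if is_control else ref
        seq = src.sequence
        n = len(seq)
        flen = int(round(rng.normal(mean_len, sd_len)))
        flen = max(cfg.min_fragment_length, min(flen, n))
        start = int(rng.integers(0, n - flen + 1))
        end = start + flen

        wmeth: set[int] = set()  # absolute positions of methylated Watson Cs
        cmeth: set[int] = set()  # absolute positions of methylated Crick Cs (Watson Gs)
        dyad_pos: list[int] = []
        dyad_states: list[str] = []
        noncpg = 0.0 if is_control else truth.noncpg_rate
        for p in range(start, end):
            b = seq[p]
            if b == "C":
                if p + 1 < n and seq[p + 1] == "G":
                    state = "U" if is_control else _draw_state(rng, truth.dyad_states[p])
                    dyad_pos.append(p)
                    dyad_states.append(state)
                    if state in ("M", "H"):
                        wmeth.add(p)
                    if state in ("M", "h"):
                        cmeth.add(p + 1)
                elif noncpg > 0 and rng.random() < noncpg:
                    wmeth.add(p)
            elif b == "G" and not (p - 1 >= 0 and seq[p - 1] == "C"):
                if noncpg > 0 and rng.random() < noncpg:
                    cmeth.add(p)
            elif b == "G" and 0 <= p - 1 < start and seq[p - 1] == "C":
                # dyad whose Watson C lies left of the fragment: only the
                # Crick side is observable, still drawn from truth
                state = "U" if is_control else _draw_state(rng, truth.dyad_states[p - 1])
                if state in ("M", "h"):
                    cmeth.add(p)

        w_chars = []
        c_chars = []  # Crick arm in Watson orientation
        for p in range(start, end):
            b = seq[p]
            if b == "C":
                if p in wmeth or rng.random() < r_ctx[watson_context(seq, p)]:
                    w_chars.append("C")
                else:
                    w_chars.append("T")
                c_chars.append("C")
            elif b == "G":
                w_chars.append("G")
                if p in cmeth or rng.random() < r_ctx[crick_context(seq, p)]:
                    c_chars.append("G")
                else:
                    c_chars.append("A")
            else:
                w_chars.append(b)
                c_chars.append(b)
        w_read = "".join(w_chars)
        c_frame = "".join(c_chars)

        if flen < cfg.arm_length:
            # read-through: arm + converted hairpin + opposite arm
            read1 = (w_read + hp_ct + revcomp(c_frame))[: cfg.arm_length]
            read2 = (c_frame + revcomp(hp_ct) + revcomp(w_read))[: cfg.arm_length]
        else:
            read1 = w_read[: cfg.arm_length]
            read2 = c_frame[: cfg.arm_length]

        read1 = _apply_sequencing_error(read1, cfg.sequencing_error, rng)
        read2 = _apply_sequencing_error(read2, cfg.sequencing_error, rng)

        read_id = f"mol{i:06d}"
        pairs.append((read_id, read1, read2))
        rows.append(
            {
                "read_id": read_id,
                "source": "control" if is_control else "genome",
                "reference": src.name,
                "start": start,
                "end": end,
                "dyad_positions": ",".join(map(str, dyad_pos)),
                "dyad_states": "".join(dyad_states),
                "watson_meth": ",".join(map(str, sorted(wmeth))),
                "crick_meth": ",".join(map(str, sorted(cmeth))),
            }
        )

    truth_table = pd.DataFrame(rows)
    return SimulatedLibrary(pairs=pairs, truth=truth_table, reference=ref, control=control_ref)


def simulate_dyad_tallies(
    probs: tuple[float, float, float, float],
    n_dyads: int,
    n_pairs: int,
    seed: int = 0,
    reference: str = "sim",
) -> pd.DataFrame:
    """Dyad-pattern count table sampled directly from a state mixture.

    Bypasses read-level simulation: each dyad receives ``n_pairs`` molecule
    observations drawn multinomially from (pMM, pMU, pUM, pUU). Used for
    estimator calibration at depths impractical to reach through full reads.
    """
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_pairs, probs, size=n_dyads)
    return pd.DataFrame(
        {
            "reference": reference,
            "position": np.arange(n_dyads) * 2,
            "nMM": counts[:, 0],
            "nMU": counts[:, 1],
            "nUM": counts[:, 2],
            "nUU": counts[:, 3],
        }
    )


# ---------------------------------------------------------------------------
# file output


def write_fasta(ref: ReferenceModel, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(ref.sequence), id=ref.name, description="")], str(path), "fasta")


def read_fasta(path) -> ReferenceModel:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceModel(name=rec.id, sequence=str(rec.seq).upper())


def write_fastq_pairs(pairs: list[tuple[str, str, str]], path_r1, path_r2) -> None:
    """Write 4-line FASTQ records with constant quality (phred 40, 'I')."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    def records(idx):
        for read_id, r1, r2 in pairs:
            seq = (r1, r2)[idx]
            rec = SeqRecord(Seq(seq), id=read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            yield rec

    SeqIO.write(records(0), str(path_r1), "fastq")
    SeqIO.write(records(1), str(path_r2), "fastq")


def replace(obj, **kwargs):
    return dataclasses.replace(obj, **kwargs)
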