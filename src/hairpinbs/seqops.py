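"""Small shared sequence utilities: strand arithmetic and cytosine context.

Context is always determined from a reference-like sequence, never from a
bisulfite read, because conversion destroys the C/T distinction the context
codes depend on.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_C_TO_T = str.maketrans("C", "T")
_G_TO_A = str.maketrans("G", "A")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def c_to_t(seq: str) -> str:
    """Collapse C onto T (the fully converted Watson-strand alphabet)."""
    return seq.translate(_C_TO_T)


def g_to_a(seq: str) -> str:
    """Collapse G onto A (the converted Crick strand seen in Watson frame)."""
    return seq.translate(_G_TO_A)


def watson_context(seq: str, pos: int) -> str:
    """Context (CpG/CHG/CHH) of a Watson-strand cytosine at ``pos``.

    Positions whose context runs off the end of the sequence fall back to CHH,
    the least specific class.
    """
    if pos + 1 < len(seq) and seq[pos + 1] == "G":
        return "CpG"
    if pos + 2 < len(seq) and seq[pos + 2] == "G":
        return "CHG"
    return "CHH"


def crick_context(seq: str, pos: int) -> str:
    """Context of the Crick-strand cytosine paired to the Watson G at ``pos``.

    The Crick strand reads right-to-left in Watson coordinates, so its
    downstream bases are the Watson bases at pos-1, pos-2 (complemented).
    """
    if pos - 1 >= 0 and seq[pos - 1] == "C":
        return "CpG"
    if pos - 2 >= 0 and seq[pos - 2] == "C":
        return "CHG"
    return "CHH"


def find_cpgs(seq: str) -> list[int]:
    """Watson-strand C positions of every CG dinucleotide."""
    out = []
    start = 0
    while True:
        i = seq.find("CG", start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1
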