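"""Shared fixtures and independent oracles.

The helpers here implement the bisulfite chemistry and alignment scoring by
independent means (direct enumeration, hand-rolled conversion) so tests never
validate the package against itself.
"""

from __future__ import annotations

import numpy as np
import pytest

from hairpinbs.recover import RecoveryConfig


def bisulfite_pair(frag: str, wmeth=(), cmeth=()) -> tuple[str, str]:
    """Error-free bisulfite chemistry applied by hand (r = 0).

    ``wmeth``/``cmeth`` are fragment-relative positions of methylated Watson
    and Crick cytosines (Crick cytosines sit at Watson G positions). Returns
    (watson arm, crick arm in Watson orientation).
    """
    wmeth, cmeth = set(wmeth), set(cmeth)
    r1 = "".join(
        "C" if (b == "C" and i in wmeth) else ("T" if b == "C" else b)
        for i, b in enumerate(frag)
    )
    r2 = "".join(
        "G" if (b == "G" and i in cmeth) else ("A" if b == "G" else b)
        for i, b in enumerate(frag)
    )
    return r1, r2


def cpg_meth_sets(frag: str) -> tuple[set[int], set[int]]:
    """Fully CpG-methylated molecule: both strands methylated at every dyad."""
    wm = {i for i in range(len(frag) - 1) if frag[i : i + 2] == "CG"}
    cm = {i + 1 for i in wm}
    return wm, cm


def oracle_align_score(a: str, b: str, cfg: RecoveryConfig) -> float:
    """Best global-alignment score by exhaustive enumeration of all paths.

    Recursion over the three moves with gap-run-aware costs (a run of length
    L costs gap_open + (L-1)*gap_extend); no memoisation, independent of the
    Gotoh implementation under test. Only feasible for short strings.
    """
    best = float("-inf")
    ms, mx, go, ge = cfg.match_score, cfg.mismatch_score, cfg.gap_open, cfg.gap_extend
    la, lb = len(a), len(b)

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if i == la and j == lb:
            if score > best:
                best = score
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, score + (ms if a[i] == b[j] else mx), "D")
        if i < la:
            rec(i + 1, j, score + (ge if last == "X" else go), "X")
        if j < lb:
            rec(i, j + 1, score + (ge if last == "Y" else go), "Y")

    rec(0, 0, 0.0, "")
    return best


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def rcfg() -> RecoveryConfig:
    return RecoveryConfig()
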