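"""Minimum-free-energy secondary structure via weighted pair maximization.

A deterministic Nussinov-style dynamic program with stacked weights
(GC = 3, AU = 2, GU = 1) and a minimum hairpin loop of 3 nt.  This is the
default folding backend for the site-accessibility predictor: only the
paired/unpaired state of each base in the MFE structure is consumed
downstream, not the energy itself.
"""

from __future__ import annotations

import numpy as np

MIN_LOOP = 3  # minimum number of unpaired bases in a hairpin loop

_PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


def _encode(seq: str) -> list[str]:
    return list(seq.upper().replace("T", "U"))


def pair_weight(a: str, b: str) -> int:
    """Pairing weight of two bases (0 = cannot pair).  T is read as U."""
    a = "U" if a in "Tt" else a.upper()
    b = "U" if b in "Tt" else b.upper()
    return _PAIR_WEIGHT.get((a, b), 0)


class FoldError(RuntimeError):
    """Raised when the folding backend cannot process a window."""


def mfe_pairs(seq: str) -> dict[int, int]:
    """Fold ``seq`` and return the base pairs of the optimal structure.

    Returns a symmetric mapping ``i -> j`` (both directions present) over
    0-based positions.  Deterministic: ties in the dynamic program are
    broken toward leaving 5' bases unpaired, then toward the closest pair.
    """
    n = len(seq)
    if n == 0:
        return {}
    bases = _encode(seq)
    weights = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            weights[i, j] = pair_weight(bases[i], bases[j])

    # score[i][j] over padded indices so empty intervals read as 0
    score = np.zeros((n + 2, n + 2), dtype=np.int64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = score[i + 2, j + 1]  # i unpaired -> (i+1, j), padded by +1
            ks = np.arange(i + MIN_LOOP + 1, j + 1)
            w = weights[i, ks]
            valid = w > 0
            if valid.any():
                ks_v = ks[valid]
                cand = score[i + 2, ks_v] + w[valid] + score[ks_v + 2, j + 1]
                best = max(best, int(cand.max()))
            score[i + 1, j + 1] = best

    pairs: dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if score[i + 1, j + 1] == score[i + 2, j + 1]:
            stack.append((i + 1, j))
            continue
        target = score[i + 1, j + 1]
        for k in range(i + MIN_LOOP + 1, j + 1):
            w = weights[i, k]
            if w and score[i + 2, k] + w + score[k + 2, j + 1] == target:
                pairs[i] = k
                pairs[k] = i
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
        else:  # pragma: no cover - DP consistency guard
            raise FoldError(f"traceback failed at interval [{i}, {j}]")
    return pairs


def unpaired_positions(seq: str) -> set[int]:
    """Positions left unpaired in the MFE structure of ``seq``."""
    paired = mfe_pairs(seq)
    return {i for i in range(len(seq)) if i not in paired}
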