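"""RNA secondary structure by base-pair maximization.

The validation ladder only consumes pairing topology (which bases pair,
where the duplex arms are), so folding is deterministic Nussinov-style
maximization of the number of base pairs rather than a thermodynamic MFE
model: A-U, G-C and G-U pairs are allowed and hairpin loops must contain
at least ``MIN_LOOP`` unpaired bases.  An MFE backend could be plugged in
behind the same ``SecondaryStructure`` contract.

Pure pair-count maximization is highly degenerate: a hairpin window
typically admits many co-optimal structures, most of them with isolated
pairs scattered outside the stem.  The search therefore optimizes
lexicographically — pair count first, then the number of stacked pairs
(pairs (i, j) whose inner neighbour (i+1, j-1) is also paired) — which
keeps the pair count maximal (the documented contract) while resolving
ties toward contiguous helices, as a thermodynamic model would.
Traceback is deterministic: j unpaired when co-optimal, else the
smallest co-optimal partner k.
"""

from __future__ import annotations

import numpy as np

from ._types import SecondaryStructure

MIN_LOOP = 3

_BASES = "ACGU"
_CANPAIR = np.zeros((5, 5), dtype=bool)
for _x, _y in ("AU", "UA", "GC", "CG", "GU", "UG"):
    _CANPAIR[_BASES.index(_x), _BASES.index(_y)] = True


def can_pair(x: str, y: str) -> bool:
    x = "U" if x in "Tt" else x.upper()
    y = "U" if y in "Tt" else y.upper()
    if x not in _BASES or y not in _BASES:
        return False
    return bool(_CANPAIR[_BASES.index(x), _BASES.index(y)])


def _encode(seq: str) -> np.ndarray:
    s = seq.upper().replace("T", "U")
    codes = np.full(len(s), 4, dtype=np.int8)  # 4 = N/other, pairs with nothing
    for i, b in enumerate(_BASES):
        codes[np.frombuffer(s.encode(), dtype=np.uint8) == ord(b)] = i
    return codes


# one pair outweighs any number of stacking bonuses (windows are < 1000 nt)
_PAIR = 1000
_STACK = 1


def fold_rna(seq: str) -> SecondaryStructure:
    """Maximum base-pair structure of ``seq`` (T read as U), ties broken
    toward stacked helices.

    Raises ``ValueError`` on an empty sequence.
    """
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    n = len(seq)
    codes = _encode(seq)
    pairable = _CANPAIR[codes][:, codes]  # pairable[i, j]
    # W[i, j]: best value of seq[i..j]; V[i, j]: best value given (i, j) paired
    NEG = np.int32(-(10**9))
    W = np.zeros((n + 1, n + 1), dtype=np.int32)
    V = np.full((n + 1, n + 1), NEG, dtype=np.int32)

    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable[i, j]:
                inner = max(int(V[i + 1, j - 1]) + _STACK, int(W[i + 1, j - 1]))
                V[i, j] = _PAIR + inner
            best = W[i, j - 1]  # j unpaired
            ks = np.nonzero(pairable[i : j - MIN_LOOP, j])[0]
            if ks.size:
                ks = ks + i
                # W[i, k-1] + V[k, j] over candidate ks
                left = np.where(ks > i, W[i, np.maximum(ks - 1, 0)], 0)
                cand = int((left + V[ks, j]).max())
                if cand > best:
                    best = cand
            W[i, j] = best

    def Wv(i: int, j: int) -> int:
        return 0 if j < i else int(W[i, j])

    pairs = [-1] * n
    stack: list[tuple[str, int, int]] = [("W", 0, n - 1)]
    while stack:
        state, i, j = stack.pop()
        if j - i < MIN_LOOP + 1:
            continue
        if state == "V":
            pairs[i] = j
            pairs[j] = i
            if int(V[i, j]) == _PAIR + int(V[i + 1, j - 1]) + _STACK:
                stack.append(("V", i + 1, j - 1))
            else:
                stack.append(("W", i + 1, j - 1))
            continue
        if W[i, j] == W[i, j - 1]:
            stack.append(("W", i, j - 1))
            continue
        target = int(W[i, j])
        for k in range(i, j - MIN_LOOP):
            if pairable[k, j] and Wv(i, k - 1) + int(V[k, j]) == target:
                if k > i:
                    stack.append(("W", i, k - 1))
                stack.append(("V", k, j))
                break
    dots = "".join("(" if (p := pairs[i]) > i else ")" if p >= 0 else "." for i in range(n))
    return SecondaryStructure(seq.upper().replace("T", "U"), dots, tuple(pairs))


def max_pairs_exhaustive(seq: str) -> int:
    """Independent oracle: maximum pair count by explicit enumeration of all
    valid non-crossing structures.  Exponential; for short sequences only."""
    s = seq.upper().replace("T", "U")
    n = len(s)

    def best(i: int, j: int, memo: dict) -> int:
        if j - i < MIN_LOOP + 1:
            return 0
        key = (i, j)
        if key in memo:
            return memo[key]
        # enumerate every fate of position i: unpaired, or paired with each j2
        out = best(i + 1, j, memo)
        for j2 in range(i + MIN_LOOP + 1, j + 1):
            if can_pair(s[i], s[j2]):
                out = max(out, 1 + best(i + 1, j2 - 1, memo) + best(j2 + 1, j, memo))
        memo[key] = out
        return out

    return best(0, n - 1, {})


def enumerate_structures(seq: str) -> list[tuple[tuple[int, int], ...]]:
    """All valid structures (as sorted pair tuples) of a short sequence."""
    s = seq.upper().replace("T", "U")
    n = len(s)
    out: list[tuple[tuple[int, int], ...]] = []

    def rec(i: int, j: int) -> list[list[tuple[int, int]]]:
        if j - i < MIN_LOOP + 1:
            return [[]]
        results = [r for r in rec(i + 1, j)]
        for j2 in range(i + MIN_LOOP + 1, j + 1):
            if can_pair(s[i], s[j2]):
                for inner in rec(i + 1, j2 - 1):
                    for outer in rec(j2 + 1, j):
                        results.append([(i, j2)] + inner + outer)
        return results

    for struct in rec(0, n - 1):
        out.append(tuple(sorted(struct)))
    return out
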