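"""Intermolecular RNA duplex minimum free energy by dynamic programming.

Hybridization-only model: no intramolecular structure, no accessibility.
A duplex is a strictly monotone, non-crossing set of base pairs between
two strands read antiparallel.  Energy terms:

* nearest-neighbour stack free energies for contiguous pairs, from the
  bundled Watson-Crick table (Turner-style DG37 values) plus simplified
  G.U wobble stacks;
* an interior-loop/bulge penalty (opening cost + per-unpaired-nucleotide
  cost), with the loop span capped at ``max_loop`` nt per strand;
* a duplex initiation penalty.

Absolute energies are internally consistent and bit-reproducible but not
comparable to RNAduplex/IntaRNA outputs, which include dangling ends,
full loop tables and intramolecular terms.

:func:`brute_force_mfe` enumerates every admissible pairing and scores it
independently of the DP; it exists to validate the DP on small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MalformedInputError

RNA_ALPHABET = "ACGU"
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE_PAIRS = {("G", "U"), ("U", "G")}

#: Watson-Crick nearest-neighbour stacks, kcal/mol at 37 C.  Key is
#: ((x1, y1), (x2, y2)) for 5'-x1 x2-3' over 3'-y1 y2-5'.  The ten unique
#: orientations below; the rest follow by rotational symmetry.
_WC_STACK_SEED = {
    (("A", "U"), ("A", "U")): -0.93,
    (("A", "U"), ("U", "A")): -1.10,
    (("U", "A"), ("A", "U")): -1.33,
    (("C", "G"), ("U", "A")): -2.08,
    (("C", "G"), ("A", "U")): -2.11,
    (("G", "C"), ("U", "A")): -2.24,
    (("G", "C"), ("A", "U")): -2.35,
    (("C", "G"), ("G", "C")): -2.36,
    (("G", "C"), ("G", "C")): -3.26,
    (("G", "C"), ("C", "G")): -3.42,
}


def _build_wc_table() -> dict:
    table = {}
    for (p1, p2), e in _WC_STACK_SEED.items():
        table[(p1, p2)] = e
        table[((p2[1], p2[0]), (p1[1], p1[0]))] = e  # 180-degree rotation
    return table


WC_STACK = _build_wc_table()


@dataclass
class DuplexParams:
    """Bundled energy-model parameters (kcal/mol)."""

    initiation: float = 4.09
    loop_open: float = 1.0
    loop_per_nt: float = 0.4
    wobble_stack_single: float = -1.2  # stack containing one G.U pair
    wobble_stack_double: float = -0.5  # stack of two G.U pairs
    max_loop: int = 6  # max unpaired nt per strand between consecutive pairs


DEFAULT_PARAMS = DuplexParams()


@dataclass
class DuplexResult:
    """Energy, pairing (i in a, j in b; i ascending, j descending) and a
    dot-bracket-like annotation ``a_struct&b_struct``."""

    energy: float
    pairing: list[tuple[int, int]]
    structure: str


def is_pairable(x: str, y: str, wobble: bool = True) -> bool:
    return (x, y) in WC_PAIRS or (wobble and (x, y) in WOBBLE_PAIRS)


def stack_energy(x1: str, y1: str, x2: str, y2: str, params: DuplexParams) -> float:
    """Stack 5'-x1 x2-3' / 3'-y1 y2-5' with pairs x1.y1 and x2.y2."""
    p1, p2 = (x1, y1), (x2, y2)
    n_wobble = (p1 in WOBBLE_PAIRS) + (p2 in WOBBLE_PAIRS)
    if n_wobble == 0:
        return WC_STACK[(p1, p2)]
    if n_wobble == 1:
        return params.wobble_stack_single
    return params.wobble_stack_double


def _check_alphabet(seq: str) -> None:
    if set(seq) - set(RNA_ALPHABET):
        raise MalformedInputError(f"non-ACGU characters in {seq!r}")


def _step_cost(i1: int, j1: int, i2: int, j2: int, a: str, br: str, params: DuplexParams) -> float | None:
    """Cost of extending pair (i1, j1) by pair (i2, j2) (reversed-b coords)."""
    gi, gj = i2 - i1 - 1, j2 - j1 - 1
    if gi > params.max_loop or gj > params.max_loop:
        return None
    if gi == 0 and gj == 0:
        return stack_energy(a[i1], br[j1], a[i2], br[j2], params)
    return params.loop_open + params.loop_per_nt * (gi + gj)


def duplex_mfe(
    a: str,
    b: str,
    wobble: bool = True,
    params: DuplexParams = DEFAULT_PARAMS,
) -> DuplexResult:
    """Minimum-free-energy duplex of two RNA strands.

    Returns the empty duplex (energy 0) when no pairing is stabilising,
    in particular whenever either strand is shorter than 3 nt.
    """
    _check_alphabet(a)
    _check_alphabet(b)
    n, m = len(a), len(b)
    empty = DuplexResult(0.0, [], "." * n + "&" + "." * m)
    if n < 3 or m < 3:
        return empty

    br = b[::-1]
    INF = float("inf")
    best = [[INF] * m for _ in range(n)]
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    for i in range(n):
        ai = a[i]
        for j in range(m):
            if not is_pairable(ai, br[j], wobble):
                continue
            e, prev = params.initiation, None
            for i2 in range(max(0, i - 1 - params.max_loop), i):
                row = best[i2]
                for j2 in range(max(0, j - 1 - params.max_loop), j):
                    if row[j2] == INF:
                        continue
                    cost = _step_cost(i2, j2, i, j, a, br, params)
                    if cost is None:
                        continue
                    cand = row[j2] + cost
                    if cand < e:
                        e, prev = cand, (i2, j2)
            best[i][j] = e
            back[(i, j)] = prev

    emin, argmin = 0.0, None
    for i in range(n):
        for j in range(m):
            if best[i][j] < emin - 1e-12:
                emin, argmin = best[i][j], (i, j)
    if argmin is None:
        return empty

    rev_pairs = []
    cur: tuple[int, int] | None = argmin
    while cur is not None:
        rev_pairs.append(cur)
        cur = back[cur]
    rev_pairs.reverse()
    pairing = [(i, m - 1 - j) for i, j in rev_pairs]
    a_ann = ["."] * n
    b_ann = ["."] * m
    for i, j in pairing:
        a_ann[i] = "("
        b_ann[j] = ")"
    return DuplexResult(round(emin, 6), pairing, "".join(a_ann) + "&" + "".join(b_ann))


def score_pairing(
    a: str,
    b: str,
    pairing_rev: list[tuple[int, int]],
    params: DuplexParams = DEFAULT_PARAMS,
) -> float:
    """Energy of an explicit pairing given in reversed-b coordinates,
    accumulated term by term (used by the enumeration oracle)."""
    if not pairing_rev:
        return 0.0
    br = b[::-1]
    total = params.initiation
    for (i1, j1), (i2, j2) in zip(pairing_rev, pairing_rev[1:]):
        cost = _step_cost(i1, j1, i2, j2, a, br, params)
        if cost is None:
            raise ValueError("pairing violates the loop cap")
        total += cost
    return total


def brute_force_mfe(
    a: str,
    b: str,
    wobble: bool = True,
    params: DuplexParams = DEFAULT_PARAMS,
) -> float:
    """Exhaustive minimum over all monotone non-crossing pairings.

    Exponential; intended for strands of length <= 12.  Recursion
    enumerates every admissible chain of pairable positions respecting the
    loop cap, scoring each chain with :func:`score_pairing`.
    """
    _check_alphabet(a)
    _check_alphabet(b)
    n, m = len(a), len(b)
    if n < 3 or m < 3:
        return 0.0
    br = b[::-1]
    pairable = [
        [is_pairable(a[i], br[j], wobble) for j in range(m)] for i in range(n)
    ]
    best = [0.0]

    def extend(chain: list[tuple[int, int]]) -> None:
        if chain:
            e = score_pairing(a, b, chain, params)
            if e < best[0]:
                best[0] = e
            i0, j0 = chain[-1]
            i_stop = min(n, i0 + 2 + params.max_loop)
            j_stop = min(m, j0 + 2 + params.max_loop)
        else:
            i0, j0 = -1, -1
            i_stop, j_stop = n, m
        for i in range(i0 + 1, i_stop):
            for j in range(j0 + 1, j_stop):
                if pairable[i][j]:
                    chain.append((i, j))
                    extend(chain)
                    chain.pop()

    extend([])
    return round(best[0], 6)
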