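"""Minimum-free-energy RNA secondary-structure prediction for hairpin screening.

The precursor screen only consumes a handful of coarse structural quantities
(stem pairs, bulge sizes, loop length, a -15 kcal/mol energy gate), so the
energy model here is a deliberately simplified nearest-neighbor model: a 6x6
stacking table over the canonical pairs (Watson-Crick plus G·U wobble) and
logarithmic destabilizing penalties for hairpin loops, bulges and internal
loops.  It is deterministic, monotone under added stacked pairs, and on the
same kcal/mol scale as full Turner-parameter folders, but it is *not*
Turner-complete (no dangles, no terminal mismatches, no special tetraloops).

Two models are exposed:

``nearest_neighbor``
    the energy model above, folded by a Zuker-style interval dynamic program
    with multibranch decomposition.
``pair_count``
    every pair scores -1 and loops are free (Nussinov maximum matching);
    used as a test mode whose optimum can be checked by exhaustive
    enumeration on short sequences.

Coordinates are 0-based; pair tables use -1 for unpaired positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

MIN_HAIRPIN_LOOP = 3
MAX_INTERIOR = 30  # per-side cap on interior-loop search, nt

# canonical pair codes
_PAIRS = {
    ("C", "G"): 0,
    ("G", "C"): 1,
    ("G", "T"): 2,
    ("T", "G"): 3,
    ("A", "T"): 4,
    ("T", "A"): 5,
}

# Stacking free energies, kcal/mol.  STACK[p, q] is the increment for pair q
# = (i+1, j-1) stacked directly inside pair p = (i, j).  Values follow the
# magnitude ordering of measured nearest-neighbor parameters (GC-rich stacks
# near -3.3, AU/GU stacks near -1) without reproducing any published table
# exactly.
#               CG     GC     GU     UG     AU     UA
_STACK = np.array(
    [
        [-3.3, -2.4, -2.1, -1.4, -2.1, -2.1],  # CG
        [-3.4, -3.3, -2.5, -1.5, -2.2, -2.4],  # GC
        [-2.5, -2.1, -1.4, +0.3, -1.4, -1.3],  # GU
        [-2.1, -1.4, -0.6, -0.5, -1.0, -0.6],  # UG
        [-2.4, -2.1, -1.4, -1.0, -0.9, -1.3],  # AU
        [-2.1, -2.1, -1.3, -0.8, -1.3, -0.6],  # UA
    ]
)

# multibranch-loop linear model, kcal/mol
_ML_CLOSE = 4.6
_ML_BRANCH = 0.4
_ML_UNPAIRED = 0.1

# tie-break bias: prefer structures with more pairs among equal-energy optima.
# Far below the 0.1 kcal/mol granularity of the tables, so it never flips a
# genuine energy comparison (max ~400 pairs * 1e-4 = 0.04).
_PAIR_BIAS = 1e-4

_INF = 1e9


def hairpin_penalty(n: int) -> float:
    """Destabilizing energy of a hairpin loop of n unpaired nt (n >= 3)."""
    return 5.4 + 1.6 * math.log(n / 3.0)


def bulge_penalty(n: int) -> float:
    """Destabilizing energy of a bulge of n unpaired nt on one strand."""
    return 3.8 + 1.6 * math.log(n)


def internal_penalty(n: int) -> float:
    """Destabilizing energy of an internal loop with n unpaired nt in total."""
    return 4.1 + 1.6 * math.log(n / 2.0)


class FoldError(ValueError):
    pass


class NotHairpinError(ValueError):
    """Structure is not a single stem-loop (no pairs, or multibranched)."""


@dataclass
class SecondaryStructure:
    """A nested secondary structure with its free energy."""

    sequence: str
    pair_table: np.ndarray  # partner index, -1 if unpaired
    dot_bracket: str
    free_energy: float  # kcal/mol (or -pairs in pair_count mode)

    @property
    def n_pairs(self) -> int:
        return int((self.pair_table >= 0).sum()) // 2


def normalize_seq(sequence: str) -> str:
    """Uppercase and map U->T; raise on anything outside ACGT(U)."""
    s = sequence.upper().replace("U", "T")
    if not s or set(s) - set("ACGT"):
        raise FoldError(f"sequence contains non-ACGT(U) characters: {sequence[:30]!r}")
    return s


def _pair_code(a: str, b: str) -> int:
    return _PAIRS.get((a, b), -1)


def pair_table_from_dotbracket(db: str) -> np.ndarray:
    pt = np.full(len(db), -1, dtype=int)
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pt


def dotbracket_from_pair_table(pt: np.ndarray) -> str:
    out = []
    for i, j in enumerate(pt):
        out.append("." if j < 0 else ("(" if j > i else ")"))
    return "".join(out)


def _children(pt: np.ndarray, i: int, j: int) -> list[tuple[int, int]]:
    """Directly enclosed pairs inside the open interval (i, j)."""
    kids = []
    k = i + 1
    while k < j:
        if pt[k] > k:
            kids.append((k, int(pt[k])))
            k = int(pt[k]) + 1
        else:
            k += 1
    return kids


def structure_energy(sequence: str, pair_table: np.ndarray) -> float:
    """Free energy of an explicit structure under the module's energy model.

    Decomposes the structure into stacks, hairpin/bulge/internal loops and
    multibranch loops and sums their table contributions.  Exterior bases are
    free.  This evaluator is independent of the folding DP and doubles as the
    scorer for brute-force enumeration in the test suite.
    """
    s = normalize_seq(sequence)
    pt = np.asarray(pair_table)
    e = 0.0
    for i in range(len(s)):
        j = int(pt[i])
        if j <= i:
            continue
        if _pair_code(s[i], s[j]) < 0:
            raise FoldError(f"non-canonical pair {s[i]}-{s[j]} at ({i},{j})")
        kids = _children(pt, i, j)
        if not kids:
            e += hairpin_penalty(j - i - 1)
        elif len(kids) == 1:
            (k, l) = kids[0]
            g5, g3 = k - i - 1, j - l - 1
            if g5 == 0 and g3 == 0:
                e += _STACK[_pair_code(s[i], s[j]), _pair_code(s[k], s[l])]
            elif g5 == 0 or g3 == 0:
                e += bulge_penalty(g5 + g3)
            else:
                e += internal_penalty(g5 + g3)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            e += _ML_CLOSE + _ML_BRANCH * (len(kids) + 1) + _ML_UNPAIRED * unpaired
    return e


def _fold_pair_count(s: str) -> np.ndarray:
    """Nussinov maximum-matching fold with min hairpin loop 3."""
    n = len(s)
    M = np.zeros((n, n), dtype=int)
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]  # i unpaired
            if _pair_code(s[i], s[j]) >= 0:
                best = max(best, 1 + (M[i + 1, j - 1] if j - i > 1 else 0))
            for k in range(i + 1 + MIN_HAIRPIN_LOOP, j):
                if _pair_code(s[i], s[k]) >= 0:
                    inner = M[i + 1, k - 1] if k - 1 > i + 1 else 0
                    best = max(best, 1 + inner + M[k + 1, j])
            M[i, j] = best
    pt = np.full(n, -1, dtype=int)

    def trace(i: int, j: int) -> None:
        while i < j:
            if M[i, j] == (M[i + 1, j] if i + 1 <= j else 0):
                i += 1
                continue
            # i must pair; prefer the smallest partner k (leftmost bracket)
            for k in range(i + 1 + MIN_HAIRPIN_LOOP, j + 1):
                if _pair_code(s[i], s[k]) < 0:
                    continue
                inner = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                rest = M[k + 1, j] if k + 1 <= j else 0
                if M[i, j] == 1 + inner + rest:
                    pt[i], pt[k] = k, i
                    trace(i + 1, k - 1)
                    i, j = k + 1, j
                    break
            else:  # pragma: no cover - DP guarantees a case matches
                raise AssertionError("traceback failed")
        return

    trace(0, n - 1)
    return pt


def _fold_nearest_neighbor(s: str) -> np.ndarray:
    n = len(s)
    code = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in s])
    ptype = np.full((n, n), -1, dtype=int)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            ptype[i, j] = _pair_code(s[i], s[j])

    V = np.full((n, n), _INF)
    WM = np.full((n, n), _INF)

    # interior-loop penalty lattice: PEN[l5, l3], (0,0) excluded (stack case)
    L = MAX_INTERIOR
    PEN = np.full((L + 1, L + 1), _INF)
    for a in range(L + 1):
        for b in range(L + 1):
            if a == 0 and b == 0:
                continue
            PEN[a, b] = bulge_penalty(a + b) if (a == 0 or b == 0) else internal_penalty(a + b)

    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            p = ptype[i, j]
            if p >= 0:
                best = hairpin_penalty(j - i - 1)
                # stack
                if j - i >= MIN_HAIRPIN_LOOP + 3 and ptype[i + 1, j - 1] >= 0:
                    cand = _STACK[p, ptype[i + 1, j - 1]] + V[i + 1, j - 1]
                    if cand < best:
                        best = cand
                # bulges / internal loops (per-side cap L)
                for l5 in range(0, min(L, j - i - 2) + 1):
                    ip = i + 1 + l5
                    jp_hi = j - 1 if l5 > 0 else j - 2  # (0,0) is the stack case
                    jp_lo = max(ip + MIN_HAIRPIN_LOOP + 1, j - 1 - L)
                    if jp_lo > jp_hi:
                        continue
                    row = V[ip, jp_lo : jp_hi + 1]
                    pen = PEN[l5, j - 1 - jp_hi : j - jp_lo][::-1]
                    cand = np.min(row + pen)
                    if cand < best:
                        best = cand
                # multibranch: closing pair + >=2 branches inside
                if j - i > 6:
                    ks = np.arange(i + 1, j - 1)
                    cand = np.min(WM[i + 1, i + 1 : j - 1] + WM[i + 2 : j, j - 1]) if len(ks) else _INF
                    cand += _ML_CLOSE + _ML_BRANCH
                    if cand < best:
                        best = cand
                V[i, j] = best - _PAIR_BIAS

            # WM: segment inside a multiloop carrying >= 1 branch
            w = WM[i + 1, j] + _ML_UNPAIRED if i + 1 <= j else _INF
            w = min(w, WM[i, j - 1] + _ML_UNPAIRED)
            if V[i, j] < _INF / 2:
                w = min(w, V[i, j] + _ML_BRANCH)
            if j - i >= 1:
                split = np.min(WM[i, i : j] + WM[i + 1 : j + 1, j])
                w = min(w, split)
            WM[i, j] = w

    # exterior strand: E[i] = min energy of suffix i..n-1, unpaired bases free
    E = np.zeros(n + 1)
    for i in range(n - 1, -1, -1):
        best = E[i + 1]
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            if V[i, j] < _INF / 2:
                cand = V[i, j] + E[j + 1]
                if cand < best - 1e-12:
                    best = cand
        E[i] = best

    pt = np.full(n, -1, dtype=int)
    tol = 1e-9

    def trace_v(i: int, j: int) -> None:
        pt[i], pt[j] = j, i
        p = ptype[i, j]
        target = V[i, j] + _PAIR_BIAS
        # hairpin
        if abs(target - hairpin_penalty(j - i - 1)) < tol:
            return
        # stack
        if ptype[i + 1, j - 1] >= 0 and abs(target - (_STACK[p, ptype[i + 1, j - 1]] + V[i + 1, j - 1])) < tol:
            trace_v(i + 1, j - 1)
            return
        # interior, leftmost-first
        for l5 in range(0, min(L, j - i - 2) + 1):
            ip = i + 1 + l5
            for jp in range(j - 1 if l5 > 0 else j - 2, max(ip + MIN_HAIRPIN_LOOP + 1, j - 1 - L) - 1, -1):
                l3 = j - 1 - jp
                if V[ip, jp] < _INF / 2 and abs(target - (PEN[l5, l3] + V[ip, jp])) < tol:
                    trace_v(ip, jp)
                    return
        # multibranch
        for k in range(i + 1, j - 1):
            if abs(target - (_ML_CLOSE + _ML_BRANCH + WM[i + 1, k] + WM[k + 1, j - 1])) < tol:
                trace_wm(i + 1, k)
                trace_wm(k + 1, j - 1)
                return
        raise AssertionError("V traceback failed")  # pragma: no cover

    def trace_wm(i: int, j: int) -> None:
        while i <= j:
            if V[i, j] < _INF / 2 and abs(WM[i, j] - (V[i, j] + _ML_BRANCH)) < tol:
                trace_v(i, j)
                return
            if abs(WM[i, j] - (WM[i + 1, j] + _ML_UNPAIRED)) < tol:
                i += 1
                continue
            if abs(WM[i, j] - (WM[i, j - 1] + _ML_UNPAIRED)) < tol:
                j -= 1
                continue
            for k in range(i, j):
                if abs(WM[i, j] - (WM[i, k] + WM[k + 1, j])) < tol:
                    trace_wm(i, k)
                    i = k + 1
                    break
            else:  # pragma: no cover
                raise AssertionError("WM traceback failed")

    i = 0
    while i < n:
        if abs(E[i] - E[i + 1]) < tol and not any(
            V[i, j] < _INF / 2 and abs(E[i] - (V[i, j] + E[j + 1])) < tol for j in range(i + 4, n)
        ):
            i += 1
            continue
        advanced = False
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            if V[i, j] < _INF / 2 and abs(E[i] - (V[i, j] + E[j + 1])) < tol:
                trace_v(i, j)
                i = j + 1
                advanced = True
                break
        if not advanced:
            i += 1
    return pt


def fold_mfe(sequence: str, model: str = "nearest_neighbor") -> SecondaryStructure:
    """Fold one sequence into its minimum-energy nested structure.

    Parameters
    ----------
    sequence
        10-400 nt, ACGT/U alphabet (U is normalized to T internally).
    model
        ``"nearest_neighbor"`` (default, kcal/mol) or ``"pair_count"``
        (every pair -1, loops free; Nussinov test mode).
    """
    s = normalize_seq(sequence)
    if not (10 <= len(s) <= 400):
        raise FoldError(f"sequence length {len(s)} outside supported range 10-400")
    if model == "pair_count":
        pt = _fold_pair_count(s)
        energy = -float((pt >= 0).sum() // 2)
    elif model == "nearest_neighbor":
        pt = _fold_nearest_neighbor(s)
        energy = structure_energy(s, pt)
    else:
        raise ValueError(f"unknown model {model!r}")
    return SecondaryStructure(s, pt, dotbracket_from_pair_table(pt), energy)


@dataclass
class Loop:
    """An unpaired interruption between two consecutive stem pairs.

    ``run5``/``run3`` are (start, length) of the unpaired run on the 5' and 3'
    strand side (length 0 if absent).  A bulge has one zero-length side; an
    internal loop has both > 0.
    """

    run5: tuple[int, int]
    run3: tuple[int, int]

    @property
    def total_nt(self) -> int:
        return self.run5[1] + self.run3[1]

    @property
    def biased(self) -> bool:
        return self.total_nt > 0 and (self.run5[1] == 0 or self.run3[1] == 0)

    def positions(self) -> list[int]:
        return list(range(self.run5[0], self.run5[0] + self.run5[1])) + list(
            range(self.run3[0], self.run3[0] + self.run3[1])
        )


@dataclass
class StemLoop:
    """Segmentation of a single stem-loop: stem pairs, loops, terminal loop."""

    outer: tuple[int, int]
    stem_pairs: list[tuple[int, int]]  # outermost -> innermost
    loops: list[Loop]
    terminal_loop: tuple[int, int]  # half-open [start, end)

    @property
    def loop_len(self) -> int:
        return self.terminal_loop[1] - self.terminal_loop[0]

    def stem_positions(self) -> set[int]:
        """All positions between the outer pair and the terminal loop."""
        i, j = self.outer
        ls, le = self.terminal_loop
        return set(range(i, ls)) | set(range(le, j + 1))


def annotate_stemloop(structure: SecondaryStructure) -> StemLoop:
    """Segment a structure into one stem-loop (stem pairs, bulges, terminal loop).

    If the structure contains several disjoint helices at the exterior level,
    the stem-loop carrying the most pairs is annotated (flanking hairpins in a
    genomic window are ignored).  A multibranch loop *inside* the chosen
    component is not a hairpin and raises :class:`NotHairpinError`.
    """
    pt = structure.pair_table
    n = len(pt)
    components = _children(pt, -1, n)
    if not components:
        raise NotHairpinError("structure has no pairs")

    def count_pairs(i: int, j: int) -> int:
        return int(sum(1 for k in range(i, j + 1) if pt[k] > k))

    outer = max(components, key=lambda c: (count_pairs(*c), -c[0]))
    i, j = outer
    stem_pairs: list[tuple[int, int]] = []
    loops: list[Loop] = []
    while True:
        stem_pairs.append((i, j))
        kids = _children(pt, i, j)
        if len(kids) > 1:
            raise NotHairpinError("multibranch structure inside the main stem")
        if not kids:
            return StemLoop(outer, stem_pairs, loops, (i + 1, j))
        (k, l) = kids[0]
        g5, g3 = k - i - 1, j - l - 1
        if g5 or g3:
            loops.append(Loop((i + 1, g5), (l + 1, g3)))
        i, j = k, l


@dataclass
class HairpinMetrics:
    """Structural quantities measured on one candidate precursor placement."""

    stem_bulge_max_nt: int
    stem_bp: int
    free_energy: float
    hairpin_len: int
    loop_len: int
    mature_bulge_max_nt: int
    mature_biased_errors_max: int
    mature_biased_bulges: int
    mature_errors: int
    mature_bp: int
    mature_pct_in_stem: float
    extra: dict = field(default_factory=dict)


def measure(
    structure: SecondaryStructure,
    segmentation: StemLoop,
    mature: tuple[int, int],
) -> HairpinMetrics:
    """Measure the screening quantities for one mature placement.

    ``mature`` is a 0-based half-open interval on the folded sequence.
    "Errors" in the mature region are its unpaired nucleotides; a loop
    "touches" the mature region if any of its unpaired positions falls inside
    the mature interval; "biased" means all unpaired nucleotides of the loop
    lie on one strand.
    """
    ms, me = mature
    if not (0 <= ms < me <= len(structure.sequence)):
        raise ValueError(f"mature interval {mature} outside sequence")
    pt = structure.pair_table
    seg = segmentation
    mature_pos = set(range(ms, me))

    stem_bulge_max = max((lp.total_nt for lp in seg.loops), default=0)
    i, j = seg.outer

    touching = [lp for lp in seg.loops if mature_pos & set(lp.positions())]
    mature_bulge_max = max((lp.total_nt for lp in touching), default=0)
    biased_bulges = sum(1 for lp in touching if lp.biased)
    biased_errors_max = max(
        (max(lp.run5[1], lp.run3[1]) for lp in touching), default=0
    )

    mature_errors = sum(1 for k in mature_pos if pt[k] < 0)
    mature_bp = sum(1 for k in mature_pos if pt[k] >= 0)
    in_stem = len(mature_pos & seg.stem_positions())

    return HairpinMetrics(
        stem_bulge_max_nt=stem_bulge_max,
        stem_bp=len(seg.stem_pairs),
        free_energy=structure.free_energy,
        hairpin_len=j - i + 1,
        loop_len=seg.loop_len,
        mature_bulge_max_nt=mature_bulge_max,
        mature_biased_errors_max=biased_errors_max,
        mature_biased_bulges=biased_bulges,
        mature_errors=mature_errors,
        mature_bp=mature_bp,
        mature_pct_in_stem=100.0 * in_stem / len(mature_pos),
    )


def duplex_energy(mirna: str, target_site: str) -> float:
    """Stacking energy of the miRNA:target duplex implied by antiparallel alignment.

    Pairs miRNA position k with target position (len-1-k) and sums stacking
    increments over consecutive canonical pairs.  Used as the energy gate of
    the complementarity target predictor.
    """
    a = normalize_seq(mirna)
    b = normalize_seq(target_site)
    m = min(len(a), len(b))
    codes = [_pair_code(a[k], b[len(b) - 1 - k]) for k in range(m)]
    e = 0.0
    for k in range(m - 1):
        if codes[k] >= 0 and codes[k + 1] >= 0:
            e += _STACK[codes[k], codes[k + 1]]
    return e
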