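"""RNA secondary-structure folding for hairpin screening.

The default engine is a dynamic-programming minimizer over non-crossing base
pairings scoring *stacked* pairs only: a pair (i, j) contributes energy when
(i+1, j-1) is also paired, with GC = -3.0, AU = -2.0, GU = -1.0 kcal/mol per
stacked pair, a minimum hairpin loop of 3 nt, and no pseudoknots.  Isolated
(unstacked) pairs carry zero energy and are never emitted by the traceback.
This keeps the model exactly reproducible by brute-force enumeration while
preserving the ranking behaviour that matters for hairpin screening; a full
thermodynamic engine (ViennaRNA's RNAfold) can be substituted through the
same ``(sequence) -> (dot-bracket, dG)`` signature.
"""

from __future__ import annotations

import shutil
import subprocess
from typing import Callable

import numpy as np

from ._util import to_rna

MIN_LOOP = 3

#: stacking energy (kcal/mol) attributed to a pair closing a stack
PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

FoldEngine = Callable[[str], tuple[str, float]]


def pair_energy(a: str, b: str) -> float | None:
    return PAIR_ENERGY.get((a, b))


def stacking_fold(seq: str) -> tuple[str, float]:
    """Minimum-energy structure of ``seq`` under the stacking model.

    Returns (dot-bracket string, dG in kcal/mol).  Accepts RNA or DNA
    alphabet; T is read as U.
    """
    s = to_rna(seq)
    n = len(s)
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU symbol(s) in window: {sorted(bad)}")
    if n == 0:
        return "", 0.0

    e = np.zeros((n, n))
    can = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            en = PAIR_ENERGY.get((s[i], s[j]))
            if en is not None:
                can[i, j] = True
                e[i, j] = en

    INF = np.inf
    # W[i, j]: best energy on [i, j]; row n and i > j mean the empty interval.
    W = np.zeros((n + 1, n))
    V = np.full((n, n), INF)

    for span in range(MIN_LOOP + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            if can[i, j]:
                v = W[i + 1, j - 1]
                if V[i + 1, j - 1] < INF:
                    v = min(v, e[i, j] + V[i + 1, j - 1])
                V[i, j] = v
            lo = i + MIN_LOOP + 1
            best = W[i + 1, j]
            if lo <= j:
                cand = V[i, lo : j + 1] + W[lo + 1 : j + 2, j]
                m = cand.min()
                if m < best:
                    best = m
            W[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack: list[tuple[int, int, str]] = [(0, n - 1, "W")]
    while stack:
        i, j, state = stack.pop()
        if i >= j:
            continue
        if state == "W":
            if W[i, j] == W[i + 1, j]:
                stack.append((i + 1, j, "W"))
                continue
            for k in range(i + MIN_LOOP + 1, j + 1):
                if V[i, k] < INF and V[i, k] + W[k + 1, j] == W[i, j]:
                    stack.append((i, k, "V"))
                    stack.append((k + 1, j, "W"))
                    break
        else:  # V: i pairs j
            pairs.append((i, j))
            if (
                can[i + 1, j - 1]
                and V[i + 1, j - 1] < INF
                and e[i, j] + V[i + 1, j - 1] == V[i, j]
            ):
                stack.append((i + 1, j - 1, "V"))
            else:
                stack.append((i + 1, j - 1, "W"))

    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db), float(W[0, n - 1])


def vienna_fold(seq: str) -> tuple[str, float]:
    """Pluggable thermodynamic backend calling ViennaRNA's ``RNAfold``."""
    if shutil.which("RNAfold") is None:
        raise RuntimeError("RNAfold executable not found on PATH")
    out = subprocess.run(
        ["RNAfold", "--noPS"],
        input=to_rna(seq) + "\n",
        capture_output=True,
        text=True,
        check=True,
    ).stdout.splitlines()
    struct_line = out[1]
    db = struct_line.split()[0]
    dg = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
    return db, dg


def fold(window: str, engine: FoldEngine | None = None,
         min_len: int = 40, max_len: int = 200) -> tuple[str, float]:
    """Fold a candidate precursor window (length ``min_len``..``max_len``)."""
    if not (min_len <= len(window) <= max_len):
        raise ValueError(
            f"window length {len(window)} outside [{min_len}, {max_len}]"
        )
    return (engine or stacking_fold)(window)


# ---------------------------------------------------------------------------
# dot-bracket structure analysis


def parse_pairs(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for k, c in enumerate(db):
        if c == "(":
            stack.append(k)
        elif c == ")":
            pairs.append((stack.pop(), k))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def _pair_tree(pairs):
    """Nesting forest: children map and parent map over sorted pairs."""
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and not (stack[-1][0] < p[0] < p[1] < stack[-1][1]):
            stack.pop()
        parent[p] = stack[-1] if stack else None
        if stack:
            children[stack[-1]].append(p)
        stack.append(p)
    return children, parent


def helices(pairs) -> list[list[tuple[int, int]]]:
    """Maximal runs of directly stacked pairs, sorted longest first."""
    pset = set(pairs)
    runs = []
    for p in pairs:
        if (p[0] - 1, p[1] + 1) in pset:
            continue  # not a run start
        run = [p]
        q = (p[0] + 1, p[1] - 1)
        while q in pset:
            run.append(q)
            q = (q[0] + 1, q[1] - 1)
        runs.append(run)
    runs.sort(key=lambda r: (-len(r), r[0][0]))
    return runs


def main_stemloop(db: str):
    """Locate the dominant stem-loop of a structure.

    The main stem-loop is the maximal non-branching chain of nested pairs
    anchored at a hairpin loop that contains the window's longest helix.
    Returns ``None`` for an unpaired window, the string ``"multiloop"`` when
    the longest helix sits above a branch point (no single stem-loop), or a
    dict with the chain's outer pair, innermost (loop-closing) pair and the
    set of chain pairs.
    """
    pairs = parse_pairs(db)
    if not pairs:
        return None
    children, parent = _pair_tree(pairs)
    top_helix = helices(pairs)[0]

    # build the non-branching chain upward from each hairpin loop
    chains = []
    for p, kids in children.items():
        if kids:
            continue
        chain = [p]
        cur = p
        while True:
            par = parent[cur]
            if par is None or len(children[par]) != 1:
                break
            chain.append(par)
            cur = par
        chains.append(chain)

    anchor = top_helix[0]
    for chain in chains:
        if anchor in chain:
            inner = chain[0]
            outer = chain[-1]
            return {
                "outer": outer,
                "inner": inner,
                "pairs": set(chain),
                "n_pairs": len(chain),
            }
    return "multiloop"
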