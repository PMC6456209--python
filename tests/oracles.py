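"""Independent oracles used by the test suite.

Everything here is deliberately written from the definitions, not from the
package's code paths: exhaustive enumeration of nested structures, a
stand-alone energy evaluator, a direct column-pair CBC scan, and set-partition
enumeration for the minimal species count.
"""

from __future__ import annotations

import itertools
import math

VALID = {"AU", "UA", "GC", "CG", "GU", "UG"}


def enumerate_structures(seq: str, minloop: int = 3):
    """Yield every nested pair set (tuples of 0-based pairs) for a sequence."""
    n = len(seq)

    def ok(i, j):
        return seq[i] + seq[j] in VALID and j - i - 1 >= minloop

    def rec(i, j):
        if i > j:
            yield ()
            return
        yield from rec(i + 1, j)  # i unpaired
        for k in range(i + minloop + 1, j + 1):
            if ok(i, k):
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        yield ((i, k),) + inner + outer

    yield from rec(0, n - 1)


# the simplified thermodynamic model, restated from its definition
_STRENGTH = {"AU": 1.1, "UA": 1.1, "GC": 1.7, "CG": 1.7, "GU": 0.7, "UG": 0.7}


def independent_energy(seq: str, pairs, model: str = "stacking", max_internal: int = 30):
    """Loop-decomposition energy via a partner-map walk (no shared code with
    the package's evaluator)."""
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    if model == "pair-count":
        return -1.0 * len(pairs)
    total = 0.0
    for i, j in pairs:
        kids = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        if not kids:
            total += 3.0 + 0.3 * unpaired
        elif len(kids) == 1:
            if unpaired == 0:
                total += -(_STRENGTH[seq[i] + seq[j]] + _STRENGTH[seq[kids[0][0]] + seq[kids[0][1]]])
            elif unpaired <= max_internal:
                total += 2.0 + 0.3 * unpaired
            else:
                return math.inf  # model cannot score it
        else:
            total += 3.4 + 0.4 * (1 + len(kids)) + 0.1 * unpaired
    return round(total, 9)


def brute_force_mfe(seq: str, model: str = "stacking", minloop: int = 3):
    """Minimum energy over exhaustive enumeration."""
    return min(
        independent_energy(seq, prs, model) for prs in enumerate_structures(seq, minloop)
    )


def cbc_scan(rows: dict[str, str], decode, x: str, y: str):
    """Direct CBC/hemi scan over all column pairs of a gapped alignment.

    ``rows`` maps record id -> gapped 12-letter string; ``decode`` maps one
    letter -> (residue, state).
    """

    def col_pairs(rid):
        stack, out = [], {}
        for c, ch in enumerate(rows[rid]):
            if ch == "-":
                continue
            state = decode(ch)[1]
            if state == "(":
                stack.append(c)
            elif state == ")":
                i = stack.pop()
                out[(i, c)] = True
        return out

    px, py = col_pairs(x), col_pairs(y)
    ncol = len(rows[x])
    cbc = hemi = 0
    for i in range(ncol):
        for j in range(i + 1, ncol):
            if (i, j) not in px or (i, j) not in py:
                continue
            xi, xj = decode(rows[x][i])[0], decode(rows[x][j])[0]
            yi, yj = decode(rows[y][i])[0], decode(rows[y][j])[0]
            if xi + xj not in VALID or yi + yj not in VALID:
                continue
            d = (xi != yi) + (xj != yj)
            if d == 2:
                cbc += 1
            elif d == 1:
                hemi += 1
    return cbc, hemi


def set_partitions(items):
    """All set partitions of a small collection."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [first]] + part[k + 1 :]
        yield part + [[first]]


def brute_force_min_blocks(ids, has_edge):
    """Minimum number of blocks with no internal edge, by partition search."""
    best = len(ids)
    for part in set_partitions(ids):
        if len(part) >= best:
            continue
        if all(
            not has_edge(a, b)
            for blk in part
            for a, b in itertools.combinations(blk, 2)
        ):
            best = len(part)
    return best
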