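"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written with plain Python loops, sets and
strings, sharing no code with the package's numpy-based paths.
"""

from itertools import combinations

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
    "-": set(),
}
AMBIGUOUS = set("RYSWKMBDHVN")


def column_differs(x: str, y: str) -> bool:
    """Window-policy difference: gap-gap matches, gap-base differs,
    bases differ when their IUPAC sets are disjoint."""
    if x == "-" and y == "-":
        return False
    return not (IUPAC_SETS[x] & IUPAC_SETS[y])


def window_hamming(a: str, b: str, start: int, length: int) -> int:
    """Mismatches over a window; *start* is a 1-based alignment column."""
    return sum(column_differs(x, y)
               for x, y in zip(a[start - 1:start - 1 + length],
                               b[start - 1:start - 1 + length]))


def p_distance(a: str, b: str, gap_policy: str = "count",
               max_indel: int = 20) -> float:
    """Direct-count p-distance with long-gap-run exclusion."""
    def long_run_columns(s: str) -> set:
        cols, run = set(), []
        for i, ch in enumerate(s + "$"):
            if ch == "-":
                run.append(i)
            else:
                if len(run) > max_indel:
                    cols.update(run)
                run = []
        return cols

    skip = long_run_columns(a) | long_run_columns(b)
    diffs = comparable = 0
    for i, (x, y) in enumerate(zip(a, b)):
        if i in skip:
            continue
        if x == "-" and y == "-":
            continue
        if (x == "-") != (y == "-"):
            if gap_policy == "count":
                comparable += 1
                diffs += 1
            continue
        comparable += 1
        if not (IUPAC_SETS[x] & IUPAC_SETS[y]):
            diffs += 1
    if comparable == 0:
        raise ZeroDivisionError("no comparable columns")
    return diffs / comparable


def best_window(seqs: dict, targets: list, canonical: str,
                span: tuple, l_min: int = 20, l_max: int = 30,
                min_separation: int = 2):
    """Exhaustive enumeration + filtering + ranking for one region.

    Returns (start_column, length, d_in, d_out) of the best window or
    None, ranked by margin desc, then fewest canonical gaps, then
    leftmost, then shortest.
    """
    r0, r1 = span
    canon = seqs[canonical]
    non_targets = [a for a in seqs if a not in set(targets)]
    best = None
    for length in range(l_min, l_max + 1):
        for s in range(r0, r1 - length + 2):
            idx = range(s - 1, s - 1 + length)
            ambiguous = any(seqs[t][i] in AMBIGUOUS for t in targets for i in idx)
            if ambiguous:
                continue
            d_in = max(sum(column_differs(canon[i], seqs[t][i]) for i in idx)
                       for t in targets)
            d_out = min(sum(column_differs(canon[i], seqs[a][i]) for i in idx)
                        for a in non_targets)
            if d_out < min_separation or d_in > d_out - 1:
                continue
            gaps = sum(canon[i] == "-" for i in idx)
            score = (-(d_out - d_in), gaps, s, length)
            if best is None or score < best[0]:
                best = (score, s, length, d_in, d_out)
    if best is None:
        return None
    _, s, length, d_in, d_out = best
    return s, length, d_in, d_out


def jc69_expected_p(t: float) -> float:
    from math import exp
    return 0.75 * (1.0 - exp(-4.0 * t / 3.0))


# ---------------------------------------------------------------------------
# Tree oracles over a plain parent-pointer representation

def root_path(parents: dict, node) -> list:
    path = [node]
    while parents.get(node) is not None:
        node = parents[node]
        path.append(node)
    return path


def naive_mrca(parents: dict, leaves: list):
    """Deepest common element of the root paths."""
    paths = [root_path(parents, leaf) for leaf in leaves]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    # the first common node walking up from any leaf is the deepest
    for node in paths[0]:
        if node in common:
            return node
    raise AssertionError("no common ancestor")


def patristic(parents: dict, lengths: dict, a, b) -> float:
    pa = root_path(parents, a)
    pb = set(root_path(parents, b))
    anc = next(n for n in pa if n in pb)
    def up(x):
        d = 0.0
        while x is not anc:
            d += lengths[x]
            x = parents[x]
        return d
    return up(a) + up(b)


def minimal_partition_size(qualifying: list) -> int | None:
    """Fewest disjoint qualifying leafsets covering their union.

    *qualifying* is a list of frozensets. Exhaustive search over
    combinations, feasible at toy scale.
    """
    universe = frozenset().union(*qualifying) if qualifying else frozenset()
    if not universe:
        return 0
    for k in range(1, len(qualifying) + 1):
        for combo in combinations(qualifying, k):
            union = frozenset().union(*combo)
            if union != universe:
                continue
            if sum(len(c) for c in combo) == len(union):  # disjoint
                return k
    return None


def single_linkage_clusters(items: list, dist, threshold: float) -> int:
    """Number of connected components of the <=threshold graph (union-find)."""
    parent = {i: i for i in items}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(items, 2):
        if dist(a, b) <= threshold:
            parent[find(a)] = find(b)
    return len({find(i) for i in items})
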