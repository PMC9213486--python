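"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the dynamic-programming recurrences of the
package: alignment scores come from exhaustive enumeration of alignment
paths, cluster memberships from breadth-first transitive closure, and
confusion matrices from direct counting.
"""

from __future__ import annotations

MATCH_STATE, UP_STATE, LEFT_STATE = 0, 1, 2


def enumerate_global(a, b, score, gap_open, gap_extend):
    """Optimal global affine-gap score by exhaustive path enumeration.

    A gap run of length k costs gap_open + k*gap_extend; a gap run in one
    direction may not directly follow one in the other (standard affine
    three-state convention).
    """
    m, n = len(a), len(b)
    best = [float("-inf")]

    def rec(i, j, state, acc):
        if i == m and j == n:
            if acc > best[0]:
                best[0] = acc
            return
        if i < m and j < n:
            rec(i + 1, j + 1, MATCH_STATE, acc + score(a[i], b[j]))
        if i < m and state != LEFT_STATE:
            cost = gap_extend if state == UP_STATE else gap_open + gap_extend
            rec(i + 1, j, UP_STATE, acc - cost)
        if j < n and state != UP_STATE:
            cost = gap_extend if state == LEFT_STATE else gap_open + gap_extend
            rec(i, j + 1, LEFT_STATE, acc - cost)

    rec(0, 0, MATCH_STATE, 0)
    return best[0]


def enumerate_local(a, b, score, gap_open, gap_extend):
    """Optimal local affine-gap score: paths from any start, scored at every
    diagonal column; the empty alignment scores 0."""
    m, n = len(a), len(b)
    best = [0]

    def rec(i, j, state, acc):
        if acc > best[0] and state == MATCH_STATE:
            best[0] = acc
        if i < m and j < n:
            rec(i + 1, j + 1, MATCH_STATE, acc + score(a[i], b[j]))
        if i < m and state != LEFT_STATE:
            cost = gap_extend if state == UP_STATE else gap_open + gap_extend
            rec(i + 1, j, UP_STATE, acc - cost)
        if j < n and state != UP_STATE:
            cost = gap_extend if state == LEFT_STATE else gap_open + gap_extend
            rec(i, j + 1, LEFT_STATE, acc - cost)

    for i in range(m):
        for j in range(n):
            rec(i, j, MATCH_STATE, 0)
    return best[0]


def transitive_closure_clusters(ids, linked):
    """Connected components by BFS over a link predicate on id pairs."""
    remaining = list(ids)
    clusters = []
    seen = set()
    for start in remaining:
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            x = queue.pop()
            if x in comp:
                continue
            comp.add(x)
            for y in remaining:
                if y not in comp and linked(x, y):
                    queue.append(y)
        seen |= comp
        clusters.append(frozenset(comp))
    return set(clusters)


def confusion_counts(called, truth, universe):
    """Direct confusion-matrix counting over a taxon universe."""
    tp = sum(1 for t in universe if t in called and t in truth)
    fp = sum(1 for t in universe if t in called and t not in truth)
    fn = sum(1 for t in universe if t not in called and t in truth)
    tn = sum(1 for t in universe if t not in called and t not in truth)
    return tp, fp, fn, tn
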