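"""Independent brute-force oracles shared by the test suite.

Each oracle re-derives a quantity by direct enumeration, independent of
the implementation path it checks.
"""

import re
from itertools import combinations, product


def oracle_indel_events(aln):
    """Maximal internal gap runs per row, grouped by exact coordinates,
    with the single-position absorption rule applied."""
    grouped = {}
    for taxon, row in zip(aln.taxa, aln.rows):
        for m in re.finditer(r"-+", row):
            if m.start() == 0 or m.end() == len(row):
                continue
            grouped.setdefault((m.start(), m.end()), set()).add(taxon)
    events = sorted(grouped.items())
    keep = []
    for (s, e), bearers in events:
        if e - s == 1 and any(e2 - s2 > 1 and b2 == bearers
                              and max(s2 - e, s - e2) <= 1
                              for (s2, e2), b2 in events):
            continue
        keep.append(((s, e), frozenset(bearers)))
    return keep


def oracle_pi(rows, gap_policy="exclude-columns"):
    """Direct O(n^2 L) pairwise difference counter."""
    n, length = len(rows), len(rows[0])
    ok = lambda c: c in "ACGT"
    npairs = n * (n - 1) / 2
    if gap_policy == "exclude-columns":
        cols = [c for c in range(length) if all(ok(r[c]) for r in rows)]
        if not cols:
            return float("nan")
        total = sum(sum(a[c] != b[c] for c in cols) for a, b in combinations(rows, 2))
        return total / npairs / len(cols)
    total = 0.0
    for a, b in combinations(rows, 2):
        sites = [c for c in range(length) if ok(a[c]) and ok(b[c])]
        if sites:
            total += sum(a[c] != b[c] for c in sites) / len(sites)
    return total / npairs


def all_rooted_binary_trees(labels):
    """Every rooted binary tree over the labels, as nested tuples."""
    labels = sorted(labels)
    if len(labels) == 1:
        return [labels[0]]
    trees = []
    rest = labels[1:]
    anchor = labels[0]
    for k in range(0, len(rest)):
        for combo in combinations(rest, k):
            left_labels = [anchor, *combo]
            right_labels = [x for x in rest if x not in combo]
            if not right_labels:
                continue
            for left in all_rooted_binary_trees(left_labels):
                for right in all_rooted_binary_trees(right_labels):
                    trees.append((left, right))
    return trees


def tree_to_newick(tree):
    if isinstance(tree, str):
        return tree
    return "(" + tree_to_newick(tree[0]) + "," + tree_to_newick(tree[1]) + ")"


def _tree_edges(tree, nodes=None, edges=None, parent=None):
    if nodes is None:
        nodes, edges = [], []
    idx = len(nodes)
    nodes.append(tree)
    if parent is not None:
        edges.append((parent, idx))
    if not isinstance(tree, str):
        _tree_edges(tree[0], nodes, edges, idx)
        _tree_edges(tree[1], nodes, edges, idx)
    return nodes, edges


def oracle_fitch_steps(tree, states):
    """Minimum changes over all internal labelings (binary states 0/1;
    '?' leaves unconstrained)."""
    nodes, edges = _tree_edges(tree)
    internal = [i for i, n in enumerate(nodes) if not isinstance(n, str)]
    leaves = [i for i, n in enumerate(nodes) if isinstance(n, str)]
    best = None
    for combo in product("01", repeat=len(internal)):
        assign = dict(zip(internal, combo))
        for i in leaves:
            assign[i] = states[nodes[i]]
        cost = 0
        for a, b in edges:
            sa, sb = assign[a], assign[b]
            if "?" in (sa, sb):
                continue
            cost += sa != sb
        if best is None or cost < best:
            best = cost
    return best


def oracle_fold(seq, bounds):
    """Exhaustive cloverleaf layout search written as nested position
    loops (independent traversal order from the implementation)."""
    pairs_ok = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                ("G", "U"), ("U", "G")}
    n = len(seq)
    best = None

    def stem_fits(i5, i3, length):
        return all((seq[i5 + k], seq[i3 + length - 1 - k]) in pairs_ok
                   for k in range(length))

    r = lambda b: range(b[0], b[1] + 1)
    for tail in r(bounds.tail):
        for la in r(bounds.acceptor):
            acc3 = n - tail - la
            if acc3 <= 0 or not stem_fits(0, acc3, la):
                continue
            for l1 in r(bounds.link1):
                for ld in r(bounds.d_stem):
                    for dl in r(bounds.d_loop):
                        d5 = la + l1
                        d3 = d5 + ld + dl
                        if d3 + ld > acc3 or not stem_fits(d5, d3, ld):
                            continue
                        for l2 in r(bounds.link2):
                            for lac in r(bounds.ac_stem):
                                for acl in r(bounds.ac_loop):
                                    ac5 = d3 + ld + l2
                                    ac3 = ac5 + lac + acl
                                    if ac3 + lac > acc3 or not stem_fits(ac5, ac3, lac):
                                        continue
                                    for lt in r(bounds.t_stem):
                                        for tl in r(bounds.t_loop):
                                            t3 = acc3 - lt
                                            t5 = t3 - tl - lt
                                            v = t5 - (ac3 + lac)
                                            if not (bounds.v_region[0] <= v <= bounds.v_region[1]):
                                                continue
                                            if t5 < 0 or not stem_fits(t5, t3, lt):
                                                continue
                                            score = la + ld + lac + lt
                                            key = (-score, la, l1, ld, dl, l2,
                                                   lac, acl, lt, tl, tail)
                                            if best is None or key < best[0]:
                                                db = ["."] * n
                                                for (i5, i3, ln) in ((0, acc3, la), (d5, d3, ld),
                                                                     (ac5, ac3, lac), (t5, t3, lt)):
                                                    for k in range(ln):
                                                        db[i5 + k] = "("
                                                        db[i3 + ln - 1 - k] = ")"
                                                best = (key, "".join(db))
    return None if best is None else best[1]
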