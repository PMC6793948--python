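"""Independent brute-force reference implementations used only by tests.

Each oracle is written as a direct, unvectorised transcription of the
defining formula, deliberately sharing no code with the package.
"""

import math


def gower_pair(values_i, values_j, scales, all_values):
    """Gower dissimilarity for one species pair, averaging per-trait terms.

    ``all_values[t]`` is the full per-species value list for trait ``t``
    (used for ranges and Podani ranks); missing entries are None.
    """
    terms = []
    for t, scale in enumerate(scales):
        xi, xj = values_i[t], values_j[t]
        if xi is None or xj is None:
            continue
        col = [v for v in all_values[t] if v is not None]
        if scale == "binary":
            terms.append(0.0 if xi == xj else 1.0)
        elif scale == "continuous":
            rng = max(col) - min(col)
            terms.append(0.0 if rng == 0 else abs(xi - xj) / rng)
        else:  # ordinal, Podani (1999) tie-corrected ranks
            if xi == xj:
                terms.append(0.0)
                continue
            sorted_col = sorted(col)

            def rank(v):
                idx = [k for k, u in enumerate(sorted_col) if u == v]
                return sum(i + 1 for i in idx) / len(idx)

            def ties(v):
                return sorted_col.count(v)

            r_min, r_max = rank(min(col)), rank(max(col))
            t_min, t_max = ties(min(col)), ties(max(col))
            denom = r_max - r_min - (t_max - 1) / 2 - (t_min - 1) / 2
            if denom <= 0:
                terms.append(0.0)
            else:
                num = (abs(rank(xi) - rank(xj))
                       - (ties(xi) - 1) / 2 - (ties(xj) - 1) / 2)
                terms.append(num / denom)
    if not terms:
        return None
    return sum(terms) / len(terms)


def mpd_brute(community, dist_lookup):
    """Mean over all unordered pairs of a community; None if < 2 species."""
    community = list(community)
    if len(community) < 2:
        return None
    vals = []
    for i in range(len(community)):
        for j in range(i + 1, len(community)):
            vals.append(dist_lookup[(community[i], community[j])])
    return sum(vals) / len(vals)


def isolation_brute(neighbors, base=10.0):
    """-log_base of the summed area / squared-distance kernel."""
    total = sum(a / d**2 for a, d in neighbors)
    return -math.log(total, base)


def bh_adjust_brute(pvalues):
    """Benjamini–Hochberg step-up adjusted p-values, by the definition:
    p_adj(i) = min over j >= i (in sorted order) of m * p(j) / j, capped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [None] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, m * pvalues[i] / (pos + 1))
        adj[i] = min(1.0, running)
    return adj


def welch_brute(a, b):
    """Welch t and Satterthwaite df from the textbook formulas."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def pearson_brute(x, y):
    """Sample correlation from the covariance definition."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def random_tree_tuples(rng, n_tips, prefix="x"):
    """Random binary tree as nested ((child, length), (child, length))
    tuples; leaves are label strings."""
    nodes = [(f"{prefix}{i}", float(rng.uniform(0.1, 2.0))) for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(((a, b), float(rng.uniform(0.1, 2.0))))
    return nodes[0][0]


def tree_to_newick(tree):
    def render(node, length):
        if isinstance(node, str):
            return f"{node}:{length}"
        (a, la), (b, lb) = node
        return f"({render(a, la)},{render(b, lb)}):{length}"

    (a, la), (b, lb) = tree
    return f"({render(a, la)},{render(b, lb)});"


def tip_path_lengths(tree):
    """Tip -> root-path total branch length, by explicit recursion."""
    out = {}

    def walk(node, acc):
        if isinstance(node, str):
            out[node] = acc
            return
        for child, length in node:
            walk(child, acc + [length])

    walk(tree, [])
    return out


def tip_paths(tree):
    """Tip -> list of internal node ids on its root path (for LCA)."""
    out = {}

    def walk(node, acc, nid):
        if isinstance(node, str):
            out[node] = acc
            return
        for k, (child, _) in enumerate(node):
            walk(child, acc + [nid], (nid, k))

    walk(tree, [], ())
    return out


def cophenetic_brute(tree):
    """Pairwise patristic distances: depth(i) + depth(j) - 2 * depth(LCA)."""
    paths = tip_paths(tree)
    depth = {tip: sum(v) for tip, v in tip_path_lengths(tree).items()}
    node_depth = {}

    def walk3(node, acc, nid):
        node_depth[nid] = acc
        if isinstance(node, str):
            return
        for k, (child, length) in enumerate(node):
            walk3(child, acc + length, (nid, k))

    walk3(tree, 0.0, ())
    out = {}
    tips = list(paths)
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            a, b = tips[i], tips[j]
            shared = ()
            for na, nb in zip(paths[a], paths[b]):
                if na == nb:
                    shared = na
                else:
                    break
            d = depth[a] + depth[b] - 2 * node_depth[shared]
            out[(a, b)] = out[(b, a)] = d
    return out
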