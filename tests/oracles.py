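"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and biopython's
aligner): plain dynamic programming, quadratic scans and exhaustive
tallies, tractable at test sizes.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def nw_identity_pairs(a: str, b: str, match=1, mismatch=-1, gap=-2) -> int:
    """Identities of the best free-end-gap global alignment of a vs b.

    Pure-python DP maximizing (score, identities) lexicographically via a
    combined integer objective; leading and trailing gaps are free.
    """
    BIG = 1 << 20  # identities per alignment are far below this
    n, m = len(a), len(b)
    prev = [0] * (m + 1)
    best = 0
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                diag = prev[j - 1] + match * BIG + 1
            else:
                diag = prev[j - 1] + mismatch * BIG
            up = prev[j] + gap * BIG
            left = cur[j - 1] + gap * BIG
            cur[j] = max(diag, up, left)
        best = max(best, cur[m])  # free trailing gap in b
        prev = cur
    best = max(best, max(prev))  # free trailing gap in a (last row)
    return best % BIG


def identity_oracle(a: str, b: str) -> float:
    """Both-strand free-end-gap identity over the shorter sequence."""
    ident = max(nw_identity_pairs(a, b), nw_identity_pairs(a, revcomp(b)))
    return min(1.0, ident / min(len(a), len(b)))


def greedy_cluster_oracle(entries, threshold, identity_fn):
    """Replay the greedy clustering rule with an externally supplied
    identity function: longest-first order, join the first cluster whose
    founder matches at >= threshold."""
    ordered = sorted(entries, key=lambda e: (-len(e.sequence), e.family_id))
    clusters: list[list] = []
    for entry in ordered:
        for cluster in clusters:
            if identity_fn(entry.sequence, cluster[0].sequence) >= threshold:
                cluster.append(entry)
                break
        else:
            clusters.append([entry])
    return clusters


def overlap_len(a, b) -> int:
    """Overlap in bp of two hits (0 when on different chromosomes)."""
    if a.chromosome != b.chromosome:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def resolve_overlaps_oracle(hits, max_overlap_fraction=0.0):
    """Quadratic replay of the longer-hit-wins rule."""
    retained = []
    for h in sorted(hits, key=lambda h: (-h.length(), h.start, h.hit_id)):
        if all(
            overlap_len(h, r) <= max_overlap_fraction * h.length()
            for r in retained
            if r.chromosome == h.chromosome
        ):
            retained.append(h)
    return sorted(retained, key=lambda h: (h.chromosome, h.start, h.end))


def venn_tally_oracle(rows, species):
    """Brute-force subset tally of a boolean presence matrix."""
    counts: dict[frozenset, int] = {}
    for row in rows:
        subset = frozenset(sp for sp, flag in zip(species, row) if flag)
        if subset:
            counts[subset] = counts.get(subset, 0) + 1
    return counts


def kimura_closed_form(p: float, q: float) -> float:
    """-50 * ln((1-2P-Q) * sqrt(1-2Q)), independent evaluation."""
    return -50.0 * np.log((1.0 - 2.0 * p - q) * np.sqrt(1.0 - 2.0 * q))


def spearman_oracle(x, y) -> float:
    """Rank correlation via average ranks and the Pearson formula, by hand."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def random_additive_tree(rng, n_taxa):
    """Random binary tree with branch lengths in [0.5, 5].

    Returns (labels, distance matrix) where the matrix is the exact tree
    metric (hence additive).
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # each live node maps leaf -> distance to the node's attachment point
    nodes = [{lab: 0.0} for lab in labels]
    d = np.zeros((n_taxa, n_taxa))
    idx = {lab: i for i, lab in enumerate(labels)}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        li, lj = rng.uniform(0.5, 5.0, size=2)
        if len(nodes) == 2:
            lj = 0.0  # final join contributes a single edge
        u, v = nodes[i], nodes[j]
        for leaf_a, da in u.items():
            for leaf_b, db in v.items():
                d[idx[leaf_a], idx[leaf_b]] = d[idx[leaf_b], idx[leaf_a]] = (
                    da + li + db + lj
                )
        merged = {k: dv + li for k, dv in u.items()}
        merged.update({k: dv + lj for k, dv in v.items()})
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    return labels, d


def patristic_from_newick(newick: str, labels):
    """Leaf-to-leaf path lengths computed with scikit-bio's tree parser."""
    import io

    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    dm = tree.tip_tip_distances()
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = dm[labels[i], labels[j]]
    return out
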