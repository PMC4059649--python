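"""Independent brute-force oracles used to check the fast implementations.

Deliberately naive: quadratic scans, full enumeration, direct formulas.
They share no code with the package paths they verify.
"""

from __future__ import annotations

import math

_STOPS = {"TAA", "TAG", "TGA"}


def brute_force_tu_partition(features):
    """Connected components under pairwise interval overlap (same contig),
    via union-find over all pairs. Returns a set of frozensets of ids."""
    ids = [f.feature_id for f in features]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for i, f in enumerate(features):
        for g in features[:i]:
            if (
                f.contig == g.contig
                and f.start <= g.end
                and g.start <= f.end
            ):
                union(f.feature_id, g.feature_id)

    groups = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(v) for v in groups.values()}


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def exhaustive_longest_orf(sequence):
    """Longest ATG-initiated ORF (aa), scanning every start position on
    both strands; open-ended ORFs counted to the last complete codon."""
    best = 0
    for seq in (sequence.upper(), _revcomp(sequence.upper())):
        n = len(seq)
        for i in range(n - 2):
            if seq[i:i + 3] != "ATG":
                continue
            j = i + 3
            while j + 3 <= n and seq[j:j + 3] not in _STOPS:
                j += 3
            best = max(best, (j - i) // 3)
    return best


def nearest_genes_linear_scan(linc_start, linc_end, genes):
    """(upstream_id, up_gap, downstream_id, down_gap) by scanning every
    gene; ties broken toward the smaller start. genes: (id, start, end)."""
    up = down = None
    for gid, s, e in genes:
        if e < linc_start:
            key = (e, -s)
            if up is None or key > (up[2], -up[1]):
                up = (gid, s, e)
        elif s > linc_end:
            key = (s, s)
            if down is None or key < (down[1], down[1]):
                down = (gid, s, e)
    up_out = (None, None) if up is None else (up[0], linc_start - up[2] - 1)
    down_out = (
        (None, None) if down is None else (down[0], down[1] - linc_end - 1)
    )
    return up_out + down_out


def pearson_by_formula(x, y):
    """Product-moment coefficient evaluated directly from its definition."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den
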