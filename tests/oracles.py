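"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's algorithms: edges by an O(n^2)
all-pairs scan, tags by exhaustive path enumeration, tag search by a
naive per-position substring scan, k-mer uniqueness by a full index.
"""

from __future__ import annotations

import itertools
import math


STEP_REFERENCE_MZ = 1000.0


def brute_force_edges(mzs, table, tol_ppm):
    """All (i, j, labels) with j heavier and the gap within the
    absolute step window (tol_ppm at the fixed reference m/z) of a
    residue mass."""
    edges = {}
    masses = dict(table.items())
    for i, j in itertools.permutations(range(len(mzs)), 2):
        if mzs[j] <= mzs[i]:
            continue
        delta = mzs[j] - mzs[i]
        labels = []
        for code, rm in masses.items():
            err = 1e6 * (delta - rm) / STEP_REFERENCE_MZ
            if abs(err) <= tol_ppm:
                labels.append((code, err))
        if labels:
            labels.sort(key=lambda t: (abs(t[1]), t[0]))
            edges[(i, j)] = labels
    return edges


def brute_force_tags(mzs, table, tol_ppm, min_len=1):
    """All maximal paths as (residue-string, node-tuple, ppm-tuple),
    sorted by (length desc, mean |ppm| asc, residues asc)."""
    edges = brute_force_edges(mzs, table, tol_ppm)
    succ = {}
    has_pred = set()
    for (i, j), labels in edges.items():
        succ.setdefault(i, []).append(j)
        has_pred.add(j)

    paths = []

    def walk(path):
        node = path[-1]
        nxt = succ.get(node, [])
        if not nxt:
            paths.append(tuple(path))
            return
        for j in nxt:
            walk(path + [j])

    for start in succ:
        if start not in has_pred:
            walk([start])

    tags = []
    for path in paths:
        if len(path) - 1 < min_len:
            continue
        residues = ""
        ppms = []
        for a, b in zip(path, path[1:]):
            labels = edges[(a, b)]
            if len(labels) == 1:
                residues += labels[0][0]
            else:
                residues += "[" + "".join(c for c, _ in labels) + "]"
            ppms.append(labels[0][1])
        mean_ppm = sum(abs(p) for p in ppms) / len(ppms)
        tags.append((residues, path, tuple(ppms), mean_ppm))
    tags.sort(key=lambda t: (-(len(t[1]) - 1), t[3], t[0]))
    return [(r, p, e) for r, p, e, _ in tags]


def naive_tag_search(tag_string, db_sequences):
    """All (identifier, start_1based, orientation) occurrences of a tag
    (with [..] alternative groups) by per-position scanning."""
    steps = []
    i = 0
    while i < len(tag_string):
        if tag_string[i] == "[":
            j = tag_string.index("]", i)
            steps.append(set(tag_string[i + 1 : j]))
            i = j + 1
        else:
            steps.append({tag_string[i]})
            i += 1

    def occurrences(seq, step_sets):
        L = len(step_sets)
        for pos in range(len(seq) - L + 1):
            if all(seq[pos + k] in step_sets[k] for k in range(L)):
                yield pos + 1

    out = []
    for ident, seq in db_sequences.items():
        collapsed = seq.replace("I", "J").replace("L", "J")
        for pos in occurrences(collapsed, steps):
            out.append((ident, pos, "forward"))
        rev = steps[::-1]
        if rev != steps:
            for pos in occurrences(collapsed, rev):
                out.append((ident, pos, "reverse"))
    return out


def brute_force_kmer_uniqueness(sequences, k, collapse_il=True):
    """Fraction of sequences owning a k-mer absent from all others."""
    seqs = [
        s.replace("I", "J").replace("L", "J") if collapse_il else s
        for s in sequences
    ]
    kmer_sets = [
        {s[i : i + k] for i in range(len(s) - k + 1)} for s in seqs
    ]
    n_unique = 0
    for i, mine in enumerate(kmer_sets):
        others = set().union(*(kmer_sets[:i] + kmer_sets[i + 1 :])) if len(seqs) > 1 else set()
        if mine - others:
            n_unique += 1
    return n_unique / len(seqs)


def percentile_linear(values, q):
    """Linear-interpolation percentile (inclusive), independent of numpy."""
    xs = sorted(values)
    if not xs:
        raise ValueError("empty")
    rank = q / 100 * (len(xs) - 1)
    lo = math.floor(rank)
    hi = math.ceil(rank)
    if lo == hi:
        return xs[lo]
    frac = rank - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac
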