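"""Independent brute-force TMM oracle, written directly from the
trimmed-mean-of-M definition with plain Python loops and sorting.
Deliberately shares no code with the package implementation."""

import math


def naive_tmm(matrix):
    """matrix: list of rows (genes) of counts; returns per-column factors."""
    n_genes = len(matrix)
    n_samples = len(matrix[0])
    lib = [sum(matrix[g][j] for g in range(n_genes)) for j in range(n_samples)]

    # reference: column whose upper quartile (per library size) is closest
    # to the mean upper quartile
    uq = []
    for j in range(n_samples):
        col = sorted(matrix[g][j] for g in range(n_genes))
        # linear-interpolation quantile at p=0.75 (type 7)
        h = (n_genes - 1) * 0.75
        lo = int(math.floor(h))
        frac = h - lo
        q = col[lo] if lo + 1 >= n_genes else col[lo] * (1 - frac) + col[lo + 1] * frac
        uq.append(q / lib[j])
    mean_uq = sum(uq) / n_samples
    ref = min(range(n_samples), key=lambda j: abs(uq[j] - mean_uq))

    factors = []
    for j in range(n_samples):
        ms, abs_es, vs = [], [], []
        for g in range(n_genes):
            o, r = matrix[g][j], matrix[g][ref]
            if o > 0 and r > 0:
                po, pr = o / lib[j], r / lib[ref]
                ms.append(math.log2(po / pr))
                abs_es.append((math.log2(po) + math.log2(pr)) / 2)
                vs.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        if not ms or max(abs(m) for m in ms) < 1e-6:
            factors.append(1.0)
            continue
        n = len(ms)
        lo_m = math.floor(n * 0.3) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * 0.05) + 1
        hi_a = n + 1 - lo_a
        rank_m = _ranks(ms)
        rank_a = _ranks(abs_es)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += ms[i] / vs[i]
                den += 1.0 / vs[i]
        factors.append(2 ** (num / den) if den > 0 else 1.0)

    log_sum = sum(math.log(f) for f in factors)
    geo = math.exp(log_sum / n_samples)
    return [f / geo for f in factors]


def _ranks(values):
    """1-based ranks with ties averaged."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks
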