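"""Naive, definition-by-definition RQA reference used as an independent oracle.

Deliberately written with plain Python loops and none of the package's
machinery: embedding by explicit slicing, all-pairs distances with
math.dist, run-length scanning cell by cell.  Slow but unambiguous.
"""

import math


def reference_embed(values, p, lag):
    n = len(values) - (p - 1) * lag
    return [tuple(values[i + k * lag] for k in range(p)) for i in range(n)]


def reference_rqa(values, p=2, lag=1, r_frac=0.1, lmin=2, border=2, loi_in_vertical=True):
    """Compute the recurrence matrix, line histograms and all eight metrics."""
    em = reference_embed(list(map(float, values)), p, lag)
    n = len(em)

    dists = []
    for i in range(n):
        for j in range(i + 1, n):
            dists.append(math.dist(em[i], em[j]))
    mean_distance = sum(dists) / len(dists)
    if mean_distance == 0:
        raise ValueError("zero mean distance")
    r = r_frac * mean_distance

    R = [[False] * n for _ in range(n)]
    for i in range(n):
        R[i][i] = True
        for j in range(i + 1, n):
            if math.dist(em[i], em[j]) <= r:
                R[i][j] = R[j][i] = True

    def in_band(i, j):
        return border <= i < n - border and border <= j < n - border

    # trimmed copy
    M = [[R[i][j] and in_band(i, j) for j in range(n)] for i in range(n)]

    offdiag = sum(M[i][j] for i in range(n) for j in range(n) if i != j)

    diag_hist = {}
    diag_counts = [0] * (n - 1)  # upper diagonal k = 1 .. n-1
    lmax = 0
    for k in range(1, n):
        run = 0
        for i in range(0, n - k):
            if M[i][i + k]:
                diag_counts[k - 1] += 1
                run += 1
            else:
                if run >= lmin:
                    diag_hist[run] = diag_hist.get(run, 0) + 2
                    lmax = max(lmax, run)
                run = 0
        if run >= lmin:
            diag_hist[run] = diag_hist.get(run, 0) + 2
            lmax = max(lmax, run)

    vert_hist = {}
    loi_in_runs = 0
    for j in range(n):
        i = 0
        while i < n:
            if M[i][j] and (loi_in_vertical or i != j):
                start = i
                while i < n and M[i][j] and (loi_in_vertical or i != j):
                    i += 1
                length = i - start
                if length >= lmin:
                    vert_hist[length] = vert_hist.get(length, 0) + 1
                    if loi_in_vertical and start <= j < i:
                        loi_in_runs += 1
            else:
                i += 1

    rec = offdiag / n**2
    if offdiag:
        det = sum(k * v for k, v in diag_hist.items()) / offdiag
        lam = (sum(k * v for k, v in vert_hist.items()) - loi_in_runs) / offdiag
    else:
        det = lam = float("nan")
    if diag_hist:
        total = sum(diag_hist.values())
        ent = -sum((c / total) * math.log(c / total)
                   for _, c in sorted(diag_hist.items()))
        lmean = sum(k * c for k, c in sorted(diag_hist.items())) / total
    else:
        ent = lmean = float("nan")
    div = 1.0 / lmax if lmax else float("nan")
    if vert_hist:
        vtotal = sum(vert_hist.values())
        vmean = sum(k * c for k, c in sorted(vert_hist.items())) / vtotal
    else:
        vmean = float("nan")

    k_max = n - 1 - border
    if k_max >= 2:
        ks = list(range(1, k_max + 1))
        dens = [diag_counts[k - 1] / (n - k) for k in ks]
        kbar = sum(ks) / len(ks)
        dbar = sum(dens) / len(dens)
        tre = (sum((k - kbar) * (d - dbar) for k, d in zip(ks, dens))
               / sum((k - kbar) ** 2 for k in ks))
    else:
        tre = float("nan")

    return {
        "em": em, "matrix": R, "mean_distance": mean_distance, "radius": r,
        "diagonal_hist": diag_hist, "vertical_hist": vert_hist, "lmax": lmax,
        "n_offdiag": offdiag,
        "metrics": {"REC": rec, "DET": det, "LAM": lam, "ENT": ent, "DIV": div,
                    "TRE": tre, "Lmean": lmean, "Vmean": vmean},
    }
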