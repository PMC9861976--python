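"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible (explicit loops, direct
formulas) so it cannot share a bug with the vectorized library code it is
used to check.
"""

from __future__ import annotations

import math

import numpy as np


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[set]:
    """Connected components by literal flood fill; returns sets of (r, c)."""
    binary = np.asarray(binary, dtype=bool)
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = set()
    comps = []
    h, w = binary.shape
    for r in range(h):
        for c in range(w):
            if binary[r, c] and (r, c) not in seen:
                comp = set()
                stack = [(r, c)]
                seen.add((r, c))
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and binary[nr, nc] and (nr, nc) not in seen:
                            seen.add((nr, nc))
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


def confusion_by_loop(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    tp = fp = fn = tn = 0
    for p, t in zip(np.asarray(pred, bool).ravel(), np.asarray(truth, bool).ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def pearson_by_formula(x, y) -> tuple[float, float]:
    """Covariance/variance formula plus the t transform with n-2 df."""
    from scipy.stats import t as tdist

    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * tdist.sf(abs(t), n - 2)
    return r, p


def icc2_by_anova(x, y) -> float:
    """ICC(2,1) from an explicit two-way ANOVA decomposition (loops)."""
    data = [[float(a), float(b)] for a, b in zip(x, y)]
    n, k = len(data), 2
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((data[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def roc_by_sweep(conf: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by sweeping every observed confidence as a >= threshold."""
    conf = np.asarray(conf, float).ravel()
    truth = np.asarray(truth, bool).ravel()
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    pts = [(0.0, 0.0)]
    for thr in sorted(set(conf), reverse=True):
        pred = conf >= thr
        tpr = np.count_nonzero(pred & truth) / n_pos
        fpr = np.count_nonzero(pred & ~truth) / n_neg
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    pts = sorted(set(pts))
    fpr = np.array([p[0] for p in pts])
    tpr = np.array([p[1] for p in pts])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def block_max_resize_by_loop(row: np.ndarray, target: int) -> np.ndarray:
    """Per-target-column max over every overlapping source column."""
    w = len(row)
    out = np.zeros(target, dtype=row.dtype)
    for x in range(target):
        lo, hi = x * w / target, (x + 1) * w / target
        vals = [row[s] for s in range(w) if s + 1 > lo and s < hi]
        out[x] = max(vals)
    return out


def confluence_by_loop(ez, rpe, bm, tol):
    """Column loop testing both thickness conditions independently."""
    out = []
    for e, r, b in zip(ez, rpe, bm):
        defined = not (math.isnan(e) or math.isnan(r) or math.isnan(b))
        out.append(defined and (r - e) <= tol and (b - r) <= tol)
    return np.array(out)
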