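"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's optimizer paths: curve-fit oracles
are iteratively refined exhaustive grid searches; the DeLong oracle
enumerates the ranking kernel with explicit Python loops.
"""

import numpy as np


def _refine(lo, hi, best, shrink=0.15, floor=0.0):
    span = (hi - lo) * shrink
    return max(floor, best - span), best + span


def grid_fit_bem(sig, b, n_refine=2, n_pts=41):
    """Exhaustive (d, d_star, f) grid search (s0 fixed at the b=0 signal),
    refined around the incumbent; unweighted SSR."""
    s0 = sig[0]
    d_lo, d_hi = 0.0, 3.0e-3
    ds_lo, ds_hi = 0.0, 0.05
    f_lo, f_hi = 0.0, 1.0
    best = None
    for _ in range(n_refine + 1):
        ds_grid = np.linspace(ds_lo, ds_hi, n_pts)
        d_grid = np.linspace(d_lo, d_hi, n_pts)
        f_grid = np.linspace(f_lo, f_hi, n_pts)
        e_fast = np.exp(-np.outer(ds_grid, b))          # (ds, b)
        e_slow = np.exp(-np.outer(d_grid, b))           # (d, b)
        best_ssr = np.inf
        for fi, f in enumerate(f_grid):
            model = s0 * (f * e_fast[:, None, :] + (1 - f) * e_slow[None, :, :])
            ssr = ((model - sig) ** 2).sum(axis=2)      # (ds, d)
            k = np.unravel_index(np.argmin(ssr), ssr.shape)
            if ssr[k] < best_ssr:
                best_ssr = ssr[k]
                best = (float(d_grid[k[1]]), float(ds_grid[k[0]]), float(f))
        d_lo, d_hi = _refine(d_lo, d_hi, best[0])
        ds_lo, ds_hi = _refine(ds_lo, ds_hi, best[1])
        f_lo, f_hi = _refine(f_lo, f_hi, best[2])
        f_hi = min(f_hi, 1.0)
    return {"d": best[0], "d_star": best[1], "f": best[2]}


def grid_fit_sem(sig, b, n_refine=2, n_pts=61):
    """Exhaustive (ddc, alpha) grid search with s0 fixed at the b=0 signal."""
    s0 = sig[0]
    ddc_lo, ddc_hi = 0.0, 5.0e-3
    a_lo, a_hi = 0.01, 1.0
    best = None
    for _ in range(n_refine + 1):
        ddc_grid = np.linspace(ddc_lo, ddc_hi, n_pts)
        a_grid = np.linspace(a_lo, a_hi, n_pts)
        u = np.outer(ddc_grid, b)                       # (ddc, b)
        best_ssr = np.inf
        for a in a_grid:
            model = s0 * np.exp(-np.power(u, a))
            ssr = ((model - sig) ** 2).sum(axis=1)
            k = int(np.argmin(ssr))
            if ssr[k] < best_ssr:
                best_ssr = ssr[k]
                best = (float(ddc_grid[k]), float(a))
        ddc_lo, ddc_hi = _refine(ddc_lo, ddc_hi, best[0])
        a_lo, a_hi = _refine(a_lo, a_hi, best[1])
        a_hi = min(a_hi, 1.0)
    return {"ddc": best[0], "alpha": best[1]}


def naive_voi_statistics(values):
    """Sorting-based recomputation of the first-order statistics."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size

    def pct(q):
        pos = q / 100.0 * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        return x[lo] + (pos - lo) * (x[hi] - x[lo])

    mean = x.sum() / n
    var = ((x - mean) ** 2).sum() / n
    out = {"mean": mean, "median": pct(50), "p10": pct(10), "p90": pct(90)}
    if var > 0:
        m3 = ((x - mean) ** 3).sum() / n
        m4 = ((x - mean) ** 4).sum() / n
        out["skewness"] = m3 / var ** 1.5
        out["kurtosis"] = m4 / var ** 2    # Pearson (normal = 3)
    else:
        out["skewness"] = 0.0
        out["kurtosis"] = 3.0
    return out


def brute_force_auc(values, y):
    """AUC by enumerating all positive-negative pairs (ties count 1/2)."""
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=bool)
    pos, neg = values[y], values[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def exhaustive_youden(values, y):
    """Best J = se + sp - 1 over all observed thresholds (predict positive
    when value >= threshold); ties broken toward higher specificity."""
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=bool)
    rows = []
    for thr in np.unique(values):
        pred = values >= thr
        se = np.sum(pred & y) / y.sum()
        sp = np.sum(~pred & ~y) / (~y).sum()
        rows.append((se + sp - 1.0, sp, float(thr)))
    jmax = max(r[0] for r in rows)
    cand = [r for r in rows if r[0] >= jmax - 1e-12]
    best = max(cand, key=lambda r: (r[1], r[2]))
    return {"youden": best[0], "cutoff": best[2]}


def delong_variance_oracle(a, b, y):
    """Loop-based structural-components variance of AUC(a) - AUC(b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    y = np.asarray(y, dtype=bool)

    def psi(u, v):
        return 1.0 if u > v else (0.5 if u == v else 0.0)

    def components(scores):
        pos, neg = scores[y], scores[~y]
        v10 = np.array([np.mean([psi(p, q) for q in neg]) for p in pos])
        v01 = np.array([np.mean([psi(p, q) for p in pos]) for q in neg])
        return v10, v01

    v10a, v01a = components(a)
    v10b, v01b = components(b)
    m, n = v10a.size, v01a.size

    def sample_cov(x, z):
        xm, zm = x.mean(), z.mean()
        return np.sum((x - xm) * (z - zm)) / (x.size - 1)

    var = (sample_cov(v10a, v10a) + sample_cov(v10b, v10b)
           - 2 * sample_cov(v10a, v10b)) / m
    var += (sample_cov(v01a, v01a) + sample_cov(v01b, v01b)
            - 2 * sample_cov(v01a, v01b)) / n
    return {"auc_a": v10a.mean(), "auc_b": v10b.mean(), "var": var}


def icc21_anova(r1, r2):
    """ICC(2,1) from the two-way ANOVA mean squares, written out longhand."""
    x = np.column_stack([np.asarray(r1, float), np.asarray(r2, float)])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_rows = k * np.sum((row_means - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_err = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return ((ms_rows - ms_err)
            / (ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n))
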