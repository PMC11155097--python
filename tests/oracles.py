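"""Independent brute-force oracles used by the tests.

Everything here is written with explicit Python loops over pixels / matrix
entries, deliberately avoiding the vectorized code paths under test.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

def mip_by_loops(volume):
    ns, nr, nc = volume.shape
    out = np.zeros((nr, nc))
    for r in range(nr):
        for c in range(nc):
            best = volume[0, r, c]
            for s in range(1, ns):
                if volume[s, r, c] > best:
                    best = volume[s, r, c]
            out[r, c] = best
    return out


# ---------------------------------------------------------------------------
# AUC by pair counting
# ---------------------------------------------------------------------------

def auc_pair_counting(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def first_order_by_loops(values, bin_width=25.0, pixel_area=1.0):
    x = [float(v) for v in values]
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    srt = sorted(x)
    p10, p25, p75, p90 = (np.percentile(x, q) for q in (10, 25, 75, 90))
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    lo = min(x)
    hist = {}
    for v in x:
        b = math.floor((v - lo) / bin_width)
        hist[b] = hist.get(b, 0) + 1
    probs = [c / n for c in hist.values()]
    energy = sum(v * v for v in x)
    if var > 0:
        skew = sum((v - mean) ** 3 for v in x) / n / sd**3
        kurt = sum((v - mean) ** 4 for v in x) / n / var**2
    else:
        skew = kurt = 0.0
    return {
        "Energy": energy,
        "TotalEnergy": pixel_area * energy,
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Minimum": lo,
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": max(x),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": max(x) - lo,
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "RootMeanSquared": math.sqrt(energy / n),
        "StandardDeviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": sum(p * p for p in probs),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


def glcm_counts_by_loops(levels, offset):
    h, w = levels.shape
    ng = int(levels.max())
    counts = [[0.0] * ng for _ in range(ng)]
    dr, dc = offset
    for r in range(h):
        for c in range(w):
            a = levels[r, c]
            if a <= 0:
                continue
            for sr, sc in ((dr, dc), (-dr, -dc)):
                rr, cc = r + sr, c + sc
                if 0 <= rr < h and 0 <= cc < w and levels[rr, cc] > 0:
                    counts[a - 1][levels[rr, cc] - 1] += 1.0
    return counts


def glcm_features_by_loops(levels):
    per_angle = []
    ng = int(levels.max())
    for off in _OFFSETS:
        counts = glcm_counts_by_loops(levels, off)
        total = sum(sum(row) for row in counts)
        if total == 0:
            continue
        p = [[counts[i][j] / total for j in range(ng)] for i in range(ng)]
        per_angle.append(_glcm_single_by_loops(p, ng))
    names = per_angle[0].keys()
    return {k: sum(f[k] for f in per_angle) / len(per_angle) for k in names}


def _glcm_single_by_loops(p, ng):
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * p[i][j] for i in range(ng) for j in range(ng))
    sig2 = sum(px[i] * (i + 1 - mu) ** 2 for i in range(ng))
    psum = {}
    pdiff = {}
    for i in range(ng):
        for j in range(ng):
            psum[i + j + 2] = psum.get(i + j + 2, 0.0) + p[i][j]
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p[i][j]
    da = sum(k * v for k, v in pdiff.items())
    hxy = -sum(p[i][j] * math.log2(p[i][j]) for i in range(ng) for j in range(ng) if p[i][j] > 0)
    hx = -sum(q * math.log2(q) for q in px if q > 0)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * px[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * px[j] > 0 and p[i][j] > 0
    )
    # include terms where p=0 but px*px>0 contribute 0 to hxy1 anyway
    hxy2 = -sum(
        px[i] * px[j] * math.log2(px[i] * px[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * px[j] > 0
    )
    corr = 1.0
    if sig2 > 0:
        corr = (sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)) - mu * mu) / sig2
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = math.sqrt(max(1.0 - math.exp(-2.0 * max(hxy2 - hxy, 0.0)), 0.0))

    present = [i for i in range(ng) if px[i] > 0]
    mcc = 1.0
    if len(present) > 1:
        q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                q[a, b] = sum(
                    p[i][k] * p[j][k] / (px[i] * px[k]) for k in present
                )
        eigs = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(eigs[-2], 0.0))

    return {
        "Autocorrelation": sum((i + 1) * (j + 1) * p[i][j] for i in range(ng) for j in range(ng)),
        "ClusterProminence": sum((i + j + 2 - 2 * mu) ** 4 * p[i][j] for i in range(ng) for j in range(ng)),
        "ClusterShade": sum((i + j + 2 - 2 * mu) ** 3 * p[i][j] for i in range(ng) for j in range(ng)),
        "ClusterTendency": sum((i + j + 2 - 2 * mu) ** 2 * p[i][j] for i in range(ng) for j in range(ng)),
        "Contrast": sum((i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(v * math.log2(v) for v in pdiff.values() if v > 0),
        "DifferenceVariance": sum((k - da) ** 2 * v for k, v in pdiff.items()),
        "Id": sum(p[i][j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "Idm": sum(p[i][j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng)),
        "Idmn": sum(p[i][j] / (1 + ((i - j) / ng) ** 2) for i in range(ng) for j in range(ng)),
        "Idn": sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": sum(
            p[i][j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
        ),
        "JointAverage": mu,
        "JointEnergy": sum(p[i][j] ** 2 for i in range(ng) for j in range(ng)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": max(p[i][j] for i in range(ng) for j in range(ng)),
        "SumAverage": sum(k * v for k, v in psum.items()),
        "SumEntropy": -sum(v * math.log2(v) for v in psum.values() if v > 0),
        "SumSquares": sum((i + 1 - mu) ** 2 * p[i][j] for i in range(ng) for j in range(ng)),
    }


# ---------------------------------------------------------------------------
# GLRLM / GLSZM shared feature formulas (loops)
# ---------------------------------------------------------------------------

def run_zone_features_by_loops(counts, n_pixels, names):
    ng = len(counts)
    nl = len(counts[0]) if ng else 0
    n_runs = sum(sum(row) for row in counts)
    if n_runs == 0:
        return {n: 0.0 for n in names}
    pg = [sum(counts[i][j] for j in range(nl)) for i in range(ng)]
    pr = [sum(counts[i][j] for i in range(ng)) for j in range(nl)]
    mu_i = sum((i + 1) * pg[i] for i in range(ng)) / n_runs
    mu_j = sum((j + 1) * pr[j] for j in range(nl)) / n_runs
    feats = [
        sum(counts[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(nl)) / n_runs,
        sum(counts[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(nl)) / n_runs,
        sum(g * g for g in pg) / n_runs,
        sum(g * g for g in pg) / n_runs**2,
        sum(r * r for r in pr) / n_runs,
        sum(r * r for r in pr) / n_runs**2,
        n_runs / n_pixels,
        sum(pg[i] * (i + 1 - mu_i) ** 2 for i in range(ng)) / n_runs,
        sum(pr[j] * (j + 1 - mu_j) ** 2 for j in range(nl)) / n_runs,
        -sum(
            counts[i][j] / n_runs * math.log2(counts[i][j] / n_runs)
            for i in range(ng)
            for j in range(nl)
            if counts[i][j] > 0
        ),
        sum(counts[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(nl)) / n_runs,
        sum(counts[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(nl)) / n_runs,
        sum(counts[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(nl)) / n_runs,
        sum(counts[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nl)) / n_runs,
        sum(counts[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nl)) / n_runs,
        sum(counts[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(nl)) / n_runs,
    ]
    return dict(zip(names, feats))


def glrlm_counts_by_loops(levels, direction):
    h, w = levels.shape
    ng = int(levels.max())
    max_len = max(h, w)
    counts = [[0.0] * max_len for _ in range(ng)]
    dr, dc = direction
    starts = [
        (r, c)
        for r in range(h)
        for c in range(w)
        if not (0 <= r - dr < h and 0 <= c - dc < w)
    ]
    for r0, c0 in starts:
        r, c = r0, c0
        run_level, run_len = 0, 0
        while 0 <= r < h and 0 <= c < w:
            lvl = levels[r, c]
            if lvl == run_level:
                run_len += 1
            else:
                if run_level > 0:
                    counts[run_level - 1][run_len - 1] += 1.0
                run_level, run_len = lvl, 1
            r, c = r + dr, c + dc
        if run_level > 0:
            counts[run_level - 1][run_len - 1] += 1.0
    return counts


def glrlm_features_by_loops(levels, names):
    n_pixels = int((levels > 0).sum())
    per_dir = [
        run_zone_features_by_loops(glrlm_counts_by_loops(levels, d), n_pixels, names)
        for d in ((0, 1), (1, 1), (1, 0), (1, -1))
    ]
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in names}


def glszm_counts_by_loops(levels):
    h, w = levels.shape
    ng = int(levels.max())
    n_pixels = int((levels > 0).sum())
    counts = [[0.0] * max(n_pixels, 1) for _ in range(ng)]
    seen = set()
    for r in range(h):
        for c in range(w):
            if levels[r, c] <= 0 or (r, c) in seen:
                continue
            level = levels[r, c]
            stack = [(r, c)]
            seen.add((r, c))
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if (
                            0 <= nr < h
                            and 0 <= nc < w
                            and (nr, nc) not in seen
                            and levels[nr, nc] == level
                        ):
                            seen.add((nr, nc))
                            stack.append((nr, nc))
            counts[level - 1][size - 1] += 1.0
    return counts


def glszm_features_by_loops(levels, names):
    n_pixels = int((levels > 0).sum())
    return run_zone_features_by_loops(glszm_counts_by_loops(levels), n_pixels, names)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_counts_by_loops(levels, alpha=0.0, delta=1):
    h, w = levels.shape
    ng = int(levels.max())
    deps = {}
    max_dep = 0
    for r in range(h):
        for c in range(w):
            if levels[r, c] <= 0:
                continue
            d = 0
            for dr in range(-delta, delta + 1):
                for dc in range(-delta, delta + 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < h
                        and 0 <= cc < w
                        and levels[rr, cc] > 0
                        and abs(int(levels[rr, cc]) - int(levels[r, c])) <= alpha
                    ):
                        d += 1
            deps[(r, c)] = d
            max_dep = max(max_dep, d)
    counts = [[0.0] * (max_dep + 1) for _ in range(ng)]
    for (r, c), d in deps.items():
        counts[levels[r, c] - 1][d] += 1.0
    return counts


def gldm_features_by_loops(levels, names, alpha=0.0, delta=1, base=0):
    counts = gldm_counts_by_loops(levels, alpha, delta)
    ng = len(counts)
    nd = len(counts[0])
    total = sum(sum(row) for row in counts)
    pg = [sum(counts[i][j] for j in range(nd)) for i in range(ng)]
    pd_ = [sum(counts[i][j] for i in range(ng)) for j in range(nd)]
    dval = [j + base for j in range(nd)]
    dinv = [max(v, 1) for v in dval]
    mu_i = sum((i + 1) * pg[i] for i in range(ng)) / total
    mu_d = sum(dval[j] * pd_[j] for j in range(nd)) / total
    feats = {
        "SmallDependenceEmphasis": sum(
            counts[i][j] / dinv[j] ** 2 for i in range(ng) for j in range(nd)
        ) / total,
        "LargeDependenceEmphasis": sum(
            counts[i][j] * dval[j] ** 2 for i in range(ng) for j in range(nd)
        ) / total,
        "GrayLevelNonUniformity": sum(g * g for g in pg) / total,
        "DependenceNonUniformity": sum(d * d for d in pd_) / total,
        "DependenceNonUniformityNormalized": sum(d * d for d in pd_) / total**2,
        "GrayLevelVariance": sum(pg[i] * (i + 1 - mu_i) ** 2 for i in range(ng)) / total,
        "DependenceVariance": sum(pd_[j] * (dval[j] - mu_d) ** 2 for j in range(nd)) / total,
        "DependenceEntropy": -sum(
            counts[i][j] / total * math.log2(counts[i][j] / total)
            for i in range(ng)
            for j in range(nd)
            if counts[i][j] > 0
        ),
        "LowGrayLevelEmphasis": sum(pg[i] / (i + 1) ** 2 for i in range(ng)) / total,
        "HighGrayLevelEmphasis": sum(pg[i] * (i + 1) ** 2 for i in range(ng)) / total,
        "SmallDependenceLowGrayLevelEmphasis": sum(
            counts[i][j] / ((i + 1) ** 2 * dinv[j] ** 2) for i in range(ng) for j in range(nd)
        ) / total,
        "SmallDependenceHighGrayLevelEmphasis": sum(
            counts[i][j] * (i + 1) ** 2 / dinv[j] ** 2 for i in range(ng) for j in range(nd)
        ) / total,
        "LargeDependenceLowGrayLevelEmphasis": sum(
            counts[i][j] * dval[j] ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nd)
        ) / total,
        "LargeDependenceHighGrayLevelEmphasis": sum(
            counts[i][j] * (i + 1) ** 2 * dval[j] ** 2 for i in range(ng) for j in range(nd)
        ) / total,
    }
    return {n: feats[n] for n in names}
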