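"""Independent brute-force oracles for the 25-feature descriptor.

Every function here recomputes a feature family with explicit Python
loops (or closed forms) straight from the definitions, sharing nothing
with the package implementation beyond the stated conventions
(quantization rule, log base 2, BT.601-free gray input, GCF weight
polynomial).  They are intentionally slow and only run on tiny rasters.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def histogram(gray, mask):
    counts = [0] * 256
    n = 0
    for r in range(gray.shape[0]):
        for c in range(gray.shape[1]):
            if mask[r, c]:
                counts[int(gray[r, c])] += 1
                n += 1
    return np.array(counts), n


def hist_statistics(gray, mask):
    vals = np.array([int(gray[r, c])
                     for r in range(gray.shape[0])
                     for c in range(gray.shape[1]) if mask[r, c]],
                    dtype=np.float64)
    counts, _ = histogram(gray, mask)
    sd = vals.std()  # population SD
    return {
        6: float(stats.kurtosis(vals)) if sd > 0 else 0.0,
        9: float(stats.skew(vals)) if sd > 0 else 0.0,
        12: float(vals.mean()),
        13: float(np.median(vals)),
        14: float(sd),
        15: float(vals.var()),
        16: float(sum(1 for c in counts if c > 0)),
        17: float(int(np.argmax(counts))),
    }


def hist_groups(counts):
    runs = []
    start = None
    for b in range(1, 256):
        if counts[b] > 0 and start is None:
            start = b
        elif counts[b] == 0 and start is not None:
            runs.append((start, b))
            start = None
    if start is not None:
        runs.append((start, 256))
    assert runs, "no nonzero bin among 1..255"

    def key(run):
        s, e = run
        return (e - s, sum(counts[s:e]))

    largest = max(runs, key=lambda r: (key(r)[0], key(r)[1], -r[0]))
    smallest = min(runs, key=lambda r: (key(r)[0], key(r)[1], r[0]))
    return {
        5: float(len(runs)),
        7: float(max(counts[largest[0]:largest[1]])),
        8: float(max(counts[smallest[0]:smallest[1]])),
        10: float(largest[1] - largest[0]),
        11: float(smallest[1] - smallest[0]),
    }


def glcm_matrix(gray, mask, levels=64, distance=1):
    """Symmetric co-occurrence counts over 4 angles, both directions."""
    q = [[int(gray[r, c]) * levels // 256 for c in range(gray.shape[1])]
         for r in range(gray.shape[0])]
    h, w = gray.shape
    P = np.zeros((levels, levels))
    offsets = [(0, distance), (distance, distance), (distance, 0),
               (distance, -distance)]
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    P[q[r][c], q[rr][cc]] += 1
                    P[q[rr][cc], q[r][c]] += 1
    return P / P.sum()


def glcm_features(P):
    L = P.shape[0]
    ent = hom = inertia = energy = 0.0
    mu_i = mu_j = 0.0
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            if p > 0:
                ent -= p * math.log2(p)
            hom += p / (1 + abs(i - j))
            inertia += (i - j) ** 2 * p
            energy += p * p
            mu_i += i * p
            mu_j += j * p
    var_i = var_j = cov = 0.0
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            var_i += (i - mu_i) ** 2 * p
            var_j += (j - mu_j) ** 2 * p
            cov += (i - mu_i) * (j - mu_j) * p
    corr = cov / math.sqrt(var_i * var_j) if var_i > 0 and var_j > 0 else 0.0
    return {18: ent, 19: hom, 20: inertia, 21: corr, 22: energy}


def fft_features(gray):
    """DFT from its definition (explicit twiddle matrices), then loops."""
    h, w = gray.shape
    Wh = np.array([[np.exp(-2j * np.pi * u * r / h) for r in range(h)]
                   for u in range(h)])
    Ww = np.array([[np.exp(-2j * np.pi * c * v / w) for v in range(w)]
                   for c in range(w)])
    F = Wh @ np.asarray(gray, dtype=complex) @ Ww
    # center the spectrum: index k maps to k - size//2 after the shift
    power = np.empty((h, w))
    for u in range(h):
        for v in range(w):
            power[(u + h // 2) % h, (v + w // 2) % w] = abs(F[u, v]) ** 2
    cy, cx = h // 2, w // 2
    power[cy, cx] = 0.0
    total = power.sum()
    if total <= 0:
        return {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
    energy = ent = hom = inertia = 0.0
    for u in range(h):
        for v in range(w):
            qv = power[u, v] / total
            d = math.hypot(u - cy, v - cx)
            energy += qv * qv
            if qv > 0:
                ent -= qv * math.log2(qv)
            hom += qv / (1 + d)
            inertia += d * d * qv
    return {1: energy, 2: ent, 3: hom, 4: inertia}


def image_entropy(counts, n):
    e = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            e -= p * math.log2(p)
    return e


def gcf(gray):
    img = np.asarray(gray, dtype=np.float64)
    total = 0.0
    for i in range(1, 10):
        h, w = img.shape
        if h < 2 or w < 2:
            break
        contrast_sum = 0.0
        L = 100.0 * np.sqrt((img / 255.0) ** 2.2)
        for r in range(h):
            for c in range(w):
                diffs = []
                for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        diffs.append(abs(L[r, c] - L[rr, cc]))
                contrast_sum += sum(diffs) / len(diffs)
        wi = (-0.406385 * i / 9 + 0.334573) * i / 9 + 0.0877526
        total += wi * contrast_sum / (h * w)
        h2, w2 = h // 2, w // 2
        if h2 < 1 or w2 < 1:
            break
        nxt = np.empty((h2, w2))
        for r in range(h2):
            for c in range(w2):
                nxt[r, c] = img[2 * r: 2 * r + 2, 2 * c: 2 * c + 2].mean()
        img = nxt
    return total


def eme(gray, mask, k1=8, k2=8):
    h, w = gray.shape
    rows = np.linspace(0, h, k1 + 1).astype(int)
    cols = np.linspace(0, w, k2 + 1).astype(int)
    terms = []
    for bi in range(k1):
        for bj in range(k2):
            vals = [int(gray[r, c])
                    for r in range(rows[bi], rows[bi + 1])
                    for c in range(cols[bj], cols[bj + 1]) if mask[r, c]]
            if not vals:
                continue
            imax = max(max(vals), 1)
            imin = max(min(vals), 1)
            terms.append(20.0 * math.log10(imax / imin))
    return sum(terms) / len(terms)


def all_features(gray, mask):
    """All 25 features from the loops above, keyed 1-25."""
    out = {}
    counts, n = histogram(gray, mask)
    out.update(fft_features(np.asarray(gray, dtype=np.float64)))
    out.update(hist_groups(counts))
    out.update(hist_statistics(gray, mask))
    out.update(glcm_features(glcm_matrix(gray, mask)))
    out[23] = image_entropy(counts, n)
    out[24] = gcf(gray)
    out[25] = eme(gray, mask)
    return out
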