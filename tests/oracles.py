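"""Independent brute-force oracles for texture matrices and features.

Everything here is written as naive enumeration (explicit loops over
voxels, neighbors, grid lines, flood fills) and literal formula
transcription, deliberately sharing no code path with the package's
vectorized builders. The tests assert exact integer agreement for the
matrices and 1e-10 agreement for the features.
"""

from __future__ import annotations

import math
from itertools import groupby, product

import numpy as np

NEIGHBORS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
POSITIVE_13 = [
    d for d in NEIGHBORS_26 if next(c for c in d if c != 0) > 0
]


def _in_grid(v, shape):
    return all(0 <= c < n for c, n in zip(v, shape))


def naive_glcm_counts(label_vol: np.ndarray, ng: int, distance: int = 1):
    """Symmetrized per-direction co-occurrence counts, (13, ng, ng)."""
    shape = label_vol.shape
    out = np.zeros((13, ng, ng), dtype=np.int64)
    for k, d in enumerate(POSITIVE_13):
        dd = tuple(c * distance for c in d)
        for v in product(*[range(n) for n in shape]):
            a = label_vol[v]
            if a == 0:
                continue
            w = tuple(c + s for c, s in zip(v, dd))
            if _in_grid(w, shape) and label_vol[w] > 0:
                out[k, a - 1, label_vol[w] - 1] += 1
        out[k] = out[k] + out[k].T
    return out


def naive_glrlm_counts(label_vol: np.ndarray, ng: int, distance: int = 1):
    """Per-direction run-length counts via full grid-line decomposition."""
    shape = label_vol.shape
    out = []
    for d in POSITIVE_13:
        dd = tuple(c * distance for c in d)
        runs: dict[tuple[int, int], int] = {}
        # line origins: voxels whose predecessor along -d is outside the grid
        for v in product(*[range(n) for n in shape]):
            pred = tuple(c - s for c, s in zip(v, dd))
            if _in_grid(pred, shape):
                continue
            line = []
            w = v
            while _in_grid(w, shape):
                line.append(int(label_vol[w]))
                w = tuple(c + s for c, s in zip(w, dd))
            for lab, grp in groupby(line):
                if lab > 0:
                    key = (lab, len(list(grp)))
                    runs[key] = runs.get(key, 0) + 1
        rmax = max((r for _, r in runs), default=1)
        mat = np.zeros((ng, rmax), dtype=np.int64)
        for (lab, r), c in runs.items():
            mat[lab - 1, r - 1] = c
        out.append(mat)
    return out


def naive_glszm_counts(label_vol: np.ndarray, ng: int):
    """Size-zone counts via set-based flood fill over the 26-neighborhood."""
    shape = label_vol.shape
    seen: set[tuple] = set()
    zones: dict[tuple[int, int], int] = {}
    for v in product(*[range(n) for n in shape]):
        if label_vol[v] == 0 or v in seen:
            continue
        lab = int(label_vol[v])
        frontier = [v]
        seen.add(v)
        size = 0
        while frontier:
            u = frontier.pop()
            size += 1
            for d in NEIGHBORS_26:
                w = tuple(c + s for c, s in zip(u, d))
                if (
                    _in_grid(w, shape)
                    and w not in seen
                    and label_vol[w] == lab
                ):
                    seen.add(w)
                    frontier.append(w)
        key = (lab, size)
        zones[key] = zones.get(key, 0) + 1
    zmax = max((s for _, s in zones), default=1)
    mat = np.zeros((ng, zmax), dtype=np.int64)
    for (lab, size), c in zones.items():
        mat[lab - 1, size - 1] = c
    return mat


def naive_ngtdm(label_vol: np.ndarray, ng: int):
    """(n_i, p_i, s_i) via explicit neighbor loops."""
    shape = label_vol.shape
    n_i = np.zeros(ng, dtype=np.int64)
    s_i = np.zeros(ng, dtype=np.float64)
    for v in product(*[range(n) for n in shape]):
        lab = int(label_vol[v])
        if lab == 0:
            continue
        nb = []
        for d in NEIGHBORS_26:
            w = tuple(c + s for c, s in zip(v, d))
            if _in_grid(w, shape) and label_vol[w] > 0:
                nb.append(int(label_vol[w]))
        if not nb:
            continue
        n_i[lab - 1] += 1
        s_i[lab - 1] += abs(lab - sum(nb) / len(nb))
    total = n_i.sum()
    p_i = n_i / total if total > 0 else np.zeros(ng)
    return n_i, p_i, s_i


# ---------------------------------------------------------------------------
# literal feature transcriptions


def literal_first_order(x):
    x = list(map(float, x))
    n = len(x)
    mu = sum(x) / n
    m2 = sum((v - mu) ** 2 for v in x) / n
    if m2 == 0:
        return {"Variance": 0.0, "Skewness": 0.0, "Kurtosis": 0.0}
    m3 = sum((v - mu) ** 3 for v in x) / n
    m4 = sum((v - mu) ** 4 for v in x) / n
    return {
        "Variance": m2,
        "Skewness": m3 / m2**1.5,
        "Kurtosis": m4 / m2**2,
    }


def literal_glcm_features(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    if p.sum() <= 0:
        return {f"GLCM {k}": math.nan for k in (
            "Energy", "Contrast", "Entropy", "Homogeneity", "Correlation",
            "Sum Average", "Variance", "Autocorrelation", "Dissimilarity")}
    energy = contrast = entropy = homog = sumavg = autoc = dissim = 0.0
    mux = muy = 0.0
    for i in range(1, ng + 1):
        for j in range(1, ng + 1):
            pij = float(p[i - 1, j - 1])
            energy += pij**2
            contrast += (i - j) ** 2 * pij
            if pij > 0:
                entropy -= pij * math.log2(pij)
            homog += pij / (1 + abs(i - j))
            sumavg += (i + j) / 2 * pij
            autoc += i * j * pij
            dissim += abs(i - j) * pij
            mux += i * pij
            muy += j * pij
    sigx2 = sigy2 = variance = 0.0
    for i in range(1, ng + 1):
        for j in range(1, ng + 1):
            pij = float(p[i - 1, j - 1])
            sigx2 += (i - mux) ** 2 * pij
            sigy2 += (j - muy) ** 2 * pij
            variance += (i - mux) ** 2 * pij  # mu = joint gray-level mean
    if sigx2 > 0 and sigy2 > 0:
        corr = (autoc - mux * muy) / math.sqrt(sigx2 * sigy2)
    else:
        corr = math.nan
    return {
        "GLCM Energy": energy,
        "GLCM Contrast": contrast,
        "GLCM Entropy": entropy,
        "GLCM Homogeneity": homog,
        "GLCM Correlation": corr,
        "GLCM Sum Average": sumavg,
        "GLCM Variance": variance,
        "GLCM Autocorrelation": autoc,
        "GLCM Dissimilarity": dissim,
    }


def literal_size_features(counts: np.ndarray, n_slots: float, suffixes) -> dict:
    ng, jmax = counts.shape
    n = float(counts.sum())
    if n <= 0:
        return {s: math.nan for s in suffixes}
    sre = lre = gln = rln = lgre = hgre = srlge = srhge = lrlge = lrhge = 0.0
    gi = [float(counts[i].sum()) for i in range(ng)]
    rj = [float(counts[:, j].sum()) for j in range(jmax)]
    for i in range(1, ng + 1):
        for j in range(1, jmax + 1):
            c = float(counts[i - 1, j - 1])
            sre += c / j**2
            lre += c * j**2
            lgre += c / i**2
            hgre += c * i**2
            srlge += c / (i**2 * j**2)
            srhge += c * i**2 / j**2
            lrlge += c * j**2 / i**2
            lrhge += c * i**2 * j**2
    gln = sum(g**2 for g in gi)
    rln = sum(r**2 for r in rj)
    mu_i = sum(g * (i + 1) for i, g in enumerate(gi)) / n
    mu_j = sum(r * (j + 1) for j, r in enumerate(rj)) / n
    glv = sum(g * ((i + 1) - mu_i) ** 2 for i, g in enumerate(gi)) / n
    rlv = sum(r * ((j + 1) - mu_j) ** 2 for j, r in enumerate(rj)) / n
    vals = [
        sre / n, lre / n, gln / n, rln / n, n / n_slots,
        lgre / n, hgre / n, srlge / n, srhge / n, lrlge / n, lrhge / n,
        glv, rlv,
    ]
    return dict(zip(suffixes, vals))


def literal_ngtdm_features(n_i, p_i, s_i) -> dict[str, float]:
    ng = len(n_i)
    total = float(sum(n_i))
    names = ("NGTDM Coarseness", "NGTDM Contrast", "NGTDM Busyness",
             "NGTDM Complexity", "NGTDM Strength")
    if total <= 0:
        return {k: math.nan for k in names}
    occ = [i for i in range(ng) if p_i[i] > 0]
    ngp = len(occ)
    den = sum(p_i[i] * s_i[i] for i in range(ng))
    coarse = 1e6 if den == 0 else min(1.0 / den, 1e6)
    if ngp >= 2:
        acc = 0.0
        for i in occ:
            for j in occ:
                acc += p_i[i] * p_i[j] * ((i + 1) - (j + 1)) ** 2
        contrast = acc / (ngp * (ngp - 1)) * (sum(s_i) / total)
        bden = 0.0
        for i in occ:
            for j in occ:
                bden += abs((i + 1) * p_i[i] - (j + 1) * p_i[j])
        busy = den / bden if bden > 0 else math.nan
    else:
        contrast = math.nan
        busy = math.nan
    comp = 0.0
    for i in occ:
        for j in occ:
            comp += (
                abs((i + 1) - (j + 1))
                * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                / (p_i[i] + p_i[j])
            )
    comp /= total
    ssum = float(sum(s_i))
    if ssum > 0:
        stren = sum(
            (p_i[i] + p_i[j]) * ((i + 1) - (j + 1)) ** 2 for i in occ for j in occ
        ) / ssum
    else:
        stren = 0.0
    return {
        "NGTDM Coarseness": coarse,
        "NGTDM Contrast": contrast,
        "NGTDM Busyness": busy,
        "NGTDM Complexity": comp,
        "NGTDM Strength": stren,
    }


def random_label_volume(rng: np.random.Generator, shape=(5, 5, 5), ng=4):
    """A random quantized ROI: labels 1..ng inside a random mask, 0 outside."""
    labels = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) < rng.uniform(0.3, 0.9)
    if not mask.any():
        mask.flat[rng.integers(0, mask.size)] = True
    return np.where(mask, labels, 0).astype(np.int64)
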