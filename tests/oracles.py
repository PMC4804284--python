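"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive — explicit loops, direct formulas —
and shares no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Connected-component labels by iterative flood fill."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                stack = [(r0, c0)]
                labels[r0, c0] = current
                while stack:
                    r, c = stack.pop()
                    for dr, dc in steps:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and labels[rr, cc] == 0:
                            labels[rr, cc] = current
                            stack.append((rr, cc))
    return labels


def component_areas(mask: np.ndarray, connectivity: int) -> list[int]:
    labels = flood_fill_labels(mask, connectivity)
    return sorted(
        int(np.sum(labels == lab)) for lab in range(1, labels.max() + 1)
    )


def glcm_at_pixel(
    q: np.ndarray,
    r: int,
    c: int,
    levels: int,
    window: int,
    offsets: list[tuple[int, int]],
) -> np.ndarray:
    """Symmetric normalized GLCM at one pixel by exhaustive pair enumeration.

    A pair (p, p+offset) counts when p lies in the window (clipped to the
    image) and p+offset lies inside the image.
    """
    h, w = q.shape
    half = window // 2
    counts = np.zeros((levels, levels), dtype=float)
    for dr, dc in offsets:
        for rr in range(max(0, r - half), min(h, r + half + 1)):
            for cc in range(max(0, c - half), min(w, c + half + 1)):
                pr, pc = rr + dr, cc + dc
                if 0 <= pr < h and 0 <= pc < w:
                    counts[q[rr, cc], q[pr, pc]] += 1
    counts = counts + counts.T
    total = counts.sum()
    return counts / total if total > 0 else counts


def haralick_stats_direct(glcm: np.ndarray) -> dict[str, float]:
    """The five Haralick statistics by direct summation."""
    levels = glcm.shape[0]
    contrast = energy = homogeneity = entropy = 0.0
    mu = 0.0
    pi = glcm.sum(axis=1)
    for i in range(levels):
        mu += i * pi[i]
    var = sum((i - mu) ** 2 * pi[i] for i in range(levels))
    cross = 0.0
    for i in range(levels):
        for j in range(levels):
            p = glcm[i, j]
            contrast += p * (i - j) ** 2
            energy += p * p
            homogeneity += p / (1.0 + (i - j) ** 2)
            if p > 0:
                entropy -= p * np.log2(p)
            cross += p * i * j
    correlation = (cross - mu * mu) / var if var > 1e-12 else 1.0
    return {
        "haralick_contrast": contrast,
        "haralick_correlation": correlation,
        "haralick_energy": energy,
        "haralick_homogeneity": homogeneity,
        "haralick_entropy": entropy,
    }


def entropy_at_pixel(q: np.ndarray, r: int, c: int, bins: int, window: int) -> float:
    """Shannon entropy (bits) of the clipped-window histogram at one pixel."""
    h, w = q.shape
    half = window // 2
    counts = np.zeros(bins)
    for rr in range(max(0, r - half), min(h, r + half + 1)):
        for cc in range(max(0, c - half), min(w, c + half + 1)):
            counts[q[rr, cc]] += 1
    p = counts / counts.sum()
    return float(-sum(x * np.log2(x) for x in p if x > 0))


def fourier_hog_at_center(
    channel: np.ndarray, m: int, sigma: float, truncate: float = 4.0
) -> float:
    """|order-m angular gradient moment pooled with a Gaussian| at the center.

    Gradient by explicit central differences (one-sided at borders), pooling
    by direct summation against a truncated normalized Gaussian kernel.
    """
    h, w = channel.shape
    gr = np.zeros_like(channel, dtype=float)
    gc = np.zeros_like(channel, dtype=float)
    gr[1:-1, :] = (channel[2:, :] - channel[:-2, :]) / 2.0
    gr[0, :] = channel[1, :] - channel[0, :]
    gr[-1, :] = channel[-1, :] - channel[-2, :]
    gc[:, 1:-1] = (channel[:, 2:] - channel[:, :-2]) / 2.0
    gc[:, 0] = channel[:, 1] - channel[:, 0]
    gc[:, -1] = channel[:, -1] - channel[:, -2]
    mag = np.hypot(gr, gc)
    theta = np.arctan2(gr, gc)
    radius = int(truncate * sigma + 0.5)
    r0, c0 = h // 2, w // 2
    acc = 0.0 + 0.0j
    norm = 0.0
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            rr, cc = r0 + dr, c0 + dc
            if not (0 <= rr < h and 0 <= cc < w):
                continue  # center far from borders in tests: window inside
            k = np.exp(-(dr * dr + dc * dc) / (2.0 * sigma * sigma))
            norm += k
            acc += k * mag[rr, cc] * np.exp(1j * m * theta[rr, cc])
    return float(abs(acc) / norm)


def pr_counts_at_threshold(
    scores: np.ndarray, is_target: np.ndarray, threshold: float
) -> tuple[int, int, int]:
    """(TP, FP, FN) by direct recount with predict-iff-score>=threshold."""
    tp = fp = fn = 0
    for s, t in zip(scores, is_target):
        if s >= threshold:
            if t:
                tp += 1
            else:
                fp += 1
        elif t:
            fn += 1
    return tp, fp, fn


def fleiss_kappa_direct(counts: np.ndarray) -> float:
    """Fleiss' kappa term by term from the item-by-category count table."""
    counts = np.asarray(counts, dtype=float)
    n, _ = counts.shape
    k = counts[0].sum()
    p_j = counts.sum(axis=0) / (n * k)
    p_bar_e = sum(p * p for p in p_j)
    p_bar = 0.0
    for i in range(n):
        agree_i = (sum(x * x for x in counts[i]) - k) / (k * (k - 1))
        p_bar += agree_i / n
    return (p_bar - p_bar_e) / (1.0 - p_bar_e)
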