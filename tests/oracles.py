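"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately naive — double loops, exhaustive
enumeration — and shares no code path with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def naive_kde(values, centers, sigma):
    """Double loop over pixels × bins, Gaussian kernel, renormalized."""
    raw = np.zeros(len(centers))
    for j, z in enumerate(centers):
        for v in values:
            raw[j] += np.exp(-((z - v) ** 2) / (2 * sigma**2)) / np.sqrt(
                2 * np.pi * sigma**2
            )
    raw /= len(values)
    return raw / raw.sum()


def enumerate_pairs(phi_s, connectivity):
    """All unordered neighbor pairs inside phi_s with inverse-distance weights."""
    h, w = phi_s.shape
    coords = [(r, c) for r in range(h) for c in range(w) if phi_s[r, c]]
    index = {rc: k for k, rc in enumerate(coords)}
    if connectivity == 4:
        offs = [(0, 1), (1, 0)]
    else:
        offs = [(0, 1), (1, 0), (1, 1), (1, -1)]
    pairs = []
    for (r, c) in coords:
        for dr, dc in offs:
            nb = (r + dr, c + dc)
            if nb in index:
                pairs.append((index[(r, c)], index[nb], 1.0 / np.hypot(dr, dc)))
    return pairs


def naive_smoothness(labels_flat, phi_s, connectivity):
    return sum(
        w for i, j, w in enumerate_pairs(phi_s, connectivity)
        if labels_flat[i] != labels_flat[j]
    )


def naive_energy(labels_flat, phi_values, model_probs, bin_of_value, gamma,
                 phi_s, connectivity):
    """−Bhattacharyya (dirac kernel) + γ·smoothness, all recomputed from scratch."""
    e_vals = [v for v, l in zip(phi_values, labels_flat) if l == 1]
    hist = np.zeros(len(model_probs))
    for v in e_vals:
        hist[bin_of_value(v)] += 1
    hist = hist / hist.sum()
    b = float(np.sqrt(hist * model_probs).sum())
    return -b + gamma * naive_smoothness(labels_flat, phi_s, connectivity)


def exhaustive_minimum(image, partition, params):
    """Global minimum of the segmentation energy over all non-empty-E labelings.

    Vectorized enumeration of the full 2^m labeling space; only feasible
    for m ≤ ~16 pixels.
    """
    from renoseg.segmentation import _EnergyState

    state = _EnergyState(image, partition, params)
    m = partition.area_phi_s
    assert m <= 16
    n_lab = 2**m
    bits = ((np.arange(1, n_lab)[:, None] >> np.arange(m)) & 1).astype(float)
    n = bits @ state.K.T  # (n_lab-1, n_bins)
    w = bits @ state.kappa
    b = (np.sqrt(n * state.D[None, :])).sum(axis=1) / np.sqrt(w)
    smooth = np.zeros(n_lab - 1)
    for i, j, wt in zip(state.pi, state.pj, state.pw):
        smooth += wt * (bits[:, i] != bits[:, j])
    energies = -b + params.gamma * smooth
    k = int(np.argmin(energies))
    return float(energies[k]), bits[k]


def icc_two_way_absolute(a, b):
    """ICC(A,1) and ICC(A,k) from explicit ANOVA mean squares."""
    x = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = x.shape
    gm = x.mean()
    msr = k * ((x.mean(axis=1) - gm) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - gm) ** 2).sum() / (k - 1)
    sse = ((x - gm) ** 2).sum() - (n - 1) * msr - (k - 1) * msc
    mse = sse / ((n - 1) * (k - 1))
    single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    average = (msr - mse) / (msr + (msc - mse) / n)
    return single, average
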