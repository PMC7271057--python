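"""Distribution-matching kidney segmentation by iterative bound optimization.

The region to segment (Φs) is searched for the labeling L : Φs → {0, 1}
minimizing

    C(L) = −B(P_E, D) + γ · E(L),

where E = {x : L_x = 1} is the "safety" region whose kernel density P_E
should match the background model D (estimated on the complement domain
Φs̄), B is the Bhattacharyya coefficient, and E(L) is an inverse-distance
weighted boundary-length prior over neighboring pixel pairs.  The kidney is
the complement of the optimum: E_kidney = Φs \\ E_opt.

Optimization starts from E⁰ = Φs and iterates shrink moves: at each step a
modular auxiliary objective that upper-bounds C on every labeling reachable
by 1→0 flips, and touches C at the current labeling, is minimized exactly by
a binary min-cut.  Each accepted move strictly decreases the true energy, so
the energy trace is non-increasing and E is shrink-monotone.  A final greedy
single-flip descent guarantees that no single 1→0 flip can improve the
energy at convergence.

Per-pixel removal costs of the auxiliary objective (κ_x = Σ_z K_z(I_x),
n(z) = Σ_{x∈E} K_z(I_x), W = Σ_{x∈E} κ_x):

    c_x = (3 / (2√W)) · Σ_z √(D(z)/n(z)) · K_z(I_x)  −  B(P_E, D) · κ_x / (2W)

obtained from the chord bound √(n−s) ≥ √n − s/√n and
(1−t)^{−1/2} ≥ 1 + t/2 (capped at 3/2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_flow

from .distributions import (
    Binning,
    IntensityDistribution,
    KernelSpec,
    bhattacharyya,
    kde_estimate,
    kernel_matrix,
    make_bins,
)
from .image_model import (
    PATIENT_LEFT_ON_VIEWER_RIGHT,
    DomainPartition,
    IntensityImage,
    split_domain,
)

__all__ = [
    "EnergyParams",
    "LabelMap",
    "SegmentationResult",
    "matching_term",
    "smoothness_term",
    "evaluate_energy",
    "optimize_labeling",
    "extract_kidneys",
    "segment_kidneys",
    "DegenerateRegionError",
    "EmptySegmentationError",
]

_FLIP_TOL = 1e-12


class DegenerateRegionError(ValueError):
    """Raised when a region needed for density estimation is empty."""


class EmptySegmentationError(ValueError):
    """Raised when kidney extraction finds no connected component."""


@dataclass(frozen=True)
class EnergyParams:
    """Tunables of the segmentation energy and its optimizer.

    gamma
        Smoothness weight.  The matching term's per-pixel scale is
        O(1/|Φs|) while each boundary pair contributes O(1), so useful
        values are small; the default 1e-4 balances the two on
        128×128-scale inputs.
    kernel
        Density kernel (Gaussian with auto bandwidth by default).
    n_bins
        Intensity bins spanning [min, max] of the full image.
    connectivity
        4 or 8; diagonal pairs are weighted 1/√2 (inverse pixel distance).
    epsilon / max_iter
        Stop when a bound step decreases the energy by less than epsilon,
        or after max_iter accepted bound steps.
    """

    gamma: float = 1e-4
    kernel: KernelSpec = field(default_factory=KernelSpec)
    n_bins: int = 256
    connectivity: int = 8
    epsilon: float = 1e-6
    max_iter: int = 50

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


@dataclass
class LabelMap:
    """Binary labeling of the Φs pixels (1 = model-matching region E)."""

    partition: DomainPartition
    labels: np.ndarray  # flat, one entry per phi_s pixel, row-major order

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        n = self.partition.area_phi_s
        if lab.shape != (n,):
            raise ValueError(f"labels must be flat over phi_s ({n} pixels)")
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be binary")
        self.labels = lab.astype(np.int8)

    def to_image(self) -> np.ndarray:
        """2-D int array: label on Φs, −1 elsewhere."""
        out = np.full(self.partition.phi_s.shape, -1, dtype=np.int8)
        out[self.partition.phi_s] = self.labels
        return out

    def kidney_mask(self) -> np.ndarray:
        """Pixels of Φs labeled 0 (the kidney candidate region)."""
        out = np.zeros(self.partition.phi_s.shape, dtype=bool)
        out[self.partition.phi_s] = self.labels == 0
        return out


@dataclass
class SegmentationResult:
    final_labels: LabelMap
    kidney_mask: np.ndarray
    energy_trace: list[float]
    iterations: int
    matching_term: float
    smoothness_term: float
    empty_kidney: bool = False
    shrink_monotone: bool = True

    @property
    def energy(self) -> float:
        return self.energy_trace[-1]


# ---------------------------------------------------------------------------
# energy pieces


def _bins_from_distribution(model: IntensityDistribution) -> Binning:
    c = model.bin_centers
    if len(c) == 1:
        edges = np.array([c[0] - 0.5, c[0] + 0.5])
    else:
        w = c[1] - c[0]
        edges = np.concatenate([c - w / 2.0, [c[-1] + w / 2.0]])
    return Binning(edges=edges, centers=c)


def neighbor_pairs(
    phi_s: np.ndarray, connectivity: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbor pairs fully inside Φs, in flat Φs indexing.

    Returns (i, j, w): each unordered pair once, with inverse-distance
    weight (1 for axial, 1/√2 for diagonal).  Pairs with an endpoint
    outside Φs are ignored (labels are only defined on Φs).
    """
    idx = np.full(phi_s.shape, -1, dtype=np.int64)
    idx[phi_s] = np.arange(int(phi_s.sum()))
    offsets = [((0, 1), 1.0), ((1, 0), 1.0)]
    if connectivity == 8:
        w = 1.0 / np.sqrt(2.0)
        offsets += [((1, 1), w), ((1, -1), w)]
    ii, jj, ww = [], [], []
    for (dr, dc), w in offsets:
        a = idx
        # shift: pair (r, c) with (r+dr, c+dc)
        r0, r1 = max(0, -dr), min(a.shape[0], a.shape[0] - dr)
        c0, c1 = max(0, -dc), min(a.shape[1], a.shape[1] - dc)
        src = a[r0:r1, c0:c1]
        dst = a[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (src >= 0) & (dst >= 0)
        ii.append(src[ok])
        jj.append(dst[ok])
        ww.append(np.full(ok.sum(), w))
    if not ii:
        return (np.empty(0, int), np.empty(0, int), np.empty(0, float))
    return (
        np.concatenate(ii).astype(np.int64),
        np.concatenate(jj).astype(np.int64),
        np.concatenate(ww),
    )


def matching_term(
    E_values: np.ndarray,
    model: IntensityDistribution,
    kernel: KernelSpec,
) -> float:
    """−B(P_E, D): negative Bhattacharyya overlap of region E with the model."""
    v = np.asarray(E_values, dtype=float).ravel()
    if v.size == 0:
        raise DegenerateRegionError("region E is empty")
    bins = _bins_from_distribution(model)
    p_e = kde_estimate(v, kernel, bins)
    return -bhattacharyya(p_e, model)


def smoothness_term(labels: LabelMap, connectivity: int = 8) -> float:
    """Inverse-distance weighted count of disagreeing neighbor pairs in Φs."""
    i, j, w = neighbor_pairs(labels.partition.phi_s, connectivity)
    if len(i) == 0:
        return 0.0
    lab = labels.labels
    return float(w[lab[i] != lab[j]].sum())


def evaluate_energy(
    labels: LabelMap,
    image: IntensityImage,
    partition: DomainPartition,
    params: EnergyParams,
    model: IntensityDistribution,
) -> float:
    """C(L) = −B(P_E, D) + γ·E(L); lower is better."""
    values = image.values[partition.phi_s]
    e_values = values[labels.labels == 1]
    m = matching_term(e_values, model, params.kernel)
    s = smoothness_term(labels, params.connectivity)
    return m + params.gamma * s


# ---------------------------------------------------------------------------
# optimizer internals


class _EnergyState:
    """Precomputed quantities for fast energy evaluation over Φs."""

    def __init__(
        self,
        image: IntensityImage,
        partition: DomainPartition,
        params: EnergyParams,
    ):
        self.params = params
        self.partition = partition
        self.bins = make_bins(image.values, params.n_bins)
        self.model = kde_estimate(
            image.values[partition.phi_s_bar], params.kernel, self.bins
        )
        self.values = image.values[partition.phi_s]
        self.K = kernel_matrix(self.values, params.kernel, self.bins)
        self.kappa = self.K.sum(axis=0)
        self.D = self.model.probabilities
        self.sqrtD = np.sqrt(self.D)
        pi, pj, pw = neighbor_pairs(partition.phi_s, params.connectivity)
        self.pi, self.pj, self.pw = pi, pj, pw
        m = len(self.values)
        if len(pi):
            data = np.concatenate([pw, pw])
            rows = np.concatenate([pi, pj])
            cols = np.concatenate([pj, pi])
            self.adj = csr_matrix((data, (rows, cols)), shape=(m, m))
        else:
            self.adj = csr_matrix((m, m))

    def bhatt(self, L: np.ndarray) -> float:
        n = self.K @ L
        w = float(self.kappa @ L)
        return float((self.sqrtD * np.sqrt(n)).sum() / np.sqrt(w))

    def smooth(self, L: np.ndarray) -> float:
        if not len(self.pi):
            return 0.0
        return float(self.pw[L[self.pi] != L[self.pj]].sum())

    def energy(self, L: np.ndarray) -> float:
        return -self.bhatt(L) + self.params.gamma * self.smooth(L)

    def removal_costs(self, L: np.ndarray) -> np.ndarray:
        """Modular auxiliary removal cost c_x for each pixel of E = {L=1}."""
        e_idx = np.flatnonzero(L == 1)
        n = self.K @ L
        w = float(self.kappa @ L)
        b = float((self.sqrtD * np.sqrt(n)).sum() / np.sqrt(w))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(n > 0, self.sqrtD / np.sqrt(np.maximum(n, 1e-300)), 0.0)
        t1 = (1.5 / np.sqrt(w)) * (self.K[:, e_idx].T @ ratio)
        return t1 - b * self.kappa[e_idx] / (2.0 * w)


def _min_st_cut(
    m: int,
    keep_cost: np.ndarray,
    remove_cost: np.ndarray,
    pi: np.ndarray,
    pj: np.ndarray,
    pw: np.ndarray,
) -> np.ndarray:
    """Exact minimizer of Σ_x cost(label_x) + Σ_pairs w·[labels differ].

    Nodes on the source side keep label 1; sink side flips to 0.  Float
    capacities are scaled into an int32-safe range (the solver computes in
    int32); ties resolve deterministically via BFS order on the residual
    graph.  Returns a boolean keep-mask of length m.
    """
    shift = np.minimum(keep_cost, remove_cost)
    cap_src = remove_cost - shift  # cut when node goes to sink (label 0)
    cap_snk = keep_cost - shift  # cut when node stays with source (label 1)
    if m == 0:
        return np.zeros(0, dtype=bool)
    src, snk = m, m + 1
    rows = [np.full(m, src), np.arange(m), np.arange(m), np.full(m, snk)]
    cols = [np.arange(m), np.full(m, src), np.full(m, snk), np.arange(m)]
    caps = [cap_src, np.zeros(m), cap_snk, np.zeros(m)]
    if len(pi):
        rows += [pi, pj]
        cols += [pj, pi]
        caps += [pw, pw]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    caps = np.concatenate(caps)

    max_cap = caps.max(initial=0.0)
    total_src = float(cap_src.sum())
    scale_ref = max(max_cap, total_src, 1e-300)
    scale = (2.0**30) / scale_ref
    icaps = np.rint(caps * scale).astype(np.int64)
    graph = csr_matrix((icaps, (rows, cols)), shape=(m + 2, m + 2))
    res = maximum_flow(graph, src, snk)
    residual = graph - res.flow
    residual.data = np.maximum(residual.data, 0)
    # BFS from source on strictly positive residual capacity
    keep = np.zeros(m + 2, dtype=bool)
    keep[src] = True
    frontier = [src]
    indptr, indices, data = residual.indptr, residual.indices, residual.data
    while frontier:
        nxt = []
        for u in frontier:
            for k in range(indptr[u], indptr[u + 1]):
                v = indices[k]
                if data[k] > 0 and not keep[v]:
                    keep[v] = True
                    nxt.append(v)
        frontier = nxt
    return keep[:m]


def _greedy_flip_descent(
    state: _EnergyState, L: np.ndarray, trace: list[float]
) -> np.ndarray:
    """Strict-decrease single 1→0 flips until a local optimum (E kept non-empty)."""
    gamma = state.params.gamma
    while True:
        e_idx = np.flatnonzero(L == 1)
        if len(e_idx) <= 1:
            return L
        n = state.K @ L
        w = float(state.kappa @ L)
        b = float((state.sqrtD * np.sqrt(n)).sum() / np.sqrt(w))
        ke = state.K[:, e_idx]
        rem_w = w - state.kappa[e_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            b_new = (
                state.sqrtD[:, None] * np.sqrt(np.maximum(n[:, None] - ke, 0.0))
            ).sum(axis=0) / np.sqrt(np.maximum(rem_w, 1e-300))
        d_match = b - b_new
        d_smooth = np.asarray(state.adj[e_idx] @ (2.0 * L - 1.0)).ravel()
        d_c = d_match + gamma * d_smooth
        j = int(np.argmin(d_c))
        if d_c[j] >= -_FLIP_TOL:
            return L
        L = L.copy()
        L[e_idx[j]] = 0
        trace.append(state.energy(L))


def optimize_labeling(
    image: IntensityImage,
    partition: DomainPartition,
    params: Optional[EnergyParams] = None,
    method: str = "bound",
) -> SegmentationResult:
    """Minimize C(L) over binary labelings of Φs and extract the kidney.

    ``method="bound"`` (default) is the auxiliary-bound + min-cut scheme
    with a final single-flip polish; ``method="sweep"`` is the slower
    reference path that only performs greedy strict-decrease single flips.
    Both start from L ≡ 1 (E⁰ = Φs) and only ever shrink E, so the energy
    trace is non-increasing and the final kidney mask is Φs \\ E_opt.
    """
    if params is None:
        params = EnergyParams()
    if method not in ("bound", "sweep"):
        raise ValueError("method must be 'bound' or 'sweep'")
    if partition.area_phi_s < 2:
        raise DegenerateRegionError("phi_s must contain at least 2 pixels")
    if partition.area_phi_s_bar < 1:
        raise DegenerateRegionError("phi_s_bar is empty: cannot build the model")

    state = _EnergyState(image, partition, params)
    m = partition.area_phi_s
    L = np.ones(m)
    trace = [state.energy(L)]
    iterations = 0
    shrink_ok = True

    if method == "bound":
        while iterations < params.max_iter:
            e_idx = np.flatnonzero(L == 1)
            costs = state.removal_costs(L)
            keep_cost = params.gamma * np.asarray(
                state.adj[e_idx] @ (1.0 - L)
            ).ravel()
            sub_pi, sub_pj, sub_pw = _restrict_pairs(
                state.pi, state.pj, state.pw, L, e_idx
            )
            keep = _min_st_cut(
                len(e_idx), keep_cost, costs, sub_pi, sub_pj, params.gamma * sub_pw
            )
            if keep.all():
                break
            if not keep.any():
                # a cut emptying E is disallowed: retain the best single pixel
                keep[int(np.argmin(costs))] = True
            new_L = L.copy()
            new_L[e_idx[~keep]] = 0
            shrink_ok = shrink_ok and bool(np.all(new_L <= L))
            new_c = state.energy(new_L)
            if new_c > trace[-1] + _FLIP_TOL:
                break  # bound slack/quantization produced no true descent
            L = new_L
            iterations += 1
            decreased = trace[-1] - new_c
            trace.append(new_c)
            if decreased < params.epsilon:
                break

    L = _greedy_flip_descent(state, L, trace)

    labels = LabelMap(partition=partition, labels=L)
    kidney = labels.kidney_mask()
    empty = not kidney.any()
    if empty:
        warnings.warn(
            "segmentation returned an empty kidney mask (E = Φs)", stacklevel=2
        )
    e_values = state.values[L == 1]
    return SegmentationResult(
        final_labels=labels,
        kidney_mask=kidney,
        energy_trace=trace,
        iterations=max(iterations, 1) if method == "bound" else len(trace) - 1,
        matching_term=matching_term(e_values, state.model, params.kernel),
        smoothness_term=state.smooth(L),
        empty_kidney=empty,
        shrink_monotone=shrink_ok,
    )


def _restrict_pairs(pi, pj, pw, L, e_idx):
    """Pairs with both endpoints currently in E, re-indexed locally."""
    if not len(pi):
        return pi, pj, pw
    local = np.full(len(L), -1, dtype=np.int64)
    local[e_idx] = np.arange(len(e_idx))
    both = (L[pi] == 1) & (L[pj] == 1)
    return local[pi[both]], local[pj[both]], pw[both]


# ---------------------------------------------------------------------------
# kidney extraction


_CC_STRUCTURE = np.ones((3, 3), dtype=bool)


def extract_kidneys(
    result: SegmentationResult, side_choice: str
) -> dict[str, np.ndarray]:
    """Connected-component cleanup of the kidney mask.

    Single-kidney modes return the largest component under the requested
    side's name; ``two_kidneys`` mode returns the two largest, assigned
    right/left by centroid column under the display convention.  Raises
    :class:`EmptySegmentationError` when the mask has no component; a
    two-kidney request finding only one component returns it with a
    warning.
    """
    mask = result.kidney_mask
    labeled, n = ndimage.label(mask, structure=_CC_STRUCTURE)
    if n == 0:
        raise EmptySegmentationError("no connected component in the kidney mask")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1

    if side_choice in ("left_kidney", "right_kidney"):
        side = "left" if side_choice == "left_kidney" else "right"
        return {side: labeled == order[0]}

    if side_choice != "two_kidneys":
        raise ValueError(f"unknown side_choice {side_choice!r}")
    if n < 2:
        warnings.warn(
            "two_kidneys mode found a single component; returning one mask",
            stacklevel=2,
        )
        return {"single": labeled == order[0]}
    m1, m2 = labeled == order[0], labeled == order[1]
    col1 = ndimage.center_of_mass(m1)[1]
    col2 = ndimage.center_of_mass(m2)[1]
    viewer_left, viewer_right = (m1, m2) if col1 < col2 else (m2, m1)
    if PATIENT_LEFT_ON_VIEWER_RIGHT:
        return {"right": viewer_left, "left": viewer_right}
    return {"right": viewer_right, "left": viewer_left}


def segment_kidneys(
    image: IntensityImage,
    side_choice: str = "two_kidneys",
    params: Optional[EnergyParams] = None,
    split_index: Optional[int] = None,
    kidneys_half: str = "lower",
) -> tuple[SegmentationResult, dict[str, np.ndarray]]:
    """Convenience pipeline: split the domain, optimize, extract kidneys."""
    partition = split_domain(image, side_choice, split_index, kidneys_half)
    result = optimize_labeling(image, partition, params)
    masks = extract_kidneys(result, side_choice)
    return result, masks
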