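"""Seed/breeding zone delineation by k-medoids (PAM) over PCA scores.

PAM (partitioning around medoids) is run with BUILD initialization and
full SWAP refinement (best-improvement steepest descent, evaluating all
medoid/non-medoid exchanges per iteration) on the Euclidean distances of
the top PCA score vectors.  Within-cluster variation is reported as

    W(k) = mean distance to the assigned medoid
           / RMS distance of all points to the single best medoid,

a scale-free quantity so scans are comparable across datasets.  Scanning
k = 2..16 with warm-started medoids guarantees W(k) is non-increasing.
The operational k is the smallest k whose next reduction r(k+1) falls
below a fraction theta of the median of the reductions achieved so far.

For tractability on large rasters, PAM runs on a seeded random subsample
of cells and every masked-in cell is then assigned to its nearest medoid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .grids import ZoneMap

log = logging.getLogger(__name__)

DEFAULT_K_RANGE = range(2, 17)
DEFAULT_THETA = 0.5
DEFAULT_SUBSAMPLE = 4_000
DEFAULT_RESTARTS = 5


class ZonationError(ValueError):
    pass


@dataclass
class PAMResult:
    medoids: np.ndarray        # indices into the point array
    assignments: np.ndarray    # medoid slot per point (0..k-1)
    total_cost: float          # sum of distances to assigned medoids
    w: float                   # normalized within-cluster variation


@dataclass
class ClusterScan:
    k_values: list[int]
    W: dict[int, float]                 # within-cluster variation per k
    medoids: dict[int, np.ndarray]      # medoid point coordinates per k
    seed: int

    def reductions(self) -> dict[int, float]:
        """r(k) = W(k-1) - W(k) for consecutive scanned k."""
        out = {}
        for prev, k in zip(self.k_values, self.k_values[1:]):
            out[k] = self.W[prev] - self.W[k]
        return out

    def frame(self):
        import pandas as pd

        r = self.reductions()
        return pd.DataFrame({
            "k": self.k_values,
            "W": [self.W[k] for k in self.k_values],
            "r": [r.get(k, np.nan) for k in self.k_values],
        })


# ---------------------------------------------------------------------------
# PAM core (numba)


@njit(cache=True)
def _build_init(D, k):
    """Greedy BUILD: repeatedly add the medoid lowering total cost most."""
    n = D.shape[0]
    medoids = np.empty(k, dtype=np.int64)
    # first medoid: minimizes total distance
    best, best_cost = 0, np.inf
    for c in range(n):
        cost = D[c].sum()
        if cost < best_cost:
            best, best_cost = c, cost
    medoids[0] = best
    dnear = D[best].copy()
    for m in range(1, k):
        best, best_gain = -1, -np.inf
        for c in range(n):
            taken = False
            for t in range(m):
                if medoids[t] == c:
                    taken = True
                    break
            if taken:
                continue
            gain = 0.0
            for i in range(n):
                d = dnear[i] - D[c, i]
                if d > 0:
                    gain += d
            if gain > best_gain:
                best, best_gain = c, gain
        medoids[m] = best
        for i in range(n):
            if D[best, i] < dnear[i]:
                dnear[i] = D[best, i]
    return medoids


@njit(cache=True)
def _swap_refine(D, medoids, max_iter=200):
    """Steepest-descent SWAP: apply the best improving exchange until none."""
    n = D.shape[0]
    k = len(medoids)
    meds = medoids.copy()
    for _ in range(max_iter):
        # nearest and second-nearest medoid distance per point
        near = np.empty(n, dtype=np.int64)
        d1 = np.full(n, np.inf)
        d2 = np.full(n, np.inf)
        for i in range(n):
            for t in range(k):
                d = D[meds[t], i]
                if d < d1[i]:
                    d2[i] = d1[i]
                    d1[i] = d
                    near[i] = t
                elif d < d2[i]:
                    d2[i] = d
        best_delta = -1e-9
        best_t, best_c = -1, -1
        delta = np.empty(k)
        for c in range(n):
            taken = False
            for t in range(k):
                if meds[t] == c:
                    taken = True
                    break
            if taken:
                continue
            # cost change of swapping medoid slot t for candidate c:
            # points keeping their medoid contribute min(dc - d1, 0) for
            # every t != nearest; a point losing its medoid moves to
            # min(dc, d2) instead.
            acc = 0.0
            for t in range(k):
                delta[t] = 0.0
            for i in range(n):
                dc = D[c, i]
                shared = dc - d1[i] if dc < d1[i] else 0.0
                acc += shared
                nd = dc if dc < d2[i] else d2[i]
                delta[near[i]] += (nd - d1[i]) - shared
            for t in range(k):
                tot = acc + delta[t]
                if tot < best_delta:
                    best_delta = tot
                    best_t, best_c = t, c
        if best_t < 0:
            break
        meds[best_t] = best_c
    return meds


@njit(cache=True)
def _assign_cost(D, medoids):
    n = D.shape[0]
    k = len(medoids)
    assign = np.empty(n, dtype=np.int64)
    cost = 0.0
    for i in range(n):
        bt, bd = 0, np.inf
        for t in range(k):
            d = D[medoids[t], i]
            if d < bd:  # ties -> lowest slot (lowest zone id)
                bt, bd = t, d
        assign[i] = bt
        cost += bd
    return assign, cost


def _pairwise_distances(points: np.ndarray) -> np.ndarray:
    # cdist's direct differences avoid the cancellation error of the
    # square-expansion formula, which matters for near-tie medoid choices
    from scipy.spatial.distance import cdist

    pts = np.asarray(points, dtype=np.float64)
    return cdist(pts, pts)


def _rms_scale(D: np.ndarray) -> float:
    """RMS distance of all points to the single best medoid (k=1 solution)."""
    costs = (D**2).sum(axis=1)
    best = int(np.argmin(D.sum(axis=1)))
    return float(np.sqrt(np.mean(D[best] ** 2)))


_EXACT_SUBSET_CAP = 20_000


def _exhaustive_from_D(D: np.ndarray, k: int) -> PAMResult:
    """Exact k-medoids optimum by subset enumeration (tiny instances)."""
    import itertools

    n = D.shape[0]
    best_cost, best_meds = np.inf, None
    for meds in itertools.combinations(range(n), k):
        cost = D[list(meds)].min(axis=0).sum()
        if cost < best_cost:
            best_cost, best_meds = cost, meds
    meds = np.asarray(best_meds, dtype=np.int64)
    assign, cost = _assign_cost(D, meds)
    scale = _rms_scale(D)
    w = (cost / n) / scale if scale > 0 else 0.0
    return PAMResult(meds, assign, float(cost), float(w))


def _pam_from_D(D: np.ndarray, k: int, seed: int, n_restarts: int,
                init_medoids: np.ndarray | None = None) -> PAMResult:
    n = D.shape[0]
    from math import comb

    if comb(n, k) <= _EXACT_SUBSET_CAP:
        # tiny instance: the optimum is cheaper than the heuristic
        return _exhaustive_from_D(D, k)
    rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
    inits = [_build_init(D, k)]
    for _ in range(max(0, n_restarts - 1)):
        inits.append(np.sort(rng.choice(n, size=k, replace=False)
                             ).astype(np.int64))
    if init_medoids is not None and len(init_medoids) == k:
        inits.append(np.asarray(init_medoids, dtype=np.int64))
    best: PAMResult | None = None
    scale = _rms_scale(D)
    for init in inits:
        meds = _swap_refine(D, init)
        assign, cost = _assign_cost(D, meds)
        if best is None or cost < best.total_cost - 1e-12:
            w = (cost / n) / scale if scale > 0 else 0.0
            best = PAMResult(meds, assign, float(cost), float(w))
    assert best is not None
    return best


def pam_cluster(points: np.ndarray, k: int, seed: int = 0,
                n_restarts: int = DEFAULT_RESTARTS,
                init_medoids: np.ndarray | None = None) -> PAMResult:
    """PAM k-medoids: best of BUILD + random restarts, SWAP-refined.

    *init_medoids* adds one extra warm-start candidate (used by the k-scan
    to enforce monotone W).  Ties in nearest-medoid assignment break toward
    the lowest medoid slot.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ZonationError("points must be 2-D (n, d)")
    n = len(points)
    if k > n:
        raise ZonationError(f"k={k} exceeds {n} points")
    if not np.isfinite(points).all():
        raise ZonationError("points must be finite")
    return _pam_from_D(_pairwise_distances(points), k, seed, n_restarts,
                       init_medoids)


def cluster_scan(points: np.ndarray, k_range=DEFAULT_K_RANGE, seed: int = 0,
                 n_restarts: int = DEFAULT_RESTARTS) -> ClusterScan:
    """W(k) over the scanned range (k=1 included internally for r(2)).

    Warm starts: the k-medoid solution seeds the (k+1) scan via the best
    greedy addition, so W can never increase with k.
    """
    ks = sorted(set(int(k) for k in k_range))
    points = np.asarray(points, dtype=float)
    if ks[0] < 1 or ks[-1] > len(points):
        raise ZonationError(f"k range {ks[0]}..{ks[-1]} outside [1, "
                            f"{len(points)}]")
    if not np.isfinite(points).all():
        raise ZonationError("points must be finite")
    D = _pairwise_distances(points)
    W: dict[int, float] = {}
    medoid_pts: dict[int, np.ndarray] = {}
    prev_meds: np.ndarray | None = None
    full = range(1, ks[-1] + 1)  # k=1 included so r(2) is defined
    for k in full:
        warm = None
        if prev_meds is not None:
            warm = _greedy_addition(D, prev_meds, k)
        # the warm start extends the (k-1)-solution, which SWAP can only
        # improve, so best-of-inits W(k) <= W(k-1) by construction
        res = _pam_from_D(D, k, seed, n_restarts, warm)
        W[k] = res.w
        medoid_pts[k] = points[res.medoids].copy()
        prev_meds = res.medoids
    return ClusterScan(list(full), W, medoid_pts, seed)


def _greedy_addition(D: np.ndarray, medoids: np.ndarray, k: int
                     ) -> np.ndarray | None:
    """Extend a medoid set to size k by greedy best additions."""
    meds = list(int(m) for m in medoids)
    if len(meds) >= k:
        return np.asarray(meds[:k], dtype=np.int64)
    dnear = D[meds].min(axis=0)
    n = D.shape[0]
    while len(meds) < k:
        gains = np.maximum(dnear[None, :] - D, 0.0).sum(axis=1)
        gains[meds] = -np.inf
        c = int(np.argmax(gains))
        meds.append(c)
        dnear = np.minimum(dnear, D[c])
    return np.asarray(meds, dtype=np.int64)


@dataclass
class KSelection:
    k: int
    theta: float
    no_elbow: bool
    trace: list[dict]


def select_k(scan: ClusterScan, theta: float = DEFAULT_THETA) -> KSelection:
    """Smallest k whose next reduction is substantially below the prior ones.

    chosen k = min { k : r(k+1) < theta * median(r(2..k)) }.  If no k in
    the scanned range satisfies the rule, the maximum scanned k is returned
    with a no-elbow flag.  The rule is invariant to uniform rescaling of
    all reductions.
    """
    ks = scan.k_values
    if len(ks) < 3:
        raise ZonationError("need at least 3 scanned k values")
    r = scan.reductions()
    trace = []
    lo = ks[1]  # first k with a defined reduction
    for k in ks[1:-1]:
        prior = [r[j] for j in range(lo, k + 1)]
        med = float(np.median(prior))
        nxt = r[k + 1]
        hit = nxt < theta * med
        trace.append({"k": k, "median_prior_r": med, "next_r": nxt,
                      "rule_met": bool(hit)})
        if hit:
            log.info("select_k: chose k=%d (r(%d)=%.4g < %.2g * median %.4g)",
                     k, k + 1, nxt, theta, med)
            return KSelection(k, theta, False, trace)
    log.info("select_k: no elbow found, returning k=%d", ks[-1])
    return KSelection(ks[-1], theta, True, trace)


# ---------------------------------------------------------------------------
# Zone maps


def delineate(points: np.ndarray, mask: np.ndarray, cell_size: float,
              k: int, seed: int = 0, subsample: int = DEFAULT_SUBSAMPLE,
              n_restarts: int = DEFAULT_RESTARTS,
              x_origin: float = 0.0, y_origin: float = 0.0,
              crs: str = "local-equal-area",
              provenance: str = "gradient-forest PAM") -> ZoneMap:
    """Cluster masked-cell score vectors into k zones and rasterize.

    PAM runs on at most *subsample* seeded random cells; every masked-in
    cell is then assigned to its nearest medoid.  Zone ids are relabelled
    1..k by descending zone area.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n != int(mask.sum()):
        raise ZonationError("one score vector per masked-in cell required")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    if n > subsample:
        idx = np.sort(rng.choice(n, size=subsample, replace=False))
        log.info("PAM subsample: %d of %d cells", subsample, n)
    else:
        idx = np.arange(n)
    res = pam_cluster(points[idx], k, seed=seed, n_restarts=n_restarts)
    medoid_pts = points[idx][res.medoids]
    assign = _nearest_assign(points, medoid_pts)
    return make_zone_map(assign, mask, cell_size, x_origin, y_origin, crs,
                         provenance)


def _nearest_assign(points: np.ndarray, medoid_pts: np.ndarray) -> np.ndarray:
    """Nearest-medoid slot per point; ties break toward the lowest slot."""
    d2 = ((points[:, None, :] - medoid_pts[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def make_zone_map(assignments: np.ndarray, mask: np.ndarray, cell_size: float,
                  x_origin: float = 0.0, y_origin: float = 0.0,
                  crs: str = "local-equal-area",
                  provenance: str = "") -> ZoneMap:
    """Rasterize cluster assignments; labels 1..k ordered by descending area."""
    assignments = np.asarray(assignments)
    if len(assignments) != int(mask.sum()):
        raise ZonationError(
            f"{len(assignments)} assignments for {int(mask.sum())} masked cells")
    ids, counts = np.unique(assignments, return_counts=True)
    # stable relabel: biggest zone -> 1; ties by original id
    order = np.lexsort((ids, -counts))
    relabel = {int(ids[o]): rank + 1 for rank, o in enumerate(order)}
    labels = np.zeros(mask.shape, dtype=np.int64)
    labels[mask] = np.array([relabel[int(a)] for a in assignments])
    return ZoneMap(labels, cell_size, x_origin, y_origin, crs, provenance)
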