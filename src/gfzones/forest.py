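"""Histogram-based regression forest engine for per-SNP fits.

Thousands of per-SNP forests share one predictor matrix, so the predictors
are quantile-binned once (<= 255 bins per predictor) and every forest then
works on the shared integer codes.  Trees are CART regression trees with
variance-reduction splits, bootstrap resampling, a random predictor subset
per split, and a minimum leaf size; split candidates are the bin
boundaries.  Out-of-bag predictions and every split's impurity reduction
(in the units of sklearn's impurity-decrease importance, i.e. weighted by
the node's bootstrap-sample fraction) are recorded.

All randomness is an explicit xorshift64* stream seeded per forest, so fits
are bit-reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

MAX_BINS = 255
_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)


@dataclass
class BinnedPredictors:
    """Shared quantile binning of a predictor matrix.

    ``codes[i, j]`` is the bin index of sample i on predictor j; a split
    "code <= b" corresponds to "value <= thresholds[j, b]" in predictor
    units.
    """

    codes: np.ndarray       # (n, p) int16
    thresholds: np.ndarray  # (p, MAX_BINS) float
    n_bins: np.ndarray      # (p,) int64
    names: list[str]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.codes.shape[1]

    def subset(self, rows: np.ndarray) -> "BinnedPredictors":
        return BinnedPredictors(self.codes[rows], self.thresholds,
                                self.n_bins, self.names)


def bin_predictors(X: np.ndarray, names: list[str] | None = None,
                   max_bins: int = MAX_BINS) -> BinnedPredictors:
    """Quantile-bin each predictor column of X into at most *max_bins* bins."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    codes = np.empty((n, p), dtype=np.int16)
    thresholds = np.full((p, max_bins), np.nan)
    n_bins = np.empty(p, dtype=np.int64)
    for j in range(p):
        col = X[:, j]
        uniq = np.unique(col)
        if len(uniq) <= max_bins:
            # exact: one bin per distinct value, thresholds at midpoints
            edges = uniq
            codes[:, j] = np.searchsorted(edges, col, side="left")
            nb = len(uniq)
            if nb > 1:
                thresholds[j, : nb - 1] = (uniq[:-1] + uniq[1:]) / 2.0
        else:
            qs = np.quantile(col, np.linspace(0.0, 1.0, max_bins + 1)[1:-1])
            edges = np.unique(qs)
            # code b <=> edges[b-1] < value <= edges[b]
            codes[:, j] = np.searchsorted(edges, col, side="left")
            nb = len(edges) + 1
            thresholds[j, : nb - 1] = edges
        n_bins[j] = nb
    return BinnedPredictors(codes, thresholds, n_bins, list(names))


@njit(cache=True)
def _build_tree(codes, y, buf, mtry, min_leaf, n_bins, rand_state,
                feat, thr_bin, left, right, value, imp):
    """Grow one CART tree over bootstrap draws in *buf*; returns n_nodes, rng."""
    n_total = len(buf)
    p = codes.shape[1]
    tmp = np.empty(n_total, dtype=np.int64)
    feats = np.arange(p)
    cnt = np.empty(MAX_BINS, dtype=np.float64)
    sm = np.empty(MAX_BINS, dtype=np.float64)
    # node stack rows: start, end, node_id
    stack = np.empty((2 * n_total + 2, 3), dtype=np.int64)
    stack[0, 0] = 0
    stack[0, 1] = n_total
    stack[0, 2] = 0
    top = 1
    n_nodes = 1
    while top > 0:
        top -= 1
        start, end, nid = stack[top, 0], stack[top, 1], stack[top, 2]
        n_node = end - start
        s = 0.0
        s2 = 0.0
        for k in range(start, end):
            yy = y[buf[k]]
            s += yy
            s2 += yy * yy
        mean = s / n_node
        node_var = s2 / n_node - mean * mean
        value[nid] = mean
        feat[nid] = -1
        if n_node < 2 * min_leaf or node_var <= 1e-12:
            continue
        best_gain = 0.0
        best_f = -1
        best_b = -1
        for t in range(mtry):
            rand_state ^= (rand_state << np.uint64(13)) & _MASK64
            rand_state ^= rand_state >> np.uint64(7)
            rand_state ^= (rand_state << np.uint64(17)) & _MASK64
            r = t + int(rand_state % np.uint64(p - t))
            f = feats[r]
            feats[r] = feats[t]
            feats[t] = f
            nb = n_bins[f]
            if nb < 2:
                continue
            for b in range(nb):
                cnt[b] = 0.0
                sm[b] = 0.0
            for k in range(start, end):
                i = buf[k]
                c = codes[i, f]
                cnt[c] += 1.0
                sm[c] += y[i]
            cl = 0.0
            sl = 0.0
            for b in range(nb - 1):
                cl += cnt[b]
                sl += sm[b]
                cr = n_node - cl
                if cl < min_leaf or cr < min_leaf:
                    continue
                sr = s - sl
                gain = sl * sl / cl + sr * sr / cr
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_b = b
        if best_f < 0:
            continue
        # exact impurity reduction of the chosen split
        cl = 0.0
        sl = 0.0
        sl2 = 0.0
        for k in range(start, end):
            i = buf[k]
            if codes[i, best_f] <= best_b:
                cl += 1.0
                yy = y[i]
                sl += yy
                sl2 += yy * yy
        cr = n_node - cl
        sr = s - sl
        sr2 = s2 - sl2
        var_l = sl2 / cl - (sl / cl) ** 2
        var_r = sr2 / cr - (sr / cr) ** 2
        red = (n_node / n_total) * (
            node_var - (cl / n_node) * var_l - (cr / n_node) * var_r
        )
        if red <= 0.0:
            continue
        # stable partition of buf[start:end]
        a = start
        nb_tmp = 0
        for k in range(start, end):
            i = buf[k]
            if codes[i, best_f] <= best_b:
                buf[a] = i
                a += 1
            else:
                tmp[nb_tmp] = i
                nb_tmp += 1
        for k in range(nb_tmp):
            buf[a + k] = tmp[k]
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        feat[nid] = best_f
        thr_bin[nid] = best_b
        left[nid] = lid
        right[nid] = rid
        imp[nid] = red
        stack[top, 0] = start
        stack[top, 1] = a
        stack[top, 2] = lid
        top += 1
        stack[top, 0] = a
        stack[top, 1] = end
        stack[top, 2] = rid
        top += 1
    return n_nodes, rand_state


@njit(cache=True)
def _fit_forest(codes, y, n_trees, mtry, min_leaf, n_bins, seed):
    n = len(y)
    max_nodes = 2 * n + 2
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=np.int64)
    cap = 16384
    sp_feat = np.empty(cap, dtype=np.int64)
    sp_bin = np.empty(cap, dtype=np.int64)
    sp_imp = np.empty(cap)
    n_sp = 0
    feat = np.empty(max_nodes, dtype=np.int64)
    thr_bin = np.empty(max_nodes, dtype=np.int64)
    left = np.empty(max_nodes, dtype=np.int64)
    right = np.empty(max_nodes, dtype=np.int64)
    value = np.empty(max_nodes)
    imp = np.zeros(max_nodes)
    buf = np.empty(n, dtype=np.int64)
    inbag = np.empty(n, dtype=np.int64)
    # xorshift64*: seed must be non-zero
    rs = (np.uint64(seed) * np.uint64(2685821657736338717) + np.uint64(1)) & _MASK64
    for _ in range(n_trees):
        for i in range(n):
            inbag[i] = 0
        for k in range(n):
            rs ^= (rs << np.uint64(13)) & _MASK64
            rs ^= rs >> np.uint64(7)
            rs ^= (rs << np.uint64(17)) & _MASK64
            i = int(rs % np.uint64(n))
            buf[k] = i
            inbag[i] += 1
        for nid in range(max_nodes):
            imp[nid] = 0.0
        n_nodes, rs = _build_tree(codes, y, buf, mtry, min_leaf, n_bins, rs,
                                  feat, thr_bin, left, right, value, imp)
        for nid in range(n_nodes):
            if feat[nid] >= 0:
                if n_sp >= cap:
                    new_cap = cap * 2
                    nf = np.empty(new_cap, dtype=np.int64)
                    nb2 = np.empty(new_cap, dtype=np.int64)
                    ni = np.empty(new_cap)
                    nf[:cap] = sp_feat
                    nb2[:cap] = sp_bin
                    ni[:cap] = sp_imp
                    sp_feat, sp_bin, sp_imp, cap = nf, nb2, ni, new_cap
                sp_feat[n_sp] = feat[nid]
                sp_bin[n_sp] = thr_bin[nid]
                sp_imp[n_sp] = imp[nid]
                n_sp += 1
        for i in range(n):
            if inbag[i] == 0:
                nid = 0
                while feat[nid] >= 0:
                    if codes[i, feat[nid]] <= thr_bin[nid]:
                        nid = left[nid]
                    else:
                        nid = right[nid]
                oob_sum[i] += value[nid]
                oob_cnt[i] += 1
    return oob_sum, oob_cnt, sp_feat[:n_sp], sp_bin[:n_sp], sp_imp[:n_sp]


@dataclass
class ForestFit:
    """Raw output of one regression-forest fit."""

    oob_prediction: np.ndarray   # NaN where a sample was never out-of-bag
    oob_fraction: float          # fraction of samples with an OOB prediction
    split_predictor: np.ndarray  # (n_splits,) predictor index
    split_value: np.ndarray      # (n_splits,) threshold in predictor units
    split_importance: np.ndarray  # (n_splits,) impurity reduction, >= 0

    def oob_r2(self, y: np.ndarray) -> float:
        """1 - MSE_oob / Var(y) over samples that have an OOB prediction."""
        have = ~np.isnan(self.oob_prediction)
        resid = y[have] - self.oob_prediction[have]
        return float(1.0 - np.mean(resid**2) / np.var(y))


def fit_regression_forest(binned: BinnedPredictors, y: np.ndarray,
                          n_trees: int = 200, mtry: int | None = None,
                          min_samples_leaf: int = 5,
                          seed: int = 0) -> ForestFit:
    """Fit one bootstrap regression forest on pre-binned predictors."""
    y = np.ascontiguousarray(y, dtype=float)
    if len(y) != binned.n_samples:
        raise ValueError("response length does not match predictor rows")
    if mtry is None:
        mtry = max(1, binned.n_predictors // 3)
    mtry = min(mtry, binned.n_predictors)
    oob_sum, oob_cnt, sp_f, sp_b, sp_i = _fit_forest(
        np.ascontiguousarray(binned.codes), y, int(n_trees), int(mtry),
        int(min_samples_leaf), binned.n_bins, int(seed) & 0x7FFFFFFFFFFFFFFF,
    )
    with np.errstate(invalid="ignore"):
        oob_pred = np.where(oob_cnt > 0, oob_sum / np.maximum(oob_cnt, 1), np.nan)
    values = binned.thresholds[sp_f, sp_b]
    return ForestFit(
        oob_prediction=oob_pred,
        oob_fraction=float(np.mean(oob_cnt > 0)),
        split_predictor=sp_f,
        split_value=values,
        split_importance=sp_i,
    )
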