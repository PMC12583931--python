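"""Respiration-informed two-cluster k-medoids of SCG beats.

Beats are clustered by dynamic-time-warping (DTW) dissimilarity into two
groups that track the respiration phase.  Initial medoids come from a median
split of a respiration covariate (lung volume or flow rate): within each
half, the beat minimizing the summed distance (DTW or cross-correlation) to
its half is the initial medoid.  All four {covariate} x {metric}
combinations are run and the one with the lowest intra-cluster variability
is kept.

The DTW here is the classic dynamic program with unit steps
{(1,0),(0,1),(1,1)} and local cost |a_i - b_j|; it also returns the warping
path length (number of matched cell pairs), which downstream features use to
normalize the accumulated cost into a per-step dissimilarity.  Ties in the
dynamic program prefer the diagonal step, then the vertical, for
determinism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import fft as sfft

from .errors import ClusteringFailedError, DegenerateSplitError, InvalidConfigError
from .segmentation import BeatSet

log = logging.getLogger(__name__)

INIT_BASES = ("lung_volume", "flow_rate")
INIT_METRICS = ("dtw", "xcorr")
REPRESENTATIVE_FRAC = 0.15


@dataclass
class DistanceResult:
    distance: float
    path_length: int  # 0 for cross-correlation distance


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-beat cluster id in {1, 2}
    medoid_1: int
    medoid_2: int
    representative_1: np.ndarray
    representative_2: np.ndarray
    init_basis: str
    init_metric: str
    n_iterations: int
    converged: bool
    audit: dict = field(default_factory=dict)  # WV_intra of all candidate runs


@njit(cache=True)
def _dtw_core(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    n = a.shape[0]
    m = b.shape[0]
    INF = np.inf
    prev = np.full(m + 1, INF)
    cur = np.full(m + 1, INF)
    prev_l = np.zeros(m + 1, dtype=np.int64)
    cur_l = np.zeros(m + 1, dtype=np.int64)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[0] = INF
        if i > 1:
            prev[0] = INF
        for j in range(1, m + 1):
            c = abs(a[i - 1] - b[j - 1])
            d_diag = prev[j - 1]
            d_up = prev[j]
            d_left = cur[j - 1]
            # tie preference: diagonal, then vertical, then horizontal
            if d_diag <= d_up and d_diag <= d_left:
                best, bl = d_diag, prev_l[j - 1]
            elif d_up <= d_left:
                best, bl = d_up, prev_l[j]
            else:
                best, bl = d_left, cur_l[j - 1]
            cur[j] = c + best
            cur_l[j] = bl + 1
        prev, cur = cur, prev
        prev_l, cur_l = cur_l, prev_l
    return prev[m], prev_l[m]


@njit(cache=True)
def _dtw_pairwise(data: np.ndarray, lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = lengths.shape[0]
    D = np.zeros((n, n))
    L = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        L[i, i] = lengths[i]
        for j in range(i + 1, n):
            d, l = _dtw_core(data[i, : lengths[i]], data[j, : lengths[j]])
            D[i, j] = d
            D[j, i] = d
            L[i, j] = l
            L[j, i] = l
    return D, L


def dtw_distance(a: np.ndarray, b: np.ndarray) -> DistanceResult:
    """Accumulated DTW cost and optimal warping path length."""
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidConfigError("DTW inputs need length >= 2")
    d, l = _dtw_core(a, b)
    return DistanceResult(distance=float(d), path_length=int(l))


MIN_XCORR_OVERLAP_FRAC = 0.5


def _xcorr_max_coeff(a0: np.ndarray, b0: np.ndarray, num: np.ndarray) -> float:
    """Max normalized cross-correlation coefficient over admissible lags.

    ``num`` is the full linear cross-correlation of the demeaned signals.
    Each lag is normalized by the norms of the two overlapping segments so
    a zero-padded shift of a waveform still correlates to ~1; lags with
    less than half the shorter waveform overlapping are excluded.
    """
    la, lb = len(a0), len(b0)
    ca = np.concatenate([[0.0], np.cumsum(a0**2)])
    cb = np.concatenate([[0.0], np.cumsum(b0**2)])
    best = -np.inf
    min_ov = max(2, int(np.ceil(MIN_XCORR_OVERLAP_FRAC * min(la, lb))))
    for m in range(la + lb - 1):
        s = m - (lb - 1)  # shift of b relative to a
        a_lo, a_hi = max(0, s), min(la, s + lb)
        ov = a_hi - a_lo
        if ov < min_ov:
            continue
        b_lo = a_lo - s
        na = ca[a_hi] - ca[a_lo]
        nb = cb[b_lo + ov] - cb[b_lo]
        if na <= 0 or nb <= 0:
            continue
        c = num[m] / np.sqrt(na * nb)
        if c > best:
            best = c
    if not np.isfinite(best):
        raise InvalidConfigError("no admissible lag for cross-correlation distance")
    return float(best)


def xcorr_distance(a: np.ndarray, b: np.ndarray) -> DistanceResult:
    """1 minus the maximum normalized cross-correlation over lags (in [0, 2])."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a0 = a - a.mean()
    b0 = b - b.mean()
    if np.linalg.norm(a0) == 0 or np.linalg.norm(b0) == 0:
        raise InvalidConfigError("cross-correlation distance undefined for constant input")
    num = np.correlate(a0, b0, mode="full")  # index m <-> shift m-(lb-1)
    d = 1.0 - _xcorr_max_coeff(a0, b0, num)
    return DistanceResult(distance=float(max(d, 0.0)), path_length=0)


class BeatDistanceCache:
    """Per-session cache of pairwise beat distances.

    The DTW cost and path-length matrices are computed once (the dominant
    cost of the whole pipeline) and shared by initialization, k-medoids, and
    the waveform-variability features.
    """

    def __init__(self, beat_set: BeatSet):
        self.beat_set = beat_set
        self._waves = [np.ascontiguousarray(w, dtype=float) for w in beat_set.waveforms()]
        self._dtw: tuple[np.ndarray, np.ndarray] | None = None
        self._xcorr: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self._waves)

    @property
    def waveforms(self) -> list[np.ndarray]:
        return self._waves

    @property
    def dtw_cost(self) -> np.ndarray:
        return self._dtw_matrices()[0]

    @property
    def dtw_path_len(self) -> np.ndarray:
        return self._dtw_matrices()[1]

    @property
    def dtw_normalized(self) -> np.ndarray:
        D, L = self._dtw_matrices()
        return D / L

    def _dtw_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        if self._dtw is None:
            lengths = np.array([len(w) for w in self._waves], dtype=np.int64)
            data = np.zeros((len(self._waves), int(lengths.max())))
            for i, w in enumerate(self._waves):
                data[i, : len(w)] = w
            self._dtw = _dtw_pairwise(data, lengths)
        return self._dtw

    @property
    def xcorr(self) -> np.ndarray:
        if self._xcorr is None:
            n = len(self._waves)
            maxlen = max(len(w) for w in self._waves)
            nfft = sfft.next_fast_len(2 * maxlen - 1)
            demeaned = [w - w.mean() for w in self._waves]
            if any(np.linalg.norm(w) == 0 for w in demeaned):
                raise InvalidConfigError("constant beat: cross-correlation undefined")
            F = np.stack([sfft.rfft(w, nfft) for w in demeaned])
            M = np.zeros((n, n))
            for i in range(n):
                a0 = demeaned[i]
                for j in range(i + 1, n):
                    b0 = demeaned[j]
                    la, lb = len(a0), len(b0)
                    cc = sfft.irfft(F[i] * np.conj(F[j]), nfft)
                    # map circular lags to the linear 'full' layout:
                    # index m <-> shift s = m - (lb - 1)
                    num = np.concatenate([cc[nfft - (lb - 1) :], cc[:la]])
                    d = 1.0 - _xcorr_max_coeff(a0, b0, num)
                    M[i, j] = M[j, i] = max(d, 0.0)
            self._xcorr = M
        return self._xcorr

    def metric_matrix(self, metric: str) -> np.ndarray:
        if metric == "dtw":
            return self.dtw_cost
        if metric == "xcorr":
            return self.xcorr
        raise ValueError(f"unknown metric {metric!r}")


def initial_medoids(
    beats: BeatSet, basis: str, metric: str, cache: BeatDistanceCache | None = None
) -> tuple[int, int]:
    """Median-split the respiration covariate; return per-half center beats."""
    if len(beats) < 4:
        raise InvalidConfigError("need at least 4 beats to initialize")
    cache = cache or BeatDistanceCache(beats)
    cov = beats.covariate(basis)
    if np.ptp(cov) == 0:
        raise DegenerateSplitError(f"covariate {basis!r} is constant across beats")
    order = np.argsort(cov, kind="stable")
    n = len(cov)
    halves = (np.sort(order[: n // 2]), np.sort(order[n // 2 :]))
    M = cache.metric_matrix(metric)
    centers = []
    for half in halves:
        sub = M[np.ix_(half, half)]
        row_sums = sub.sum(axis=1)
        # halves sorted ascending, so argmin ties resolve to the lowest beat index
        centers.append(int(half[int(np.argmin(row_sums))]))
    return centers[0], centers[1]


def kmedoids_two(
    beats: BeatSet,
    init: tuple[int, int],
    cache: BeatDistanceCache | None = None,
    max_iter: int = 50,
) -> ClusterResult:
    """Two-cluster k-medoids with DTW assignment distance.

    Alternates nearest-medoid assignment and in-cluster medoid update until
    the assignment is unchanged between consecutive iterations.  An emptied
    cluster is re-seeded with the beat farthest from the other medoid.
    """
    cache = cache or BeatDistanceCache(beats)
    D = cache.dtw_cost
    n = len(cache)
    m1, m2 = int(init[0]), int(init[1])
    if not (0 <= m1 < n and 0 <= m2 < n) or m1 == m2:
        raise InvalidConfigError("invalid initial medoid indices")
    labels = np.zeros(n, dtype=int)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_labels = np.where(D[:, m1] <= D[:, m2], 1, 2)
        # medoids always keep their own label (resolves zero-distance ties)
        new_labels[m1] = 1
        new_labels[m2] = 2
        # guarantee non-empty clusters
        for lab, own, other in ((1, m1, m2), (2, m2, m1)):
            if not np.any(new_labels == lab):
                far = int(np.argmax(D[:, other]))
                new_labels[far] = lab
                log.warning("cluster %d emptied; re-seeded with beat %d", lab, far)
        if np.array_equal(new_labels, labels):
            converged = True
            labels = new_labels
            break
        labels = new_labels
        for lab in (1, 2):
            idx = np.flatnonzero(labels == lab)
            sub = D[np.ix_(idx, idx)]
            med = int(idx[int(np.argmin(sub.sum(axis=1)))])
            if lab == 1:
                m1 = med
            else:
                m2 = med
    if not converged:
        log.warning("k-medoids hit max_iter=%d without convergence", max_iter)
    waves = cache.waveforms
    rep1 = representative_beat([waves[i] for i in np.flatnonzero(labels == 1)],
                               D[np.flatnonzero(labels == 1), m1])
    rep2 = representative_beat([waves[i] for i in np.flatnonzero(labels == 2)],
                               D[np.flatnonzero(labels == 2), m2])
    return ClusterResult(
        labels=labels,
        medoid_1=m1,
        medoid_2=m2,
        representative_1=rep1,
        representative_2=rep2,
        init_basis="",
        init_metric="",
        n_iterations=it,
        converged=converged,
    )


def representative_beat(
    cluster_waveforms: list[np.ndarray],
    dists_to_medoid: np.ndarray,
    frac: float = REPRESENTATIVE_FRAC,
) -> np.ndarray:
    """Average of the ``frac`` of beats nearest the medoid (DTW distance).

    The selected beats are linearly resampled to the cluster's median beat
    length before the pointwise average.
    """
    if len(cluster_waveforms) == 0:
        raise InvalidConfigError("cluster is empty")
    k = max(1, int(round(frac * len(cluster_waveforms))))
    nearest = np.argsort(np.asarray(dists_to_medoid), kind="stable")[:k]
    med_len = int(round(np.median([len(w) for w in cluster_waveforms])))
    x_new = np.linspace(0.0, 1.0, med_len)
    resampled = [
        np.interp(x_new, np.linspace(0.0, 1.0, len(cluster_waveforms[i])), cluster_waveforms[i])
        for i in nearest
    ]
    return np.mean(resampled, axis=0)


def _wv_intra_of(cache: BeatDistanceCache, labels: np.ndarray, m1: int, m2: int) -> float:
    ND = cache.dtw_normalized
    own = np.where(labels == 1, m1, m2)
    return float(np.mean(ND[np.arange(len(labels)), own]))


def select_best_clustering(
    beats: BeatSet, cache: BeatDistanceCache | None = None, max_iter: int = 50
) -> ClusterResult:
    """Run all four {covariate} x {init metric} combinations; keep the run
    with the lowest intra-cluster variability (path-normalized DTW)."""
    cache = cache or BeatDistanceCache(beats)
    best: ClusterResult | None = None
    best_wv = np.inf
    audit: dict[str, float] = {}
    for basis in INIT_BASES:
        for metric in INIT_METRICS:
            key = f"{basis}/{metric}"
            try:
                init = initial_medoids(beats, basis, metric, cache=cache)
                res = kmedoids_two(beats, init, cache=cache, max_iter=max_iter)
            except (DegenerateSplitError, InvalidConfigError) as exc:
                log.warning("initialization %s failed: %s", key, exc)
                audit[key] = float("nan")
                continue
            wv = _wv_intra_of(cache, res.labels, res.medoid_1, res.medoid_2)
            audit[key] = wv
            if wv < best_wv:
                best_wv = wv
                res.init_basis = basis
                res.init_metric = metric
                best = res
    if best is None:
        raise ClusteringFailedError("all four initializations were degenerate")
    best.audit = audit
    return best


def cluster_space_plot(beats: BeatSet, labels: np.ndarray, path) -> None:
    """Scatter beats in lung-volume / flow-rate space with an LDA boundary."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lv = beats.covariate("lung_volume")
    fr = beats.covariate("flow_rate")
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, marker, color in ((1, "o", "tab:blue"), (2, "^", "tab:red")):
        sel = labels == lab
        ax.scatter(lv[sel], fr[sel], marker=marker, c=color, label=f"cluster {lab}", alpha=0.8)
    X = np.column_stack([lv, fr])
    if len(np.unique(labels)) == 2 and np.linalg.matrix_rank(X - X.mean(0)) == 2:
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        lda = LinearDiscriminantAnalysis().fit(X, labels)
        w = lda.coef_[0]
        b = lda.intercept_[0]
        xs = np.linspace(lv.min(), lv.max(), 50)
        if abs(w[1]) > 1e-12:
            ys = -(w[0] * xs + b) / w[1]
            mask = (ys >= fr.min() - 0.5 * np.ptp(fr)) & (ys <= fr.max() + 0.5 * np.ptp(fr))
            ax.plot(xs[mask], ys[mask], "k--", label="decision boundary")
    ax.set_xlabel("lung volume (a.u.)")
    ax.set_ylabel("flow rate (a.u./s)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


class BeatKMedoids:
    """Two-cluster k-medoids estimator over a :class:`BeatSet`.

    scikit-learn-style interface: construct with hyperparameters, call
    :meth:`fit`, read fitted attributes (``labels_``, ``medoid_indices_``,
    ``representatives_``, ``result_``).  ``init_basis='auto'`` runs all four
    initialization combinations and keeps the best (lowest WV_intra).
    """

    def __init__(self, init_basis: str = "auto", init_metric: str = "dtw", max_iter: int = 50):
        self.init_basis = init_basis
        self.init_metric = init_metric
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"init_basis": self.init_basis, "init_metric": self.init_metric, "max_iter": self.max_iter}

    def set_params(self, **params) -> "BeatKMedoids":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, beat_set: BeatSet, y=None) -> "BeatKMedoids":
        cache = BeatDistanceCache(beat_set)
        if self.init_basis == "auto":
            result = select_best_clustering(beat_set, cache=cache, max_iter=self.max_iter)
        else:
            init = initial_medoids(beat_set, self.init_basis, self.init_metric, cache=cache)
            result = kmedoids_two(beat_set, init, cache=cache, max_iter=self.max_iter)
            result.init_basis = self.init_basis
            result.init_metric = self.init_metric
        self.cache_ = cache
        self.result_ = result
        self.labels_ = result.labels
        self.medoid_indices_ = (result.medoid_1, result.medoid_2)
        self.representatives_ = (result.representative_1, result.representative_2)
        return self

    def fit_predict(self, beat_set: BeatSet, y=None) -> np.ndarray:
        return self.fit(beat_set).labels_
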