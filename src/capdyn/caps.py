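"""Co-activation pattern (CAP) extraction.

The CAP pipeline treats single fMRI frames as samples of transient brain
states: per-run z-scoring, selection of frames where a seed network (FPN or
DAN) is highly active, k-means clustering of the selected frames into K
spatial co-activation maps, consensus-clustering selection of the model
order K, and assignment of every frame to a state sequence.

Frame-to-centroid distance is 1 - Pearson correlation: after centering and
unit-normalizing each frame across parcels, Lloyd iterations with
normalized mean centroids (spherical k-means) monotonically decrease the
objective, which is asserted at every iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .dynamics import CENSORED, StateSequence
from .io import ParcelTimeSeries, SeedDefinition


@dataclass
class FrameSelectionPolicy:
    """How suprathreshold frames are chosen from the seed signal.

    ``top_fraction`` keeps the ceil(fraction * n_usable) frames with the
    highest seed z-score; ``z_threshold`` keeps frames with seed z above
    ``z_cut``.  With polarity ``both`` the mirrored low/negative frames are
    also kept, stored sign-flipped so co-deactivations cluster together
    with co-activations.
    """

    mode: str = "top_fraction"
    fraction: float = 0.15
    z_cut: float = 1.0
    polarity: str = "activation"

    def __post_init__(self) -> None:
        if self.mode not in ("top_fraction", "z_threshold"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.polarity not in ("activation", "both"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.mode == "top_fraction" and not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")


@dataclass
class CAPSet:
    """K spatial co-activation maps plus the policy that produced them."""

    maps: np.ndarray  # K x P, mean z-scored BOLD of member frames
    k: int
    seed: SeedDefinition | None = None
    policy: FrameSelectionPolicy | None = None
    member_counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.shape[0] != self.k:
            raise ValueError("maps must have k rows")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("CAP maps must be finite")


@dataclass
class ConsensusReport:
    """Consensus-clustering summary per candidate model order."""

    k_range: list[int]
    pac: dict[int, float]
    mean_consensus: dict[int, float]
    n_resamples: int
    subsample_fraction: float
    selected_k: int

    def to_dict(self) -> dict:
        return {
            "k_range": list(self.k_range),
            "pac": {str(k): v for k, v in self.pac.items()},
            "mean_consensus": {str(k): v for k, v in self.mean_consensus.items()},
            "n_resamples": self.n_resamples,
            "subsample_fraction": self.subsample_fraction,
            "selected_k": self.selected_k,
        }


def zscore_run(series: ParcelTimeSeries, drop_constant: bool = False) -> ParcelTimeSeries:
    """Z-score each parcel over usable frames (population SD).

    Censored frames pass through untouched (they stay flagged and are never
    used downstream).  A zero-variance parcel raises unless
    ``drop_constant`` asks for it to be dropped.
    """
    usable = series.censor_mask
    if usable.sum() < 2:
        raise ValueError("need >= 2 usable frames to z-score")
    vals = series.values.copy()
    mu = vals[usable].mean(axis=0)
    sd = vals[usable].std(axis=0)
    zero = sd == 0
    if zero.any():
        names = [series.parcel_ids[j] for j in np.flatnonzero(zero)]
        if not drop_constant:
            raise ValueError(f"zero-variance parcels: {names}")
        warnings.warn(f"dropping zero-variance parcels: {names}")
        keep = ~zero
        vals = vals[:, keep]
        mu, sd = mu[keep], sd[keep]
        parcel_ids = [p for p, k in zip(series.parcel_ids, keep) if k]
    else:
        parcel_ids = list(series.parcel_ids)
    out = vals.copy()
    out[usable] = (vals[usable] - mu) / sd
    return ParcelTimeSeries(
        values=out,
        tr_seconds=series.tr_seconds,
        censor_mask=series.censor_mask.copy(),
        subject_id=series.subject_id,
        session_id=series.session_id,
        parcel_ids=parcel_ids,
    )


def seed_signal(series: ParcelTimeSeries, seed: SeedDefinition) -> np.ndarray:
    """Mean of the seed parcels per frame, re-standardized over usable frames."""
    seed.validate_against(series.n_parcels)
    sig = series.values[:, seed.parcel_indices].mean(axis=1)
    usable = series.censor_mask
    mu = sig[usable].mean()
    sd = sig[usable].std()
    if sd == 0:
        raise ValueError("seed signal has zero variance over usable frames")
    return (sig - mu) / sd


def select_frames(
    series: ParcelTimeSeries,
    seed: SeedDefinition,
    policy: FrameSelectionPolicy,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Select suprathreshold frames from a z-scored run.

    Returns ``(activation_indices, deactivation_indices, seed_z)``; both
    index arrays are strictly increasing and exclude censored frames.
    Deactivation indices are empty unless polarity is ``both``.
    """
    z = seed_signal(series, seed)
    usable_idx = np.flatnonzero(series.censor_mask)
    zu = z[usable_idx]
    if policy.mode == "top_fraction":
        n_sel = int(np.ceil(policy.fraction * usable_idx.size))
        if n_sel > usable_idx.size:
            raise ValueError("fewer usable frames than requested selection")
        # stable order: descending z, ties broken by frame index
        order = np.lexsort((usable_idx, -zu))
        act = np.sort(usable_idx[order[:n_sel]])
        deact = np.array([], dtype=int)
        if policy.polarity == "both":
            order_lo = np.lexsort((usable_idx, zu))
            deact = np.sort(usable_idx[order_lo[:n_sel]])
    else:
        act = usable_idx[zu > policy.z_cut]
        deact = np.array([], dtype=int)
        if policy.polarity == "both":
            deact = usable_idx[zu < -policy.z_cut]
    if policy.polarity == "both" and np.intersect1d(act, deact).size:
        both = np.intersect1d(act, deact)
        raise ValueError(f"frames selected as both activation and deactivation: {both}")
    return act, deact, z


def _row_normalize(frames: np.ndarray) -> np.ndarray:
    """Center and unit-normalize rows so cosine similarity equals Pearson r."""
    x = frames - frames.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-variance frame cannot be correlated")
    return x / norms


def _greedy_kmeanspp(xn: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy k-means++ seeding on unit rows (distance 1 - cosine)."""
    n = xn.shape[0]
    n_cand = 2 + int(np.log(k)) if k > 1 else 1
    centers = np.empty((k, xn.shape[1]))
    first = rng.integers(n)
    centers[0] = xn[first]
    d = 1.0 - xn @ centers[0]
    np.maximum(d, 0.0, out=d)
    for c in range(1, k):
        size = min(n_cand, n)
        if d.sum() > 0 and np.count_nonzero(d) >= size:
            probs = d / d.sum()
        else:
            probs = np.full(n, 1.0 / n)  # (near-)duplicate data: uniform
        cand = rng.choice(n, size=size, p=probs, replace=False)
        best_pot, best_i, best_d = np.inf, cand[0], None
        for i in cand:
            di = np.minimum(d, 1.0 - xn @ xn[i])
            pot = di.sum()
            if pot < best_pot:
                best_pot, best_i, best_d = pot, i, di
        centers[c] = xn[best_i]
        d = np.maximum(best_d, 0.0)
    return centers


def _lloyd_corr(
    xn: np.ndarray, centers: np.ndarray, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Spherical Lloyd iterations; returns (labels, centers, objective).

    An emptied cluster is repaired deterministically by re-seeding it at
    the frame currently worst-fit by its own centroid (ties -> lowest
    frame index); the monotonicity assertion is re-armed after a repair.
    """
    k = centers.shape[0]
    prev_obj = np.inf
    labels = None
    for _ in range(max_iter):
        sim = xn @ centers.T
        new_labels = np.argmax(sim, axis=1)
        obj = float(np.sum(1.0 - sim[np.arange(xn.shape[0]), new_labels]))
        # monotone objective is a correctness invariant of spherical k-means
        assert obj <= prev_obj + 1e-9, "k-means objective increased"
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        prev_obj = obj
        repaired = False
        own_sim = sim[np.arange(xn.shape[0]), labels].copy()
        for c in range(k):
            members = xn[labels == c]
            m = members.sum(axis=0) if members.shape[0] else np.zeros(xn.shape[1])
            norm = np.linalg.norm(m)
            if members.shape[0] == 0 or norm == 0:
                far = int(np.argmin(own_sim))
                centers[c] = xn[far]
                labels[far] = c
                own_sim[far] = np.inf  # a frame repairs at most one cluster
                repaired = True
            else:
                centers[c] = m / norm
        if repaired:
            prev_obj = np.inf
    sim = xn @ centers.T
    final = np.argmax(sim, axis=1)
    if len(np.unique(final)) < k and labels is not None and len(np.unique(labels)) == k:
        final = labels  # degenerate duplicate-frame data: keep repaired split
    if len(np.unique(final)) < k:
        raise _EmptyCluster  # caller restarts with a new seeding
    obj = float(np.sum(1.0 - sim[np.arange(xn.shape[0]), final]))
    return final, centers, obj


class _EmptyCluster(Exception):
    pass


def kmeans_correlation(
    frames: np.ndarray,
    k: int,
    rng_seed: int,
    n_init: int = 20,
    max_iter: int = 300,
) -> tuple[np.ndarray, float]:
    """K-means with 1 - Pearson correlation distance.

    Returns ``(labels, objective)`` of the best restart (lowest total
    within-cluster distance).  Cluster labels are arbitrary here; ordering
    is applied by :func:`kmeans_caps`.
    """
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} frames, got {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    xn = _row_normalize(frames)
    rng = np.random.default_rng(rng_seed)
    best_labels, best_obj = None, np.inf
    attempts, done = 0, 0
    while done < n_init and attempts < n_init * 10:
        attempts += 1
        try:
            centers = _greedy_kmeanspp(xn, k, rng)
            labels, _, obj = _lloyd_corr(xn, centers.copy(), max_iter)
        except _EmptyCluster:
            continue  # reseed and try again
        done += 1
        if obj < best_obj - 1e-12:
            best_obj, best_labels = obj, labels
    if best_labels is None:
        raise RuntimeError("k-means failed: every restart produced an empty cluster")
    return best_labels, best_obj


def kmeans_caps(
    frames: np.ndarray,
    k: int,
    rng_seed: int,
    seed: SeedDefinition | None = None,
    policy: FrameSelectionPolicy | None = None,
    n_init: int = 20,
) -> tuple[CAPSet, np.ndarray]:
    """Cluster selected frames into K CAPs.

    Each CAP map is the mean of its member frames; CAPs are renumbered in
    descending member count (ties by original cluster index) and frame
    labels are returned in 1..K.
    """
    frames = np.asarray(frames, dtype=float)
    raw_labels, _ = kmeans_correlation(frames, k, rng_seed, n_init=n_init)
    counts = np.bincount(raw_labels, minlength=k)
    order = np.lexsort((np.arange(k), -counts))  # descending count, stable
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    labels = remap[raw_labels]
    maps = np.vstack([frames[labels == c].mean(axis=0) for c in range(1, k + 1)])
    caps = CAPSet(
        maps=maps,
        k=k,
        seed=seed,
        policy=policy,
        member_counts=np.bincount(labels, minlength=k + 1)[1:],
    )
    return caps, labels


def consensus_select_k(
    frames: np.ndarray,
    k_range: list[int],
    n_resamples: int = 100,
    subsample_fraction: float = 0.8,
    rng_seed: int = 0,
    n_init: int = 1,
    pac_window: tuple[float, float] = (0.1, 0.9),
) -> ConsensusReport:
    """Select the model order by consensus clustering.

    For each k, one k-means fit is run per subsample (uniform, without
    replacement): the assignment instability across initializations and
    subsamples is exactly what the consensus matrix measures, so restarts
    are NOT pooled here.  consensus(i, j) = co-assignments / co-inclusions
    over resamples.  PAC (proportion of ambiguous clustering) is the
    fraction of defined off-diagonal consensus values strictly inside
    ``pac_window``; the selected k minimizes PAC (ties -> smaller k).
    """
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    k_range = sorted(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    if k_range[0] < 2 or k_range[-1] > n // 2:
        raise ValueError(f"k_range must lie within [2, n/2] = [2, {n // 2}]")
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    n_sub = max(2, int(round(subsample_fraction * n)))
    rng = np.random.default_rng(rng_seed)
    # one shared set of subsamples across k, so orders face identical data
    subsamples = [rng.choice(n, size=n_sub, replace=False) for _ in range(n_resamples)]
    incl_mat = np.zeros((n_resamples, n))
    for r, idx in enumerate(subsamples):
        incl_mat[r, idx] = 1.0
    co_incl = incl_mat.T @ incl_mat
    pac: dict[int, float] = {}
    mean_cons: dict[int, float] = {}
    lo, hi = pac_window
    iu = np.triu_indices(n, k=1)
    for k in k_range:
        co_assign = np.zeros((n, n))
        for idx in subsamples:
            labels, _ = kmeans_correlation(
                frames[idx], k, rng_seed=int(rng.integers(2**31)), n_init=n_init
            )
            onehot = np.zeros((n, k))
            onehot[idx, labels] = 1.0
            co_assign += onehot @ onehot.T
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = co_assign / co_incl
        vals = consensus[iu]
        defined = co_incl[iu] > 0
        if not defined.any():
            raise ValueError("no frame pair was ever co-included")
        v = vals[defined]
        pac[k] = float(np.mean((v > lo) & (v < hi)))
        mean_cons[k] = float(np.mean(v))
    selected = min(k_range, key=lambda k: (pac[k], k))
    return ConsensusReport(
        k_range=k_range,
        pac=pac,
        mean_consensus=mean_cons,
        n_resamples=n_resamples,
        subsample_fraction=subsample_fraction,
        selected_k=selected,
    )


def assign_states(
    series: ParcelTimeSeries,
    caps: CAPSet,
    policy: FrameSelectionPolicy,
    seed: SeedDefinition,
) -> StateSequence:
    """Label every frame of a z-scored run with a CAP state.

    Frames passing the selection policy get the label of the CAP with the
    highest spatial (Pearson) correlation, lower CAP index winning ties;
    all other usable frames are baseline 0; censored frames are -1.
    """
    if caps.maps.shape[1] != series.n_parcels:
        raise ValueError("CAP maps and series disagree on parcel count")
    act, deact, _ = select_frames(series, seed, policy)
    labels = np.zeros(series.n_frames, dtype=int)
    labels[~series.censor_mask] = CENSORED
    maps_n = _row_normalize(caps.maps)
    for idx, flip in ((act, 1.0), (deact, -1.0)):
        if idx.size == 0:
            continue
        sel = flip * series.values[idx]
        centered = sel - sel.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        ok = norms > 0
        if not ok.all():
            warnings.warn(
                f"{(~ok).sum()} zero-variance selected frame(s) kept at baseline"
            )
        corr = np.zeros((idx.size, caps.k))
        corr[ok] = (centered[ok] / norms[ok, None]) @ maps_n.T
        labels[idx[ok]] = np.argmax(corr[ok], axis=1) + 1
    return StateSequence(
        labels=labels,
        n_states=caps.k,
        subject_id=series.subject_id,
        session_id=series.session_id,
    )


def pool_selected_frames(
    timeseries: dict,
    seed: SeedDefinition,
    policy: FrameSelectionPolicy,
) -> np.ndarray:
    """Z-score every run, select seed frames, and pool them cohort-wide.

    Pooling across all subjects and both sessions gives one shared state
    space, which longitudinal comparisons require; per-run z-scoring keeps
    any single subject from dominating the clusters.
    """
    pooled = []
    for key in sorted(timeseries):
        z = zscore_run(timeseries[key])
        act, deact, _ = select_frames(z, seed, policy)
        pooled.append(z.values[act])
        if deact.size:
            pooled.append(-z.values[deact])
    return np.vstack(pooled)


def match_maps(planted: np.ndarray, recovered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian-match recovered CAP maps to planted maps by correlation.

    Returns ``(assignment, correlations)`` where ``assignment[i]`` is the
    recovered row matched to planted row i and ``correlations[i]`` the
    Pearson correlation of the matched pair.
    """
    pn = _row_normalize(np.asarray(planted, dtype=float))
    rn = _row_normalize(np.asarray(recovered, dtype=float))
    corr = pn @ rn.T
    row, col = linear_sum_assignment(-corr)
    return col, corr[row, col]
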