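"""Descriptive and multivariate brain-behavior statistics.

Univariate layer: paired t-tests between sessions and Pearson correlations
between longitudinal changes in network metrics and score changes.

Multivariate layer: behavioral grouped partial least squares correlation
(PLSC).  Brain (B metrics) and behavior (C scores) blocks are z-scored
WITHIN each subject group, the C x B cross-correlation matrices are
stacked over the G groups, and the stacked matrix R is decomposed by SVD
R = U S V'.  Each latent component (LC) pairs a brain salience (column of
V) with per-group behavior saliences (rows of U), capturing an axis along
which network dynamics and behavior covary while absolute group
differences are removed.  Significance of each LC comes from permuting
behavior rows within group (add-one permutation p on the singular value,
Procrustes-aligned by default); salience stability comes from within-group
bootstrap resampling with 5th/95th percentile intervals, an interval
excluding zero flagging the salience as robust.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


def paired_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test of y - x; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    d = y - x
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired differences have zero variance; t undefined")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class PLSCResult:
    """Grouped-PLSC decomposition plus optional inference results."""

    singular_values: np.ndarray
    brain_saliences: np.ndarray  # B x L (columns of V)
    behavior_saliences: np.ndarray  # (G*C) x L (columns of U, stacked per group)
    latent_brain_scores: np.ndarray  # n x L
    latent_behavior_scores: np.ndarray  # n x L
    group_labels: list[str]
    groups_order: list[str]
    cross_correlation: np.ndarray  # (G*C) x B stacked matrix R
    perm_p: np.ndarray | None = None
    boot_low_brain: np.ndarray | None = None
    boot_high_brain: np.ndarray | None = None
    boot_low_behavior: np.ndarray | None = None
    boot_high_behavior: np.ndarray | None = None
    n_perm: int = 0
    n_boot: int = 0
    rng_seed: int | None = None

    @property
    def n_components(self) -> int:
        return self.singular_values.size

    @property
    def robust_brain(self) -> np.ndarray:
        return (self.boot_low_brain > 0) | (self.boot_high_brain < 0)

    @property
    def robust_behavior(self) -> np.ndarray:
        return (self.boot_low_behavior > 0) | (self.boot_high_behavior < 0)

    def n_significant(self, alpha: float = 0.05) -> int:
        return int(np.sum(self.perm_p < alpha))

    def to_dict(self) -> dict:
        out = {
            "singular_values": self.singular_values.tolist(),
            "brain_saliences": self.brain_saliences.tolist(),
            "behavior_saliences": self.behavior_saliences.tolist(),
            "groups_order": self.groups_order,
            "n_perm": self.n_perm,
            "n_boot": self.n_boot,
        }
        if self.perm_p is not None:
            out["perm_p"] = self.perm_p.tolist()
        if self.boot_low_brain is not None:
            out["boot_low_brain"] = self.boot_low_brain.tolist()
            out["boot_high_brain"] = self.boot_high_brain.tolist()
            out["boot_low_behavior"] = self.boot_low_behavior.tolist()
            out["boot_high_behavior"] = self.boot_high_behavior.tolist()
            out["robust_brain"] = self.robust_brain.tolist()
            out["robust_behavior"] = self.robust_behavior.tolist()
        return out


def _group_zscore(x: np.ndarray, groups: np.ndarray, order: list[str]) -> np.ndarray:
    z = np.empty_like(x, dtype=float)
    for g in order:
        sel = groups == g
        sub = x[sel]
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        if np.any(sd == 0):
            cols = np.flatnonzero(sd == 0)
            raise ValueError(f"zero-variance column(s) {cols.tolist()} within group {g!r}")
        z[sel] = (sub - mu) / sd
    return z


def _stacked_corr(
    xz: np.ndarray, yz: np.ndarray, groups: np.ndarray, order: list[str]
) -> np.ndarray:
    blocks = []
    for g in order:
        sel = groups == g
        n_g = int(sel.sum())
        blocks.append(yz[sel].T @ xz[sel] / (n_g - 1))
    return np.vstack(blocks)


def plsc_fit(
    brain: np.ndarray,
    behavior: np.ndarray,
    groups: list[str] | np.ndarray,
) -> PLSCResult:
    """Grouped behavioral PLSC decomposition (no inference).

    Deterministic up to the documented sign convention: the largest-
    magnitude element of each brain salience is made positive.
    """
    x = np.asarray(brain, dtype=float)
    y = np.asarray(behavior, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0] or x.shape[0] != groups.size:
        raise ValueError("brain, behavior and groups must agree on the subject dimension")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    order = sorted(set(groups.tolist()))
    for g in order:
        if (groups == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
    xz = _group_zscore(x, groups, order)
    yz = _group_zscore(y, groups, order)
    r = _stacked_corr(xz, yz, groups, order)
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    v = vt.T
    # sign convention per LC: dominant brain-salience element positive
    for ell in range(s.size):
        j = int(np.argmax(np.abs(v[:, ell])))
        if v[j, ell] < 0:
            v[:, ell] *= -1
            u[:, ell] *= -1
    lx = xz @ v
    c = y.shape[1]
    ly = np.empty((y.shape[0], s.size))
    for gi, g in enumerate(order):
        sel = groups == g
        ly[sel] = yz[sel] @ u[gi * c : (gi + 1) * c, :]
    return PLSCResult(
        singular_values=s,
        brain_saliences=v,
        behavior_saliences=u,
        latent_brain_scores=lx,
        latent_behavior_scores=ly,
        group_labels=groups.tolist(),
        groups_order=order,
        cross_correlation=r,
    )


def _procrustes_rotation(v_ref: np.ndarray, v_new: np.ndarray) -> np.ndarray:
    """Orthogonal rotation aligning a resampled salience basis to the reference."""
    n, _, mt = np.linalg.svd(v_ref.T @ v_new)
    return (n @ mt).T


def plsc_permutation(
    brain: np.ndarray,
    behavior: np.ndarray,
    groups: list[str] | np.ndarray,
    n_perm: int = 1000,
    rng_seed: int = 0,
    procrustes: bool = False,
    fit: PLSCResult | None = None,
) -> np.ndarray:
    """Permutation p-values per LC (behavior rows shuffled within group).

    p(LC) = (1 + #{perm S >= observed S}) / (1 + n_perm), comparing sorted
    singular values.  Procrustes alignment of the permuted solution to the
    observed saliences is available but OFF by default: projecting permuted
    decompositions onto the observed directions systematically shrinks the
    permuted singular values and makes the test strongly anticonservative
    (empirical type-I error several times nominal under a true null).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives coarse p-values; consider >= 100")
    x = np.asarray(brain, dtype=float)
    y = np.asarray(behavior, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    if fit is None:
        fit = plsc_fit(x, y, groups)
    order = fit.groups_order
    xz = _group_zscore(x, groups, order)
    yz = _group_zscore(y, groups, order)
    rng = np.random.default_rng(rng_seed)
    s_obs = fit.singular_values
    exceed = np.zeros(s_obs.size)
    idx_groups = [np.flatnonzero(groups == g) for g in order]
    for _ in range(n_perm):
        perm = np.arange(groups.size)
        for idx in idx_groups:
            perm[idx] = rng.permutation(idx)
        r_p = _stacked_corr(xz, yz[perm], groups, order)
        u_p, s_p, vt_p = np.linalg.svd(r_p, full_matrices=False)
        if procrustes:
            q = _procrustes_rotation(fit.brain_saliences, vt_p.T)
            s_aligned = np.linalg.norm((u_p * s_p) @ q, axis=0)
        else:
            s_aligned = s_p
        exceed += s_aligned >= s_obs
    return (1.0 + exceed) / (1.0 + n_perm)


def plsc_bootstrap(
    brain: np.ndarray,
    behavior: np.ndarray,
    groups: list[str] | np.ndarray,
    n_boot: int = 500,
    rng_seed: int = 0,
    fit: PLSCResult | None = None,
    percentiles: tuple[float, float] = (5.0, 95.0),
    max_retries: int = 100,
) -> dict[str, np.ndarray]:
    """Within-group bootstrap percentile intervals for saliences.

    Each resample draws subjects with replacement within group, refits, and
    aligns the resampled saliences to the observed ones by Procrustes
    rotation (which includes the sign).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x = np.asarray(brain, dtype=float)
    y = np.asarray(behavior, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    if fit is None:
        fit = plsc_fit(x, y, groups)
    order = fit.groups_order
    idx_groups = [np.flatnonzero(groups == g) for g in order]
    rng = np.random.default_rng(rng_seed)
    brains, behaviors = [], []
    for _ in range(n_boot):
        for attempt in range(max_retries):
            take = np.concatenate(
                [rng.choice(idx, size=idx.size, replace=True) for idx in idx_groups]
            )
            gb = groups[take]
            try:
                fb = plsc_fit(x[take], y[take], gb)
            except ValueError:
                continue  # zero-variance column in this resample; redraw
            break
        else:
            raise RuntimeError(f"no valid bootstrap sample after {max_retries} retries")
        q = _procrustes_rotation(fit.brain_saliences, fb.brain_saliences)
        brains.append(fb.brain_saliences @ q)
        behaviors.append(fb.behavior_saliences @ q)
    vb = np.stack(brains)
    ub = np.stack(behaviors)
    lo, hi = percentiles
    return {
        "boot_low_brain": np.percentile(vb, lo, axis=0),
        "boot_high_brain": np.percentile(vb, hi, axis=0),
        "boot_low_behavior": np.percentile(ub, lo, axis=0),
        "boot_high_behavior": np.percentile(ub, hi, axis=0),
    }


def plsc_analyze(
    brain: np.ndarray,
    behavior: np.ndarray,
    groups: list[str] | np.ndarray,
    n_perm: int = 1000,
    n_boot: int = 500,
    rng_seed: int = 0,
    procrustes: bool = False,
) -> PLSCResult:
    """Fit + permutation significance + bootstrap stability in one call."""
    fit = plsc_fit(brain, behavior, groups)
    fit.perm_p = plsc_permutation(
        brain, behavior, groups, n_perm=n_perm, rng_seed=rng_seed,
        procrustes=procrustes, fit=fit,
    )
    boot = plsc_bootstrap(
        brain, behavior, groups, n_boot=n_boot, rng_seed=rng_seed + 1, fit=fit
    )
    fit.boot_low_brain = boot["boot_low_brain"]
    fit.boot_high_brain = boot["boot_high_brain"]
    fit.boot_low_behavior = boot["boot_low_behavior"]
    fit.boot_high_behavior = boot["boot_high_behavior"]
    fit.n_perm = n_perm
    fit.n_boot = n_boot
    fit.rng_seed = rng_seed
    return fit


def plot_saliences(result: PLSCResult, component: int = 0, brain_names=None,
                   behavior_names=None, path=None):
    """Bar plot of one LC's brain and per-group behavior saliences."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = result.brain_saliences[:, component]
    u = result.behavior_saliences[:, component]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].bar(range(v.size), v, color="tab:blue")
    axes[0].set_title(f"LC{component + 1} brain saliences")
    if brain_names is not None:
        axes[0].set_xticks(range(v.size), brain_names, rotation=45, ha="right")
    axes[1].bar(range(u.size), u, color="tab:orange")
    axes[1].set_title(f"LC{component + 1} behavior saliences (stacked by group)")
    if behavior_names is not None:
        names = [f"{g}:{b}" for g in result.groups_order for b in behavior_names]
        axes[1].set_xticks(range(u.size), names, rotation=45, ha="right")
    if result.boot_low_brain is not None:
        err = np.vstack(
            [v - result.boot_low_brain[:, component], result.boot_high_brain[:, component] - v]
        )
        axes[0].errorbar(range(v.size), v, yerr=np.abs(err), fmt="none", ecolor="k")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
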