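"""Synthetic multi-subject BOLD cohorts with known ground truth.

The generator emulates the study design the pipeline targets: 22 glioma
patients scanned at two sessions (pre-surgery, 3-month post), parcel-level
BOLD generated from a hidden Markov chain over K co-activation states plus
a noise-only baseline state, and neuropsychological scores (TMT-A/B/B-A,
attentional matrices) at three timepoints (pre, 1-week, 3-month) carrying
one planted latent axis that links temporal network metrics to behavior.

A "deficit" subgroup has a less stable, more switching FPN-like state
(scaled self- and in-transition probabilities) and its 1-week scores are
shifted past the clinical cutoffs; 3-month scores regress to the
pre-surgical level.  Everything is deterministic given the cohort seed:
per-subject streams are derived by stable hashing of (seed, subject,
session), so adding subjects never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import StateSequence, compute_metrics
from .io import SCORE_ORIENTATION, BehavioralTable, ParcelTimeSeries, SeedDefinition

#: Default per-score generative constants on the adjusted clinical scale:
#: (intercept, scale of one latent/noise z-unit, clinical cutoff,
#:  1-week shift applied to the deficit group).  TMT scores are seconds
#: (higher = worse); attentional matrices is a count (higher = better).
SCORE_PARAMS = {
    "TMTA": {"intercept": 45.0, "scale": 8.0, "cutoff": 94.0, "deficit_shift": 70.0},
    "TMTB": {"intercept": 105.0, "scale": 16.0, "cutoff": 283.0, "deficit_shift": 90.0},
    "AttentionalMatrices": {"intercept": 50.0, "scale": 3.0, "cutoff": 31.0, "deficit_shift": -8.0},
}
TMTBA_CUTOFF = 187.0


def _derive_seed(*parts) -> int:
    """Stable 31-bit stream seed from arbitrary labeled parts."""
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    p = np.asarray(transition_matrix, dtype=float)
    w, v = np.linalg.eig(p.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def validate_transition_matrix(p: np.ndarray, atol: float = 1e-12) -> None:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(p < 0):
        i = int(np.argwhere(p < 0)[0][0])
        raise ValueError(f"transition matrix row {i} has a negative entry")
    sums = p.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > atol)
    if bad.size:
        raise ValueError(
            f"transition matrix row {bad[0]} sums to {sums[bad[0]]!r}, not 1"
        )


@dataclass
class StateModel:
    """Generative analogue of the CAP state space.

    ``maps`` holds K spatial amplitude patterns (z-scale units, unit
    variance across parcels); state 0 is a reserved noise-only baseline.
    Frame t in CAP state s emits ``a_t * maps[s-1] + noise`` with
    ``a_t ~ N(amplitude_mean, amplitude_sd)``.
    """

    n_states: int
    n_parcels: int
    maps: np.ndarray
    seed_parcels: np.ndarray
    transition_matrix: np.ndarray
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.25
    noise_sd: float = 0.8
    baseline_index: int = 0

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.seed_parcels = np.asarray(self.seed_parcels, dtype=int)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.maps.shape != (self.n_states, self.n_parcels):
            raise ValueError("maps must be n_states x n_parcels")
        sd = self.maps.std(axis=1)
        if not np.allclose(sd, 1.0, atol=1e-8):
            raise ValueError("each state map must have unit variance across parcels")
        if self.transition_matrix.shape != (self.n_states + 1, self.n_states + 1):
            raise ValueError("transition matrix must be (K+1) x (K+1)")
        validate_transition_matrix(self.transition_matrix)
        if np.any(self.seed_parcels < 0) or np.any(self.seed_parcels >= self.n_parcels):
            raise ValueError("seed_parcels out of range")


def default_transition_matrix(n_states: int = 4) -> np.ndarray:
    """Baseline-plus-K chain: sticky states with a shared baseline hub.

    Baseline persists with p=0.6 and enters each CAP with equal mass; CAP
    states persist with p=0.55 (the planted resilience), mostly fall back
    to baseline (p=0.36) and only rarely switch directly between CAPs
    (p=0.03 per target), so the baseline acts as the switching hub and the
    empirical transition graph is sparse enough for betweenness to vary
    across subjects at desk-scale scan lengths.
    """
    k1 = n_states + 1
    p = np.zeros((k1, k1))
    p[0, 0] = 0.6
    p[0, 1:] = 0.4 / n_states
    for c in range(1, k1):
        p[c, c] = 0.55
        others = [j for j in range(1, k1) if j != c]
        p[c, others] = 0.03
        p[c, 0] = 1.0 - 0.55 - 0.03 * len(others)
    return p


def default_state_model(
    n_states: int = 4,
    n_parcels: int = 90,
    n_seed_parcels: int = 9,
    map_seed: int = 0,
    **kwargs,
) -> StateModel:
    """Random orthogonal-ish state maps that all load positively on the seed."""
    rng = np.random.default_rng(_derive_seed("maps", map_seed))
    maps = rng.standard_normal((n_states, n_parcels))
    seed_parcels = np.arange(n_seed_parcels)
    # every state co-activates the seed region, so seed-driven frame
    # selection captures all K states
    maps[:, seed_parcels] = 1.5 + 0.5 * np.abs(maps[:, seed_parcels])
    maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
    return StateModel(
        n_states=n_states,
        n_parcels=n_parcels,
        maps=maps,
        seed_parcels=seed_parcels,
        transition_matrix=default_transition_matrix(n_states),
        **kwargs,
    )


@dataclass
class GroupEffects:
    """Multiplicative modifiers of the FPN-like state's transition row/column.

    ``self_scale`` rescales the state's self-transition (resilience);
    ``switch_in_scale`` rescales entries into the state from every other
    state.  Rows are renormalized afterwards, so reducing stability
    automatically raises out-switching.
    """

    self_scale: float = 1.0
    switch_in_scale: float = 1.0

    def apply(self, p: np.ndarray, state: int) -> np.ndarray:
        q = np.asarray(p, dtype=float).copy()
        q[state, state] *= self.self_scale
        for i in range(q.shape[0]):
            if i != state:
                q[i, state] *= self.switch_in_scale
        q /= q.sum(axis=1, keepdims=True)
        validate_transition_matrix(q, atol=1e-9)
        return q


#: Deficit-group dynamics: a less stable, more switching FPN state.
DEFAULT_GROUP_EFFECTS = {
    "no_deficit": GroupEffects(),
    "deficit": GroupEffects(self_scale=0.62, switch_in_scale=1.7),
}


@dataclass
class CohortSpec:
    """Everything needed to generate one synthetic cohort deterministically."""

    n_subjects: int = 22
    sessions: tuple[str, ...] = ("pre", "post3m")
    n_frames: int = 180
    tr_seconds: float = 2.0
    n_states: int = 4
    n_parcels: int = 90
    fpn_state: int = 4  # the designated FPN-like CAP (label K by default)
    group_assignment: dict[str, str] | None = None
    group_effects: dict[str, GroupEffects] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    behavior_loadings: dict[str, float] = field(
        default_factory=lambda: {"TMTA": -1.0, "TMTB": -1.0, "AttentionalMatrices": 1.0}
    )
    behavior_noise_sd: float = 0.6
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.25
    noise_sd: float = 0.8
    seed: int = 0

    def subject_ids(self) -> list[str]:
        return [f"sub{i:02d}" for i in range(self.n_subjects)]

    def groups(self) -> dict[str, str]:
        if self.group_assignment is not None:
            missing = sorted(set(self.subject_ids()) - set(self.group_assignment))
            if missing:
                raise ValueError(f"group_assignment misses subjects: {missing}")
            return dict(self.group_assignment)
        # alternate so both groups have (near-)equal size
        return {
            s: ("no_deficit" if i % 2 == 0 else "deficit")
            for i, s in enumerate(self.subject_ids())
        }

    def state_model(self) -> StateModel:
        return default_state_model(
            n_states=self.n_states,
            n_parcels=self.n_parcels,
            map_seed=self.seed,
            amplitude_mean=self.amplitude_mean,
            amplitude_sd=self.amplitude_sd,
            noise_sd=self.noise_sd,
        )


def sample_state_sequence(
    transition_matrix: np.ndarray,
    n_frames: int,
    initial_distribution: np.ndarray | None = None,
    rng_seed: int = 0,
) -> StateSequence:
    """Sample a Markov state sequence over {baseline 0, CAP 1..K}."""
    p = np.asarray(transition_matrix, dtype=float)
    validate_transition_matrix(p, atol=1e-9)
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    k1 = p.shape[0]
    if initial_distribution is None:
        initial_distribution = stationary_distribution(p)
    pi = np.asarray(initial_distribution, dtype=float)
    if pi.shape != (k1,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("initial_distribution must be a probability vector over states")
    rng = np.random.default_rng(rng_seed)
    cum = np.cumsum(p, axis=1)
    labels = np.empty(n_frames, dtype=int)
    labels[0] = int(np.searchsorted(np.cumsum(pi), rng.random(), side="right"))
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        labels[t] = int(np.searchsorted(cum[labels[t - 1]], u[t - 1], side="right"))
    return StateSequence(labels=labels, n_states=k1 - 1)


def generate_subject_timeseries(
    model: StateModel, sequence: StateSequence, rng_seed: int = 0
) -> ParcelTimeSeries:
    """Emit BOLD frames for one sequence: a_t * map + noise, or pure noise at baseline."""
    if sequence.labels.max(initial=0) > model.n_states:
        raise ValueError("sequence labels exceed the model's state count")
    rng = np.random.default_rng(rng_seed)
    t = sequence.labels.size
    values = rng.normal(0.0, model.noise_sd, size=(t, model.n_parcels))
    amps = rng.normal(model.amplitude_mean, model.amplitude_sd, size=t)
    for i, s in enumerate(sequence.labels):
        if s > 0:
            values[i] += amps[i] * model.maps[s - 1]
    return ParcelTimeSeries(
        values=values,
        tr_seconds=2.0,
        censor_mask=np.ones(t, dtype=bool),
        subject_id=sequence.subject_id,
        session_id=sequence.session_id,
    )


def _latent_axis(metrics: pd.DataFrame, fpn_state: int) -> pd.Series:
    """Planted latent: standardized occurrence + resilience of the FPN state.

    Standardization is across subjects within session, so the latent is a
    pure within-cohort contrast of FPN stability.
    """
    sub = metrics[metrics["state"] == fpn_state].set_index(["subject", "session"])
    if sub.empty:
        raise ValueError(f"metrics table has no rows for state {fpn_state}")
    out = {}
    for session, g in sub.groupby(level="session"):
        z = pd.DataFrame(index=g.index)
        for col in ("occurrence", "resilience"):
            v = g[col]
            sd = v.std(ddof=0)
            z[col] = (v - v.mean()) / (sd if sd > 0 else 1.0)
        lat = (z["occurrence"] + z["resilience"]) / np.sqrt(2.0)
        for idx, val in lat.items():
            out[idx] = val
    return pd.Series(out).rename_axis(["subject", "session"])


def generate_behavior(
    metrics: pd.DataFrame,
    spec: CohortSpec,
    rng_seed: int = 0,
) -> BehavioralTable:
    """Behavioral scores at pre / 1-week / 3-month with a planted latent axis.

    Pre and 3-month scores load on the session-specific latent (so the
    3-month-minus-pre behavioral change covaries with the change in FPN
    dynamics along the planted axis, while group means regress to the
    pre-surgical baseline); 1-week scores additionally shift the deficit
    group past the clinical cutoffs.  TMT-B-A is derived as TMTB - TMTA at
    every timepoint.
    """
    groups = spec.groups()
    subjects = spec.subject_ids()
    have = set(metrics["subject"])
    missing = sorted(set(subjects) - have)
    if missing:
        raise ValueError(f"metrics table lacks rows for subjects: {missing}")
    latent = _latent_axis(metrics, spec.fpn_state)
    rng = np.random.default_rng(_derive_seed("behavior", rng_seed))
    rows = []
    for subject in subjects:
        lat = {s: latent.get((subject, s), 0.0) for s in spec.sessions}
        deficit = groups[subject] == "deficit"
        for score, pars in SCORE_PARAMS.items():
            loading = spec.behavior_loadings.get(score, 0.0)
            noise = rng.normal(0.0, spec.behavior_noise_sd, size=3)
            vals = {
                "pre": pars["intercept"]
                + pars["scale"] * (loading * lat["pre"] + noise[0]),
                "1w": pars["intercept"]
                + pars["scale"] * (loading * lat["pre"] + noise[1])
                + (pars["deficit_shift"] if deficit else 0.0),
                "3m": pars["intercept"]
                + pars["scale"] * (loading * lat["post3m"] + noise[2]),
            }
            for tp, v in vals.items():
                rows.append(
                    {
                        "subject": subject,
                        "timepoint": tp,
                        "score": score,
                        "value": float(v),
                        "cutoff": pars["cutoff"],
                        "orientation": SCORE_ORIENTATION[score],
                    }
                )
    df = pd.DataFrame(rows)
    # derive TMT B-A exactly, preserving the identity at every timepoint
    wide = df.pivot(index=["subject", "timepoint"], columns="score", values="value")
    ba = (wide["TMTB"] - wide["TMTA"]).reset_index()
    ba.columns = ["subject", "timepoint", "value"]
    ba["score"] = "TMTBA"
    ba["cutoff"] = TMTBA_CUTOFF
    ba["orientation"] = SCORE_ORIENTATION["TMTBA"]
    df = pd.concat([df, ba], ignore_index=True)
    df = df.sort_values(["subject", "timepoint", "score"]).reset_index(drop=True)
    return BehavioralTable(table=df)


@dataclass
class Cohort:
    """A generated dataset bundle with full ground truth retained."""

    spec: CohortSpec
    model: StateModel
    group_matrices: dict[str, np.ndarray]
    sequences: dict[tuple[str, str], StateSequence]
    timeseries: dict[tuple[str, str], ParcelTimeSeries]
    metrics: pd.DataFrame  # from the planted sequences (ground truth)
    behavior: BehavioralTable
    manifest: pd.DataFrame

    @property
    def groups(self) -> dict[str, str]:
        return self.spec.groups()

    def seed_definition(self, name: str = "FPN") -> SeedDefinition:
        return SeedDefinition(name=name, parcel_indices=self.model.seed_parcels)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort bundle, deterministic given ``spec.seed``."""
    model = spec.state_model()
    groups = spec.groups()
    unknown = sorted(set(groups.values()) - set(spec.group_effects))
    if unknown:
        raise ValueError(f"no group_effects entry for groups: {unknown}")
    group_matrices = {
        g: eff.apply(model.transition_matrix, spec.fpn_state)
        for g, eff in spec.group_effects.items()
    }
    sequences: dict[tuple[str, str], StateSequence] = {}
    timeseries: dict[tuple[str, str], ParcelTimeSeries] = {}
    manifest_rows = []
    metric_frames = []
    for subject in spec.subject_ids():
        p = group_matrices[groups[subject]]
        for session in spec.sessions:
            seq = sample_state_sequence(
                p,
                spec.n_frames,
                rng_seed=_derive_seed(spec.seed, subject, session, "seq"),
            )
            seq.subject_id, seq.session_id = subject, session
            ts = generate_subject_timeseries(
                model, seq, rng_seed=_derive_seed(spec.seed, subject, session, "bold")
            )
            ts.tr_seconds = spec.tr_seconds
            sequences[(subject, session)] = seq
            timeseries[(subject, session)] = ts
            manifest_rows.append(
                {
                    "subject": subject,
                    "session": session,
                    "group": groups[subject],
                    "path": f"timeseries/{subject}_{session}.tsv",
                }
            )
            m = compute_metrics(seq, spec.tr_seconds)
            m["subject"], m["session"] = subject, session
            metric_frames.append(m)
    metrics = pd.concat(metric_frames, ignore_index=True)
    behavior = generate_behavior(
        metrics, spec, rng_seed=_derive_seed(spec.seed, "behavior")
    )
    return Cohort(
        spec=spec,
        model=model,
        group_matrices=group_matrices,
        sequences=sequences,
        timeseries=timeseries,
        metrics=metrics,
        behavior=behavior,
        manifest=pd.DataFrame(manifest_rows),
    )
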