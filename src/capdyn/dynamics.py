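"""Temporal metrics of brain-state sequences.

A state sequence labels every fMRI frame with baseline 0, a co-activation
pattern (CAP) state 1..K, or censored (-1).  From the directed transition
graph over states we compute, per subject-session-state:

* occurrence   - fraction of usable frames spent in the state
* duration     - mean dwell length of visits, in seconds (frames x TR)
* resilience   - self-transition probability (stability)
* IN-degree    - fraction of all between-state switches that enter the state
* OUT-degree   - fraction of all between-state switches that leave the state
* betweenness  - node betweenness on the -log(probability)-weighted graph

Longitudinal change is the difference of post-surgery (3-month) minus
pre-surgery values per subject and state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

CENSORED = -1
METRIC_NAMES = ("occurrence", "duration", "resilience", "in_degree", "out_degree", "betweenness")


@dataclass
class StateSequence:
    """Per-frame state labels: -1 censored, 0 baseline, 1..K CAP states."""

    labels: np.ndarray
    n_states: int
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D array")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.labels.max(initial=CENSORED) > self.n_states:
            raise ValueError(
                f"label {self.labels.max()} exceeds n_states={self.n_states}"
            )
        if self.labels.min(initial=0) < CENSORED:
            raise ValueError("labels below -1 are not allowed")

    @property
    def usable(self) -> np.ndarray:
        return self.labels != CENSORED

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())


def transition_counts(sequence: StateSequence) -> np.ndarray:
    """(K+1)x(K+1) matrix of observed i->j frame adjacencies.

    Pairs straddling a censored frame are skipped, so the total equals the
    number of usable adjacencies.
    """
    k1 = sequence.n_states + 1
    counts = np.zeros((k1, k1), dtype=int)
    lab = sequence.labels
    for a, b in zip(lab[:-1], lab[1:]):
        if a != CENSORED and b != CENSORED:
            counts[a, b] += 1
    return counts


def _dwell_lengths(sequence: StateSequence, state: int) -> list[int]:
    """Lengths of maximal runs of `state` within contiguous usable stretches."""
    out: list[int] = []
    run = 0
    for lab in sequence.labels:
        if lab == state:
            run += 1
        else:
            if run:
                out.append(run)
            run = 0
    if run:
        out.append(run)
    return out


def betweenness(counts: np.ndarray) -> np.ndarray:
    """Node betweenness of the directed transition graph.

    Edges exist where ``counts[i, j] > 0`` (i != j) with length
    ``-log(p_ij)``, p row-normalized over off-diagonal counts, so
    higher-probability routes are shorter.  Each node's value is the mean,
    over ordered pairs (s, t) with s != t != v that have at least one path,
    of the fraction of shortest s->t paths passing through v; nodes in
    graphs with fewer than three nodes score zero.
    """
    counts = np.asarray(counts)
    k1 = counts.shape[0]
    present = [i for i in range(k1) if counts[i].sum() + counts[:, i].sum() > 0]
    result = np.zeros(k1)
    if len(present) < 3:
        return result
    tol = 1e-9
    g = nx.DiGraph()
    g.add_nodes_from(present)
    for i in present:
        off = counts[i].sum() - counts[i, i]
        if off <= 0:
            continue
        for j in present:
            if i != j and counts[i, j] > 0:
                p = counts[i, j] / off
                # floor at a tiny positive length so probability-1 edges
                # cannot create zero-length cycles or ambiguous orderings
                g.add_edge(i, j, length=max(-np.log(p), 1e-6))
    acc = {v: 0.0 for v in present}
    pairs = {v: 0 for v in present}
    for s in present:
        dist = nx.single_source_dijkstra_path_length(g, s, weight="length")
        reach = [t for t in dist if t != s]
        for v in present:
            if v != s:
                pairs[v] += len([t for t in reach if t != v])
        # Brandes accumulation over the tolerance-based shortest-path DAG,
        # so ties in floating-point path lengths are counted, not broken
        order = sorted(reach, key=dist.get)
        sigma = {v: 0.0 for v in dist}
        sigma[s] = 1.0
        preds: dict[int, list[int]] = {v: [] for v in dist}
        for v in order:
            for u in g.predecessors(v):
                if u in dist and abs(dist[u] + g[u][v]["length"] - dist[v]) < tol:
                    preds[v].append(u)
                    sigma[v] += sigma[u]
        delta = {v: 0.0 for v in dist}
        for v in reversed(order):
            for u in preds[v]:
                delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
        for v in reach:
            acc[v] += delta[v]
    for v in present:
        if pairs[v]:
            result[v] = acc[v] / pairs[v]
    return result


def compute_metrics(
    sequence: StateSequence, tr_seconds: float, k: int | None = None
) -> pd.DataFrame:
    """Per-state temporal metrics for one subject-session sequence.

    Returns a tidy frame with one row per state 0..K (baseline included;
    reporting layers typically keep CAP states 1..K).  States never visited
    get occurrence 0, duration 0, degrees 0 and resilience 0 with
    ``resilience_defined`` False.
    """
    if k is None:
        k = sequence.n_states
    if sequence.labels.max(initial=CENSORED) > k:
        raise ValueError("sequence contains labels above k")
    if sequence.n_usable == 0:
        raise ValueError("all frames censored; metrics undefined")
    seq = StateSequence(
        labels=sequence.labels,
        n_states=k,
        subject_id=sequence.subject_id,
        session_id=sequence.session_id,
    )
    counts = transition_counts(seq)
    n_usable = seq.n_usable
    lab = seq.labels
    between_total = counts.sum() - np.trace(counts)
    btw = betweenness(counts)
    rows = []
    for c in range(k + 1):
        occ = float((lab == c).sum()) / n_usable
        dwells = _dwell_lengths(seq, c)
        duration = float(np.mean(dwells)) * tr_seconds if dwells else 0.0
        row_total = counts[c].sum()
        if row_total > 0:
            resilience = counts[c, c] / row_total
            res_defined = True
        else:
            resilience = 0.0
            res_defined = False
        if between_total > 0:
            in_deg = (counts[:, c].sum() - counts[c, c]) / between_total
            out_deg = (counts[c].sum() - counts[c, c]) / between_total
        else:
            in_deg = out_deg = 0.0
        rows.append(
            {
                "subject": seq.subject_id,
                "session": seq.session_id,
                "state": c,
                "occurrence": occ,
                "duration": duration,
                "resilience": float(resilience),
                "resilience_defined": res_defined,
                "in_degree": float(in_deg),
                "out_degree": float(out_deg),
                "betweenness": float(btw[c]),
            }
        )
    return pd.DataFrame(rows)


def metrics_table(
    sequences: dict[tuple[str, str], StateSequence],
    tr_seconds: float,
    k: int | None = None,
) -> pd.DataFrame:
    """Stack per-sequence metrics into one tidy cohort table."""
    frames = []
    for (subject, session), seq in sorted(sequences.items()):
        df = compute_metrics(seq, tr_seconds, k=k)
        df["subject"] = subject
        df["session"] = session
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def longitudinal_delta(
    metrics: pd.DataFrame, pre: str = "pre", post: str = "post3m"
) -> pd.DataFrame:
    """Post-minus-pre change per subject and state for every metric.

    Subjects lacking either session are dropped with a warning (they cannot
    contribute a longitudinal difference).
    """
    value_cols = [m for m in METRIC_NAMES if m in metrics.columns]
    pre_df = metrics[metrics["session"] == pre].set_index(["subject", "state"])
    post_df = metrics[metrics["session"] == post].set_index(["subject", "state"])
    common = pre_df.index.intersection(post_df.index)
    missing = sorted(
        set(metrics["subject"])
        - set(common.get_level_values(0))
    )
    if missing:
        warnings.warn(f"subjects lacking both sessions dropped from deltas: {missing}")
    delta = (post_df.loc[common, value_cols] - pre_df.loc[common, value_cols]).reset_index()
    return delta.sort_values(["subject", "state"]).reset_index(drop=True)
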