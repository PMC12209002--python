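"""Neuropsychological score handling: deficit classification and deltas.

Scores arrive already adjusted for age and education.  A subject is
classified as having a cognitive deficit at a timepoint (default: one week
after surgery) when ANY score falls on the impaired side of its clinical
cutoff; a score exactly at the cutoff is NOT impaired (strict inequality).
Orientation is normalized explicitly: for timed tests (TMT) impairment is
above the cutoff, for accuracy tests (attentional matrices) below it.
"""

from __future__ import annotations

import pandas as pd

from .io import BehavioralTable


def impairment_flags(table: BehavioralTable, timepoint: str) -> pd.DataFrame:
    """Per-subject, per-score impaired booleans at one timepoint."""
    sub = table.table[table.table["timepoint"] == timepoint].copy()
    if sub.empty:
        raise ValueError(f"no behavior rows at timepoint {timepoint!r}")
    worse = sub["orientation"] == "higher_worse"
    sub["impaired"] = (sub["value"] > sub["cutoff"]) & worse
    sub.loc[~worse, "impaired"] = sub.loc[~worse, "value"] < sub.loc[~worse, "cutoff"]
    return sub[["subject", "score", "impaired"]]


def classify_deficit(
    table: BehavioralTable,
    timepoint: str = "1w",
    required_scores: tuple[str, ...] = ("TMTA", "TMTB", "TMTBA", "AttentionalMatrices"),
) -> pd.DataFrame:
    """Dichotomous deficit classification: any impaired score -> deficit.

    Returns one row per subject with ``deficit`` plus per-score booleans.
    Raises if any required score is missing for any subject.
    """
    flags = impairment_flags(table, timepoint)
    wide = flags.pivot(index="subject", columns="score", values="impaired")
    missing = []
    for score in required_scores:
        if score not in wide.columns:
            missing.append((None, score))
        else:
            for subject in wide.index[wide[score].isna()]:
                missing.append((subject, score))
    if missing:
        raise ValueError(f"missing scores for deficit classification: {missing}")
    wide = wide[list(required_scores)].astype(bool)
    out = wide.copy()
    out.insert(0, "deficit", wide.any(axis=1))
    out.insert(0, "timepoint", timepoint)
    return out.reset_index()


def delta_scores(
    table: BehavioralTable, tp_from: str = "pre", tp_to: str = "3m"
) -> pd.DataFrame:
    """Per-subject, per-score change value(to) - value(from), wide by score."""
    a = table.wide(tp_from)
    b = table.wide(tp_to)
    if a.empty or b.empty:
        raise ValueError(f"missing timepoint among ({tp_from!r}, {tp_to!r})")
    common = a.index.intersection(b.index)
    delta = (b.loc[common] - a.loc[common]).dropna(axis=1, how="all")
    delta.columns.name = None
    return delta
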