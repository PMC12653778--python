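"""Prevalence and symmetry tabulations for four-limb marking scores.

Reproduces the standard study-style descriptive tables: per-limb score
distributions (affected vs not, and the split of the affected among the
three severity classes), prevalence of the seven limb combinations A-G
(bilateral, sagittal, diagonal and all-four patterns), and stratified
prevalence by a systematic factor (sex or coat).

"Affected" on a combination means affected (score > 0) on *every* limb the
combination lists, so combination counts are monotone under set inclusion:
the all-four combination G is a subset of each pair A-F, which are subsets
of their constituent limbs.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .simulate import LIMBS, MarkingDataset

COMBINATIONS: dict[str, tuple[str, ...]] = {
    "A": ("lf", "rf"),
    "B": ("lh", "rh"),
    "C": ("lf", "lh"),
    "D": ("rf", "rh"),
    "E": ("lf", "rh"),
    "F": ("rf", "lh"),
    "G": ("lf", "rf", "lh", "rh"),
}

CLASS_LABELS = {1: "below_fetlock", 2: "above_fetlock", 3: "cannon_bone"}


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal half-up rounding (what printed tables use; banker's rounding
    would drop some .x5 values down)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int, digits: int = 1) -> float:
    """Half-up rounded percentage; 0 total yields nan (share undefined)."""
    if total == 0:
        return float("nan")
    return round_half_up(100.0 * count / total, digits)


def _frame(data) -> pd.DataFrame:
    return data.frame if isinstance(data, MarkingDataset) else data


def _check_scores(frame: pd.DataFrame) -> None:
    for limb in LIMBS:
        bad = ~frame[limb].isin([0, 1, 2, 3])
        if bad.any():
            rid = frame.loc[bad, "animal"].iloc[0] if "animal" in frame else bad.idxmax()
            raise ValueError(f"score out of range 0..3 in column {limb} (row {rid!r})")


def score_distribution(data, digits: int = 1) -> pd.DataFrame:
    """Per-limb counts and percentages by score class.

    One row per limb with: total N, not-affected and affected counts with
    percentages of the total, and class 1-3 counts with percentages *of the
    affected animals* (the class-share convention of the study tables).
    """
    frame = _frame(data)
    _check_scores(frame)
    n = len(frame)
    rows = []
    for limb in LIMBS:
        s = frame[limb].to_numpy(dtype=int)
        n_aff = int((s > 0).sum())
        row = {
            "limb": limb,
            "n": n,
            "not_affected": n - n_aff,
            "not_affected_pct": percentage(n - n_aff, n, digits),
            "affected": n_aff,
            "affected_pct": percentage(n_aff, n, digits),
        }
        for k, label in CLASS_LABELS.items():
            nk = int((s == k).sum())
            row[label] = nk
            row[f"{label}_pct"] = percentage(nk, n_aff, digits)
        rows.append(row)
    return pd.DataFrame(rows)


def combination_prevalence(data, digits: int = 1) -> pd.DataFrame:
    """Counts and percentages of animals affected on all limbs of each
    combination A-G (and the unaffected complement)."""
    frame = _frame(data)
    _check_scores(frame)
    n = len(frame)
    affected = {limb: frame[limb].to_numpy(dtype=int) > 0 for limb in LIMBS}
    rows = []
    for name, limbs in COMBINATIONS.items():
        mask = np.ones(n, dtype=bool)
        for limb in limbs:
            mask &= affected[limb]
        n_aff = int(mask.sum())
        rows.append(
            {
                "combination": name,
                "limbs": "+".join(limbs),
                "n": n,
                "not_affected": n - n_aff,
                "not_affected_pct": percentage(n - n_aff, n, digits),
                "affected": n_aff,
                "affected_pct": percentage(n_aff, n, digits),
            }
        )
    return pd.DataFrame(rows)


def prevalence_by_factor(data, factor: str, digits: int = 2) -> pd.DataFrame:
    """Per-level, per-limb unaffected/affected percentages for ``sex`` or
    ``coat`` (text-style reports print 2 decimals)."""
    frame = _frame(data)
    if factor not in ("sex", "coat"):
        raise ValueError(f"unknown stratification factor {factor!r} (use 'sex' or 'coat')")
    _check_scores(frame)
    rows = []
    for level, sub in frame.groupby(factor, sort=True):
        n = len(sub)
        for limb in LIMBS:
            s = sub[limb].to_numpy(dtype=int)
            n_aff = int((s > 0).sum())
            rows.append(
                {
                    factor: level,
                    "limb": limb,
                    "n": n,
                    "not_affected": n - n_aff,
                    "not_affected_pct": percentage(n - n_aff, n, digits),
                    "affected": n_aff,
                    "affected_pct": percentage(n_aff, n, digits),
                }
            )
    return pd.DataFrame(rows)


def describe(data, by: str | None = None) -> pd.DataFrame:
    """Combined per-limb and combination table (study-table shape), or a
    stratified table when ``by`` is given."""
    if by is not None:
        return prevalence_by_factor(data, by)
    limb_part = score_distribution(data).rename(columns={"limb": "row"})
    comb_part = combination_prevalence(data).rename(columns={"combination": "row"})
    return pd.concat([limb_part, comb_part.drop(columns=["limbs"])], ignore_index=True)
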