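"""3C-qPCR interaction-frequency normalization and condition comparison.

Chromosome conformation capture quantified by TaqMan qPCR yields, per
restriction fragment and replicate, a template quantity from an
equal-input library. Within each replicate the quantity of the short-range
ligation control fragment (anchor ligated to an adjacent fragment) absorbs
cross-linking and ligation efficiency differences between samples, so the
relative interaction frequency of fragment *i* is

    IF_i = quantity_i / quantity_control * 100  (percent of control).

Profiles are summarized as mean +/- sd across replicates per condition, and
conditions are compared per fragment by a ratio of mean IFs with a
two-sided t-test on replicate IFs.
"""
from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ThreeCMeasurement",
    "InteractionProfile",
    "read_measurements",
    "normalize_interaction",
    "compare_conditions",
]

_COLUMNS = ["fragment_id", "distance_kb", "condition", "replicate", "quantity"]


@dataclass(frozen=True)
class ThreeCMeasurement:
    """One qPCR quantity for one restriction fragment in one replicate."""

    fragment_id: str
    distance_kb: float
    condition: str
    replicate: int
    quantity: float

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError("quantity must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclass(frozen=True)
class InteractionProfile:
    """Normalized interaction frequencies, per replicate and summarized.

    ``per_replicate`` columns: condition, replicate, fragment_id,
    distance_kb, interaction_pct. ``summary`` columns: condition,
    fragment_id, distance_kb, mean_pct, sd_pct, n_replicates. The control
    fragment is exactly 100% in every replicate by construction.
    """

    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    control_fragment: str


def read_measurements(path: str | os.PathLike) -> pd.DataFrame:
    """Read a measurement TSV with the canonical five columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    return df[_COLUMNS].copy()


def _as_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        df = measurements[_COLUMNS].copy()
    else:
        df = pd.DataFrame([vars(m) for m in measurements], columns=_COLUMNS)
    if len(df) == 0:
        raise ValueError("no measurements supplied")
    if (df["quantity"] < 0).any():
        raise ValueError("quantities must be >= 0")
    return df


def normalize_interaction(
    measurements, control_fragment: str
) -> InteractionProfile:
    """Normalize quantities to percent of the short-range control.

    Per (condition, replicate), every fragment quantity is divided by the
    control fragment's quantity and scaled to percent. A replicate without
    the control (or with control quantity 0) cannot be normalized and
    raises; a fragment missing from some replicate is simply absent from
    that replicate's rows (flagged with a warning). Multiplying all
    quantities of a replicate by c > 0 leaves its IF profile unchanged.
    """
    df = _as_frame(measurements)
    out_rows = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        ctrl = grp.loc[grp["fragment_id"] == control_fragment, "quantity"]
        if len(ctrl) == 0:
            raise ValueError(
                f"control fragment {control_fragment!r} missing in "
                f"condition {cond!r} replicate {rep}"
            )
        ctrl_q = float(ctrl.iloc[0])
        if ctrl_q <= 0:
            raise ValueError(
                f"control fragment quantity is 0 in condition {cond!r} "
                f"replicate {rep}; cannot normalize"
            )
        g = grp.copy()
        g["interaction_pct"] = g["quantity"] / ctrl_q * 100.0
        out_rows.append(g)
    per_rep = pd.concat(out_rows, ignore_index=True)[
        ["condition", "replicate", "fragment_id", "distance_kb", "interaction_pct"]
    ]
    # warn when a fragment is present in some but not all replicates
    counts = per_rep.groupby(["condition", "fragment_id"])["replicate"].nunique()
    n_reps = per_rep.groupby("condition")["replicate"].nunique()
    for (cond, frag), n in counts.items():
        if n < n_reps[cond]:
            warnings.warn(
                f"fragment {frag!r} missing from some replicates of "
                f"condition {cond!r}; summarized over {n} replicate(s)",
                stacklevel=2,
            )
    summary = (
        per_rep.groupby(["condition", "fragment_id"], sort=True)
        .agg(
            distance_kb=("distance_kb", "first"),
            mean_pct=("interaction_pct", "mean"),
            sd_pct=("interaction_pct", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
            n_replicates=("interaction_pct", "size"),
        )
        .reset_index()
    )
    return InteractionProfile(
        per_replicate=per_rep, summary=summary, control_fragment=control_fragment
    )


def compare_conditions(
    profile: InteractionProfile,
    condition_pair: tuple[str, str],
    fragments: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-fragment ratio of mean IFs between two conditions, with a t-test.

    ``condition_pair`` is (reference, test); the ratio is test/reference.
    Fewer than 3 replicates in either condition leaves the p-value NaN with
    a warning; zero-variance replicates in both groups make the t statistic
    degenerate, flagged in the ``note`` column. No claim is made beyond the
    statistic itself.
    """
    ref, test = condition_pair
    per_rep = profile.per_replicate
    for cond in condition_pair:
        if cond not in set(per_rep["condition"]):
            raise ValueError(f"condition {cond!r} not present in profile")
    frags = (
        sorted(set(fragments))
        if fragments is not None
        else sorted(set(per_rep["fragment_id"]))
    )
    rows = []
    for frag in frags:
        sel = per_rep["fragment_id"] == frag
        a = per_rep.loc[sel & (per_rep["condition"] == ref), "interaction_pct"].to_numpy()
        b = per_rep.loc[sel & (per_rep["condition"] == test), "interaction_pct"].to_numpy()
        dist = per_rep.loc[sel, "distance_kb"].iloc[0] if sel.any() else np.nan
        mean_ref = float(np.mean(a)) if len(a) else np.nan
        mean_test = float(np.mean(b)) if len(b) else np.nan
        ratio = mean_test / mean_ref if mean_ref else np.nan
        note = ""
        if len(a) < 3 or len(b) < 3:
            warnings.warn(
                f"fragment {frag!r}: fewer than 3 replicates; p-value omitted",
                stacklevel=2,
            )
            p = np.nan
            note = "ratio-only"
        else:
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                p = np.nan
                note = "degenerate-variance"
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    p = float(stats.ttest_ind(b, a, equal_var=True).pvalue)
        rows.append(
            {
                "fragment_id": frag,
                "distance_kb": dist,
                "mean_ref": mean_ref,
                "mean_test": mean_test,
                "ratio": ratio,
                "p_value": p,
                "note": note,
            }
        )
    return pd.DataFrame(rows)
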