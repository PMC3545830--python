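"""Floored fold-change and stage-specific up-regulation calls.

Fold changes between RPKM values are computed after clamping *both* operands
to a floor (default 0.1) so that ratios against values near zero stay
biologically interpretable: 0.02 vs 1.00 counts as a 10-fold increase, not a
50-fold one. A transcript is called *specifically up-regulated* at a stage
when its floored fold change versus every other stage reaches the minimum
fold (default 3); the call's magnitude is the conservative minimum of those
pairwise folds, binned into 3-10, 10-50 and >50. Because floored folds are
exactly reciprocal, at most one stage can ever be called per transcript.

A separate veraison call flags transcripts up-regulated at *both* veraison
stages (EL35 and EL36) relative to young (EL31) and ripe (EL38) berries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .schema import STAGE_CALL_NAMES, STAGES

FOLD_BIN_LABELS = ("3-10", "10-50", ">50")


def floored_fold_change(a, b, floor: float = 0.1):
    """``max(a, floor) / max(b, floor)``; accepts scalars or arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise DataError("RPKM values must be non-negative")
    out = np.maximum(a, floor) / np.maximum(b, floor)
    return float(out) if out.ndim == 0 else out


def fold_bin(fold, thresholds: tuple[float, float, float] = (3.0, 10.0, 50.0)):
    """Half-open magnitude bins [3,10), [10,50), [50,inf); "none" below 3."""
    fold = np.asarray(fold, dtype=float)
    lo, mid, hi = thresholds
    out = np.select(
        [fold >= hi, fold >= mid, fold >= lo],
        [FOLD_BIN_LABELS[2], FOLD_BIN_LABELS[1], FOLD_BIN_LABELS[0]],
        default="none",
    )
    return str(out) if out.ndim == 0 else out


def stage_specific_calls(
    rpkm: pd.DataFrame, min_fold: float = 3.0, floor: float = 0.1
) -> pd.DataFrame:
    """Classify each transcript's single-stage up-regulation.

    Parameters
    ----------
    rpkm
        transcripts x 4 stages RPKM matrix (stage columns in EL order).

    Returns
    -------
    DataFrame with columns transcript_id, call (young / early_veraison /
    late_veraison / ripe / none), min_fold_vs_others and bin. For uncalled
    transcripts ``min_fold_vs_others`` reports the best (largest) minimum
    fold over the four stage hypotheses, necessarily below ``min_fold``.
    """
    stages = list(rpkm.columns)
    if len(stages) != 4:
        raise DataError(f"expected 4 stage columns, got {len(stages)}")
    F = np.maximum(rpkm.to_numpy(dtype=float), floor)
    if (rpkm.to_numpy() < 0).any():
        raise DataError("RPKM values must be non-negative")

    # min over the other three stages of fold(s, other), for each stage s
    minfold = np.empty((len(rpkm), 4))
    for j in range(4):
        others = [k for k in range(4) if k != j]
        minfold[:, j] = (F[:, [j]] / F[:, others]).min(axis=1)

    best_stage = minfold.argmax(axis=1)
    best = minfold[np.arange(len(rpkm)), best_stage]
    called = best >= min_fold
    calls = np.where(
        called,
        np.array([STAGE_CALL_NAMES[s] for s in stages], dtype=object)[best_stage],
        "none",
    )
    return pd.DataFrame(
        {
            "transcript_id": rpkm.index,
            "call": calls,
            "min_fold_vs_others": best,
            "bin": np.where(called, fold_bin(best), "none"),
        }
    ).reset_index(drop=True)


def veraison_calls(
    rpkm: pd.DataFrame, min_fold: float = 3.0, floor: float = 0.1
) -> pd.DataFrame:
    """Flag transcripts up-regulated at both veraison stages.

    Requires floored folds EL35/EL31, EL35/EL38, EL36/EL31 and EL36/EL38 to
    all reach ``min_fold`` (inclusive); the magnitude is their minimum.
    """
    for stage in STAGES:
        if stage not in rpkm.columns:
            raise DataError(f"missing stage column {stage!r}")
    folds = np.column_stack(
        [
            floored_fold_change(rpkm["EL35"], rpkm["EL31"], floor),
            floored_fold_change(rpkm["EL35"], rpkm["EL38"], floor),
            floored_fold_change(rpkm["EL36"], rpkm["EL31"], floor),
            floored_fold_change(rpkm["EL36"], rpkm["EL38"], floor),
        ]
    )
    minfold = folds.min(axis=1)
    flagged = minfold >= min_fold
    return pd.DataFrame(
        {
            "transcript_id": rpkm.index,
            "flagged": flagged,
            "min_fold": minfold,
            "bin": np.where(flagged, fold_bin(minfold), "none"),
        }
    ).reset_index(drop=True)


def call_summary(calls: pd.DataFrame, veraison: pd.DataFrame) -> pd.DataFrame:
    """Counts of called transcripts per class and fold bin (plus totals)."""
    classes = list(STAGE_CALL_NAMES.values())
    table = pd.DataFrame(0, index=list(FOLD_BIN_LABELS), columns=classes + ["veraison"])
    called = calls[calls["call"] != "none"]
    for (cls, b), n in called.groupby(["call", "bin"]).size().items():
        table.loc[b, cls] = n
    for b, n in veraison[veraison["flagged"]].groupby("bin").size().items():
        table.loc[b, "veraison"] = n
    table.loc["total"] = table.sum()
    table.index.name = "fold_bin"
    return table
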