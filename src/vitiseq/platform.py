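"""Cross-platform comparison of RNA-Seq RPKM against probeset intensities.

The comparison pairs each transcript with one microarray probeset and asks
two questions: do the two platforms rank transcripts similarly *within* a
stage (global Spearman correlation per stage, averaged over the four
stages), and do they agree on each transcript's developmental *pattern*
(per-transcript Spearman over the 4-stage vectors, binned into a
histogram)?

Pairing rules: cross-hybridising probesets (suffix classes _s, _x, _a) and
probesets whose transcript match has a non-zero e-value are dropped; when
several probesets match one transcript, the one whose 4-stage pattern
correlates best with the transcript's log RPKM pattern is kept. Intensities
are on the log2 scale; RNA-Seq expression enters as log2(RPKM + 1).
Pairs below the expression floors — probeset mean intensity under the 25th
percentile (recomputed from the data at hand) or mean RPKM under 0.5 — are
excluded from the correlation sets. Spearman rather than Pearson throughout,
because the intensity-to-abundance response of an array is monotone but not
linear; ties get average ranks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import DataError, InsufficientDataError
from .schema import STAGES

logger = logging.getLogger(__name__)

CROSSHYB_SUFFIXES = ("_s", "_x", "_a")

#: Default histogram thresholds, descending; bins are half-open below each
#: threshold with the top bin closed at +1.
DEFAULT_THRESHOLDS = (0.9, 0.6, 0.3, 0.0, -0.3, -0.6, -0.9)


def _pattern_rho(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman over two 4-vectors; NaN when either is constant."""
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(spearmanr(a, b).statistic)


def build_matched_pairs(
    probesets: pd.DataFrame,
    rpkm: pd.DataFrame,
    *,
    log_transform_intensities: bool = False,
) -> pd.DataFrame:
    """Filter probesets and pair each transcript with its best probeset.

    Parameters
    ----------
    probesets
        Columns probeset_id, suffix_class, transcript_id, evalue and one
        intensity column per stage (log2 scale unless
        ``log_transform_intensities``).
    rpkm
        transcripts x stages RPKM matrix.

    Returns
    -------
    One row per retained transcript: transcript_id, probeset_id,
    ``int_<stage>`` log2 intensities, ``lrpkm_<stage>`` log2(RPKM+1) values
    and mean_rpkm.
    """
    stages = list(rpkm.columns)
    table = probesets.copy()
    table = table.loc[~table["suffix_class"].isin(CROSSHYB_SUFFIXES)]
    table = table.loc[table["evalue"] == 0]

    known = table["transcript_id"].isin(rpkm.index)
    if (~known).any():
        logger.warning(
            "dropping %d probeset(s) referencing unknown transcripts",
            int((~known).sum()),
        )
        table = table.loc[known]
    if table.empty:
        return pd.DataFrame(
            columns=["transcript_id", "probeset_id"]
            + [f"int_{s}" for s in stages]
            + [f"lrpkm_{s}" for s in stages]
            + ["mean_rpkm"]
        )

    intensities = table[stages].to_numpy(dtype=float)
    if log_transform_intensities:
        if (intensities <= 0).any():
            raise DataError("linear intensities must be positive to log2-transform")
        intensities = np.log2(intensities)

    lrpkm = np.log2(rpkm.loc[table["transcript_id"], stages].to_numpy(dtype=float) + 1.0)
    # "most closely correlating probeset": pattern Spearman vs the RNA-Seq side
    rho = np.array([_pattern_rho(i, l) for i, l in zip(intensities, lrpkm)])
    rho_rank = np.where(np.isnan(rho), -np.inf, rho)

    work = pd.DataFrame(
        {
            "transcript_id": table["transcript_id"].to_numpy(),
            "probeset_id": table["probeset_id"].to_numpy(),
            "_rho": rho_rank,
        }
    )
    for j, s in enumerate(stages):
        work[f"int_{s}"] = intensities[:, j]
        work[f"lrpkm_{s}"] = lrpkm[:, j]
    work["mean_rpkm"] = rpkm.loc[table["transcript_id"], stages].mean(axis=1).to_numpy()

    work = work.sort_values(
        ["transcript_id", "_rho", "probeset_id"],
        ascending=[True, False, True],
        kind="stable",
    )
    best = work.drop_duplicates("transcript_id", keep="first").drop(columns="_rho")
    return best.reset_index(drop=True)


def apply_expression_floors(
    pairs: pd.DataFrame,
    *,
    intensity_percentile: float = 25.0,
    rpkm_floor: float = 0.5,
    per_stage: bool = False,
) -> pd.DataFrame:
    """Flag pairs as expressed on each platform; both flags must hold.

    The intensity threshold is the ``intensity_percentile``-th percentile of
    the per-probeset mean intensities, recomputed from the supplied pairs
    (the published value of 4.0 is specific to one array set and is not
    hard-coded). Thresholds are inclusive (>=). With ``per_stage`` the flags
    require every stage to clear its own per-stage percentile / the RPKM
    floor, instead of the per-transcript means.
    """
    stages = [c.removeprefix("int_") for c in pairs.columns if c.startswith("int_")]
    out = pairs.copy()
    intensity = out[[f"int_{s}" for s in stages]].to_numpy(dtype=float)
    if per_stage:
        thresholds = np.percentile(intensity, intensity_percentile, axis=0)
        out["expressed_intensity"] = (intensity >= thresholds).all(axis=1)
        rpkm = 2.0 ** out[[f"lrpkm_{s}" for s in stages]].to_numpy(dtype=float) - 1.0
        out["expressed_rnaseq"] = (rpkm >= rpkm_floor).all(axis=1)
    else:
        mean_int = intensity.mean(axis=1)
        threshold = np.percentile(mean_int, intensity_percentile)
        out["expressed_intensity"] = mean_int >= threshold
        out["expressed_rnaseq"] = out["mean_rpkm"] >= rpkm_floor
    out["retained"] = out["expressed_intensity"] & out["expressed_rnaseq"]
    return out


def global_stage_correlation(pairs: pd.DataFrame) -> dict[str, float]:
    """Per-stage Spearman between intensity and log2(RPKM+1), plus the mean.

    Operates on retained pairs when a ``retained`` column is present.
    """
    if "retained" in pairs.columns:
        pairs = pairs.loc[pairs["retained"]]
    stages = [c.removeprefix("int_") for c in pairs.columns if c.startswith("int_")]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"need >= 3 retained pairs for a rank correlation, got {len(pairs)}"
        )
    out: dict[str, float] = {}
    for s in stages:
        out[s] = float(spearmanr(pairs[f"int_{s}"], pairs[f"lrpkm_{s}"]).statistic)
    out["mean"] = float(np.mean([out[s] for s in stages]))
    return out


def pattern_correlation_histogram(
    pairs: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> tuple[pd.Series, pd.Series]:
    """Per-transcript pattern Spearman and its threshold-binned histogram.

    Returns
    -------
    (rho, counts)
        ``rho``: Spearman per transcript (NaN when either platform's
        4-stage vector is constant). ``counts``: transcripts per bin, from
        "rho >= 0.9" down to "rho < -0.9", with a trailing "undefined" bin
        for the NaNs.
    """
    if "retained" in pairs.columns:
        pairs = pairs.loc[pairs["retained"]]
    stages = [c.removeprefix("int_") for c in pairs.columns if c.startswith("int_")]
    intensity = pairs[[f"int_{s}" for s in stages]].to_numpy(dtype=float)
    lrpkm = pairs[[f"lrpkm_{s}" for s in stages]].to_numpy(dtype=float)
    rho = pd.Series(
        [_pattern_rho(i, l) for i, l in zip(intensity, lrpkm)],
        index=pairs["transcript_id"].to_numpy(),
        name="pattern_rho",
    )

    edges = sorted(thresholds, reverse=True)
    labels = [f"rho >= {edges[0]:g}"]
    labels += [f"{lo:g} <= rho < {hi:g}" for hi, lo in zip(edges, edges[1:])]
    labels += [f"rho < {edges[-1]:g}", "undefined"]
    counts = pd.Series(0, index=labels, name="transcripts")
    values = rho.to_numpy()
    defined = ~np.isnan(values)
    counts["undefined"] = int((~defined).sum())
    v = values[defined]
    counts[labels[0]] = int((v >= edges[0]).sum())
    for hi, lo, label in zip(edges, edges[1:], labels[1:]):
        counts[label] = int(((v >= lo) & (v < hi)).sum())
    counts[labels[-2]] = int((v < edges[-1]).sum())
    return rho, counts
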