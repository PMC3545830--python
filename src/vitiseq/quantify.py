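"""Read filtering, proportional allocation, RPKM and detection calls.

The counting model is transcript-space: each read carries zero or more
alignment candidates (read <-> transcript hits with an identity and an
aligned-fraction attribute), and quantification proceeds in two passes.
Pass one counts reads with exactly one accepted candidate as *unique* to
their transcript. Pass two splits every multi-candidate read across its
candidate transcripts with weights proportional to the unique counts frozen
in pass one (equal split when all candidates have zero unique reads). The
split is single-pass, not an EM iteration: unique counts are never updated
from allocated mass. Allocation conserves reads exactly — per stage the
allocated total equals the number of reads with at least one accepted
candidate — which also means the fractional allocated total and the integer
read total in the RPKM denominator coincide.

RPKM follows the standard definition::

    rpkm(t) = allocated_reads(t) / ((length(t) / 1e3) * (total_mapped / 1e6))

A transcript is *detected* at a stage when its RPKM reaches 0.5 or, below
that, when at least five uniquely matched reads support it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError, DataError
from .schema import STAGES


def filter_reads(
    reads: pd.DataFrame, min_length: int = 60, max_ambiguous: int = 2
) -> pd.DataFrame:
    """Keep reads with length >= ``min_length`` and at most ``max_ambiguous``
    ambiguous characters. Row order is preserved."""
    if min_length <= 0:
        raise ConfigurationError(f"min_length must be positive, got {min_length}")
    if max_ambiguous < 0:
        raise ConfigurationError(f"max_ambiguous must be >= 0, got {max_ambiguous}")
    keep = (reads["length_after_trim"] >= min_length) & (
        reads["ambiguous_count"] <= max_ambiguous
    )
    return reads.loc[keep]


def filter_alignments(
    candidates: pd.DataFrame,
    known_read_ids: pd.Series | pd.Index | None = None,
    min_identity: float = 0.98,
    min_aligned_fraction: float = 0.5,
) -> pd.DataFrame:
    """Accept candidates with identity and aligned fraction strictly above
    their thresholds.

    Both inequalities are strict ("greater than 98% identity", "greater than
    50% of a read"). When ``known_read_ids`` is given, a candidate naming a
    read outside that set raises :class:`ConsistencyError`.
    """
    if known_read_ids is not None:
        known = pd.Index(known_read_ids)
        unknown = candidates.loc[~candidates["read_id"].isin(known), "read_id"]
        if len(unknown):
            raise ConsistencyError(
                f"{unknown.nunique()} candidate read(s) not in the read table "
                f"(e.g. {unknown.iloc[0]!r})"
            )
    keep = (candidates["percent_identity"] > min_identity) & (
        candidates["aligned_fraction"] > min_aligned_fraction
    )
    return candidates.loc[keep]


def allocate_reads(accepted: pd.DataFrame, stage: str | None = None) -> pd.DataFrame:
    """Two-pass unique counting and proportional allocation.

    Parameters
    ----------
    accepted
        Accepted candidates (columns read_id, transcript_id), all from one
        stage.

    Returns
    -------
    DataFrame with columns transcript_id, unique_reads, allocated_reads
    (plus a stage column when ``stage`` is given), one row per transcript
    with at least one accepted candidate.
    """
    if accepted.empty:
        out = pd.DataFrame(
            {"transcript_id": [], "unique_reads": [], "allocated_reads": []}
        )
        if stage is not None:
            out["stage"] = []
        return out

    n_candidates = accepted.groupby("read_id")["transcript_id"].transform("size")
    uni = accepted.loc[n_candidates == 1]
    multi = accepted.loc[n_candidates > 1].copy()

    unique_counts = uni.groupby("transcript_id").size().astype(float)

    if multi.empty:
        extra = pd.Series(dtype=float)
    else:
        multi["w"] = multi["transcript_id"].map(unique_counts).fillna(0.0)
        grp = multi.groupby("read_id")["w"]
        total_w = grp.transform("sum")
        fanout = grp.transform("size")
        # 0/0 tie rule: equal split keeps conservation exact
        multi["share"] = np.where(total_w > 0, multi["w"] / total_w, 1.0 / fanout)
        extra = multi.groupby("transcript_id")["share"].sum()

    transcripts = unique_counts.index.union(extra.index)
    out = pd.DataFrame(
        {
            "transcript_id": transcripts,
            "unique_reads": unique_counts.reindex(transcripts, fill_value=0.0)
            .astype(int)
            .to_numpy(),
            "allocated_reads": (
                unique_counts.reindex(transcripts, fill_value=0.0)
                + extra.reindex(transcripts, fill_value=0.0)
            ).to_numpy(),
        }
    ).reset_index(drop=True)
    if stage is not None:
        out["stage"] = stage
    return out


def compute_rpkm(
    allocated: pd.Series, lengths: pd.Series, total_mapped: float
) -> pd.Series:
    """RPKM per transcript from allocated counts and transcript lengths."""
    if total_mapped <= 0:
        raise DataError(f"total_mapped must be positive, got {total_mapped}")
    missing = allocated.index.difference(lengths.index)
    if len(missing):
        raise ConsistencyError(
            f"no length for {len(missing)} counted transcript(s), "
            f"e.g. {missing[0]!r}"
        )
    L = lengths.reindex(allocated.index).astype(float)
    return allocated / ((L / 1e3) * (total_mapped / 1e6))


def expected_coverage(
    rpkm: float, length: float, read_length: float, mapped_millions: float
) -> float:
    """Mean per-base coverage implied by an RPKM value.

    ``coverage = rpkm * mapped_millions * read_length / 1000`` — e.g. RPKM
    0.5 with 100 bp reads and 40 million mapped reads is 20 reads on a 1 kb
    transcript, a mean coverage of 2. The transcript length cancels out of
    the formula; it is validated but not used.
    """
    if rpkm < 0:
        raise DataError(f"rpkm must be >= 0, got {rpkm}")
    if length <= 0 or read_length <= 0 or mapped_millions <= 0:
        raise DataError("length, read_length and mapped_millions must be positive")
    return rpkm * mapped_millions * read_length / 1000.0


def detect(
    rpkm: pd.DataFrame,
    unique_reads: pd.DataFrame,
    rpkm_floor: float = 0.5,
    min_unique: int = 5,
) -> pd.DataFrame:
    """Boolean detection matrix: RPKM >= floor OR unique reads >= minimum."""
    if not rpkm.index.equals(unique_reads.index) or list(rpkm.columns) != list(
        unique_reads.columns
    ):
        raise ConsistencyError("rpkm and unique_reads matrices are not aligned")
    return (rpkm >= rpkm_floor) | (unique_reads >= min_unique)


@dataclass
class ExpressionMatrix:
    """Per-transcript, per-stage RPKM with supporting unique-read counts.

    ``total_mapped`` holds the per-stage allocated totals entering the RPKM
    denominator.
    """

    rpkm: pd.DataFrame
    unique_reads: pd.DataFrame
    total_mapped: pd.Series

    def __post_init__(self) -> None:
        if not self.rpkm.index.equals(self.unique_reads.index):
            raise ConsistencyError("rpkm/unique_reads transcript indexes differ")
        if list(self.rpkm.columns) != list(self.unique_reads.columns):
            raise ConsistencyError("rpkm/unique_reads stage columns differ")

    @property
    def stages(self) -> list[str]:
        return list(self.rpkm.columns)

    def detected(self, rpkm_floor: float = 0.5, min_unique: int = 5) -> pd.DataFrame:
        return detect(self.rpkm, self.unique_reads, rpkm_floor, min_unique)

    def to_frame(self) -> pd.DataFrame:
        """Flat table: transcript_id, RPKM per stage, unique_<stage> counts."""
        out = self.rpkm.copy()
        for stage in self.stages:
            out[f"unique_{stage}"] = self.unique_reads[stage]
        out.insert(0, "transcript_id", out.index)
        return out.reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        stages = [c for c in frame.columns if not c.startswith("unique_") and c != "transcript_id"]
        idx = frame["transcript_id"]
        rpkm = frame[stages].set_axis(idx, axis=0)
        uniq = frame[[f"unique_{s}" for s in stages]].set_axis(idx, axis=0)
        uniq.columns = stages
        totals = pd.Series({s: np.nan for s in stages})
        return cls(rpkm=rpkm, unique_reads=uniq, total_mapped=totals)


def build_expression_matrix(
    reads: pd.DataFrame,
    candidates: pd.DataFrame,
    lengths: pd.Series,
    stages: tuple[str, ...] = STAGES,
    *,
    min_length: int = 60,
    max_ambiguous: int = 2,
    min_identity: float = 0.98,
    min_aligned_fraction: float = 0.5,
) -> ExpressionMatrix:
    """Run the full counting stage: filters -> allocation -> RPKM, per stage.

    Candidates belonging to reads removed by the read filter are dropped
    before the alignment filter (they were never eligible for counting).
    """
    kept_reads = filter_reads(reads, min_length, max_ambiguous)
    rpkm_cols: dict[str, pd.Series] = {}
    uniq_cols: dict[str, pd.Series] = {}
    totals: dict[str, float] = {}
    all_t = lengths.index
    for stage in stages:
        stage_ids = kept_reads.loc[kept_reads["stage"] == stage, "read_id"]
        cands = candidates.loc[candidates["read_id"].isin(stage_ids)]
        accepted = filter_alignments(
            cands, stage_ids, min_identity, min_aligned_fraction
        )
        counts = allocate_reads(accepted, stage)
        allocated = pd.Series(
            counts["allocated_reads"].to_numpy(), index=counts["transcript_id"]
        ).reindex(all_t, fill_value=0.0)
        unique = (
            pd.Series(counts["unique_reads"].to_numpy(), index=counts["transcript_id"])
            .reindex(all_t, fill_value=0)
            .astype(int)
        )
        total = float(allocated.sum())
        totals[stage] = total
        rpkm_cols[stage] = (
            compute_rpkm(allocated, lengths, total)
            if total > 0
            else allocated * 0.0
        )
        uniq_cols[stage] = unique
    return ExpressionMatrix(
        rpkm=pd.DataFrame(rpkm_cols),
        unique_reads=pd.DataFrame(uniq_cols),
        total_mapped=pd.Series(totals),
    )


#: Default abundance bin edges mirroring the published per-stage summary.
ABUNDANCE_BIN_LABELS = (
    "RPKM > 200",
    "RPKM 10-200",
    "RPKM 0.5-10",
    "RPKM < 0.5 (unique >= 5)",
)


def abundance_bins(
    matrix: ExpressionMatrix,
    *,
    high: float = 200.0,
    mid: float = 10.0,
    floor: float = 0.5,
    min_unique: int = 5,
) -> pd.DataFrame:
    """Per-stage detected-transcript counts in four abundance bins.

    Boundary rules: ">200" is strict, "10-200" is the closed interval
    [10, 200], "0.5-10" is [0.5, 10), and the trace bin holds transcripts
    below the RPKM floor rescued by their unique-read support. Every
    detected transcript falls in exactly one bin; the ``total_detected`` row
    is the column sum.
    """
    r, u = matrix.rpkm, matrix.unique_reads
    rows = {
        ABUNDANCE_BIN_LABELS[0]: (r > high).sum(),
        ABUNDANCE_BIN_LABELS[1]: ((r >= mid) & (r <= high)).sum(),
        ABUNDANCE_BIN_LABELS[2]: ((r >= floor) & (r < mid)).sum(),
        ABUNDANCE_BIN_LABELS[3]: ((r < floor) & (u >= min_unique)).sum(),
    }
    table = pd.DataFrame(rows).T
    table.loc["total_detected"] = table.sum()
    table.index.name = "bin"
    return table.astype(int)
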