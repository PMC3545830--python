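"""Shared domain types and the four-stage study layout.

The pipeline is organised around four berry developmental stages on the
modified Eichhorn-Lorenz scale: E-L 31 (young green berries), E-L 35
(early veraison), E-L 36 (late veraison) and E-L 38 (harvest-ripe).
Every expression table in the package carries these four stages as columns,
in this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Stage labels, ordered by developmental time.
STAGES: tuple[str, ...] = ("EL31", "EL35", "EL36", "EL38")

#: Human-readable call names for single-stage up-regulation, keyed by stage.
STAGE_CALL_NAMES: dict[str, str] = {
    "EL31": "young",
    "EL35": "early_veraison",
    "EL36": "late_veraison",
    "EL38": "ripe",
}


@dataclass(frozen=True)
class TranscriptRecord:
    """One catalog entry: a reference mRNA with its annotation.

    ``archetype`` is the planted ground-truth expression shape ("flat" for
    background transcripts); it anchors parameter-recovery tests and is never
    consumed by the analysis modules themselves.
    """

    transcript_id: str
    length: int
    go_terms: frozenset[str] = field(default_factory=frozenset)
    probeset_id: str | None = None
    archetype: str = "flat"

    def __post_init__(self) -> None:
        if self.length < 100:
            raise ValueError(
                f"transcript {self.transcript_id}: length {self.length} < 100"
            )


@dataclass
class SyntheticTruth:
    """Ground truth attached to a synthetic catalog.

    Attributes
    ----------
    true_rpkm
        transcripts x 4 stages matrix of the expression levels the read
        generator samples from (RPKM scale).
    archetype_assignments
        transcript_id -> planted shape label (includes "flat").
    enriched_terms
        archetype -> GO terms deterministically planted as enriched in that
        archetype's transcripts.
    term_groups
        GO term -> representative biological-process group, the mapping the
        enrichment summariser aggregates over.
    platform_rho
        target Spearman correlation between probeset intensity and
        log2(RPKM + 1) used when calibrating probeset noise.
    """

    true_rpkm: pd.DataFrame
    archetype_assignments: pd.Series
    enriched_terms: dict[str, list[str]]
    term_groups: dict[str, str]
    platform_rho: float = 0.7


def catalog_to_frame(catalog: list[TranscriptRecord]) -> pd.DataFrame:
    """Tabular view of a catalog (GO terms ';'-joined, sorted)."""
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in catalog],
            "length": [r.length for r in catalog],
            "archetype": [r.archetype for r in catalog],
            "probeset_id": [r.probeset_id or "" for r in catalog],
            "go_terms": [";".join(sorted(r.go_terms)) for r in catalog],
        }
    )
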