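"""Synthetic four-stage berry transcriptome with known ground truth.

Everything the downstream pipeline consumes can be generated here: a
transcript catalog with GO annotation and probeset links, per-stage read
records and alignment candidates, and microarray-style probeset intensities.
Ten named expression archetypes (the developmental shapes a k-means run on
real berry data resolves: young-specific, veraison-up, ripe-specific,
decreasing, ...) are planted at configurable fractions; the remainder of the
catalog is "flat" background with at most mild stage-to-stage wobble.

Reads are drawn per stage with expected counts proportional to
``true_rpkm x length``, so the quantification module should recover the
planted matrix up to sampling noise. A configurable fraction of reads is
multi-mapped within randomly-formed homology groups (mimicking large
near-identical gene families such as the stilbene synthases), a fraction
fails the read-QC filters, and a fraction carries alignment candidates below
the identity/coverage acceptance thresholds, so every filter downstream has
work to do.

All operations are deterministic given their seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .schema import STAGES, SyntheticTruth, TranscriptRecord

#: The ten planted expression shapes as raw 4-stage amplitude vectors
#: (EL31, EL35, EL36, EL38). Amplitudes are free parameters; shapes are
#: chosen so their scale-centered forms are mutually well separated.
ARCHETYPE_TEMPLATES: dict[str, tuple[float, float, float, float]] = {
    "young_specific": (10.0, 1.0, 1.0, 1.0),
    "early_veraison_specific": (1.0, 10.0, 1.0, 1.0),
    "late_veraison_specific": (1.0, 1.0, 10.0, 1.0),
    "ripe_specific": (1.0, 1.0, 1.0, 10.0),
    "low_at_veraison": (8.0, 1.0, 1.0, 8.0),
    "veraison_up": (1.0, 8.0, 8.0, 1.0),
    "veraison_onwards": (1.0, 6.0, 8.0, 8.0),
    "increasing": (1.0, 2.0, 4.0, 8.0),
    "decreasing": (8.0, 4.0, 2.0, 1.0),
    "high_young_declining": (10.0, 9.0, 6.0, 1.0),
}

#: Default planted fractions, proportioned after the cluster sizes a k-means
#: run on the real four-stage data yields (the two young-berry shapes
#: dominate); ~62% of the catalog remains flat background.
DEFAULT_ARCHETYPE_FRACTIONS: dict[str, float] = {
    "young_specific": 0.107,
    "early_veraison_specific": 0.015,
    "late_veraison_specific": 0.009,
    "ripe_specific": 0.048,
    "low_at_veraison": 0.038,
    "veraison_up": 0.028,
    "veraison_onwards": 0.027,
    "increasing": 0.037,
    "decreasing": 0.052,
    "high_young_declining": 0.017,
}


def generate_catalog(
    n_transcripts: int,
    n_go_terms: int = 200,
    archetype_fractions: dict[str, float] | None = None,
    seed: int = 0,
    *,
    probeset_fraction: float = 0.6,
    platform_rho: float = 0.7,
    terms_per_archetype: int = 2,
    planted_term_rate: float = 0.5,
    background_term_rate: float = 0.05,
) -> tuple[list[TranscriptRecord], SyntheticTruth]:
    """Build a transcript catalog with planted archetypes and GO annotation.

    Parameters
    ----------
    n_transcripts
        Catalog size (>= 50).
    n_go_terms
        Total GO vocabulary size; the first ``10 * terms_per_archetype``
        terms are reserved for planted enrichment.
    archetype_fractions
        archetype -> fraction of the catalog planted with that shape.
        Fractions must sum to <= 1; the remainder is "flat". ``None`` uses
        :data:`DEFAULT_ARCHETYPE_FRACTIONS`; pass ``{}`` for an all-flat
        catalog.
    probeset_fraction
        Fraction of transcripts linked to a microarray probeset.
    planted_term_rate
        Within-archetype annotation rate for planted terms. The planting is
        deterministic per term: ``max(5, round(rate * size))`` members
        (capped at the archetype size), which guarantees the >= 5-transcript
        invariant whenever the archetype holds >= 5 transcripts.
    background_term_rate
        Bernoulli annotation rate for every term outside its planted
        archetype.

    Returns
    -------
    (catalog, truth)
        The record list and the attached :class:`~vitiseq.schema.SyntheticTruth`.
    """
    if n_transcripts < 50:
        raise ConfigurationError(f"n_transcripts must be >= 50, got {n_transcripts}")
    fractions = (
        DEFAULT_ARCHETYPE_FRACTIONS if archetype_fractions is None else archetype_fractions
    )
    unknown = set(fractions) - set(ARCHETYPE_TEMPLATES)
    if unknown:
        raise ConfigurationError(f"unknown archetypes: {sorted(unknown)}")
    if any(f < 0 for f in fractions.values()):
        raise ConfigurationError("archetype fractions must be non-negative")
    if sum(fractions.values()) > 1.0 + 1e-9:
        raise ConfigurationError(
            f"archetype fractions sum to {sum(fractions.values()):.4f} > 1"
        )

    rng = np.random.default_rng(seed)
    n_archetypes = len(ARCHETYPE_TEMPLATES)
    if n_go_terms < n_archetypes * terms_per_archetype:
        raise ConfigurationError(
            "n_go_terms must cover the planted vocabulary "
            f"({n_archetypes * terms_per_archetype} terms)"
        )

    # archetype labels: exact counts per fraction, then shuffled positions
    labels = np.array(["flat"] * n_transcripts, dtype=object)
    order = rng.permutation(n_transcripts)
    cursor = 0
    for name in sorted(fractions):
        count = int(round(fractions[name] * n_transcripts))
        labels[order[cursor : cursor + count]] = name
        cursor += count

    transcript_ids = np.array([f"VIT_{i:06d}" for i in range(n_transcripts)])
    lengths = rng.integers(300, 3501, size=n_transcripts)

    # expression: per-transcript abundance scale x mean-1 shape vector
    base = rng.lognormal(mean=1.5, sigma=1.2, size=n_transcripts)
    shapes = np.empty((n_transcripts, 4))
    flat_mask = labels == "flat"
    shapes[flat_mask] = rng.uniform(0.8, 1.25, size=(int(flat_mask.sum()), 4))
    for name, template in ARCHETYPE_TEMPLATES.items():
        mask = labels == name
        if mask.any():
            vec = np.asarray(template, dtype=float)
            shapes[mask] = vec / vec.mean()
    true_rpkm = pd.DataFrame(
        base[:, None] * shapes, index=transcript_ids, columns=list(STAGES)
    )

    # GO annotation: background Bernoulli + deterministic planting
    terms = [f"GO:{i:07d}" for i in range(1, n_go_terms + 1)]
    annotated = rng.random((n_transcripts, n_go_terms)) < background_term_rate
    enriched_terms: dict[str, list[str]] = {}
    term_groups: dict[str, str] = {}
    planted_cursor = 0
    for name in ARCHETYPE_TEMPLATES:
        planted = terms[planted_cursor : planted_cursor + terms_per_archetype]
        planted_cursor += terms_per_archetype
        enriched_terms[name] = planted
        for term in planted:
            term_groups[term] = f"{name}_process"
        members = np.flatnonzero(labels == name)
        if members.size == 0:
            continue
        n_plant = min(members.size, max(5, int(round(planted_term_rate * members.size))))
        for term in planted:
            chosen = rng.choice(members, size=n_plant, replace=False)
            annotated[chosen, terms.index(term)] = True
    for j in range(planted_cursor, n_go_terms):
        term_groups[terms[j]] = f"process_{(j - planted_cursor) // 5 + 1:03d}"

    has_probeset = rng.random(n_transcripts) < probeset_fraction

    term_arr = np.array(terms, dtype=object)
    catalog = [
        TranscriptRecord(
            transcript_id=transcript_ids[i],
            length=int(lengths[i]),
            go_terms=frozenset(term_arr[annotated[i]]),
            probeset_id=f"ps{i:06d}" if has_probeset[i] else None,
            archetype=labels[i],
        )
        for i in range(n_transcripts)
    ]
    truth = SyntheticTruth(
        true_rpkm=true_rpkm,
        archetype_assignments=pd.Series(labels, index=transcript_ids, name="archetype"),
        enriched_terms=enriched_terms,
        term_groups=term_groups,
        platform_rho=platform_rho,
    )
    return catalog, truth


def _homology_groups(n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Partition transcript indices into random groups of size 2-4.

    Models grouped multi-mapping among near-identical gene-family members;
    a trailing singleton is merged into the previous group.
    """
    perm = rng.permutation(n)
    groups: list[np.ndarray] = []
    i = 0
    while i < n:
        size = int(rng.integers(2, 5))
        chunk = perm[i : i + size]
        if chunk.size == 1 and groups:
            groups[-1] = np.concatenate([groups[-1], chunk])
        else:
            groups.append(chunk)
        i += size
    return groups


def generate_alignments(
    truth: SyntheticTruth,
    catalog: list[TranscriptRecord],
    reads_per_stage: int = 50_000,
    multimap_rate: float = 0.15,
    qc_fail_rate: float = 0.02,
    seed: int = 0,
    *,
    align_fail_rate: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw stage-structured reads and their alignment candidates.

    Read counts per transcript are multinomial with probabilities
    proportional to ``true_rpkm x length`` (an RPKM-faithful sampling model).
    A ``qc_fail_rate`` fraction of reads violates the length or ambiguity
    filter; an ``align_fail_rate`` fraction carries a candidate below the
    identity or aligned-fraction threshold; a ``multimap_rate`` fraction
    receives one passing candidate per member of its source transcript's
    homology group (2-4 candidates).

    Returns
    -------
    (reads, candidates)
        ``reads`` columns: read_id, stage, length_after_trim, ambiguous_count.
        ``candidates`` columns: read_id, transcript_id, percent_identity,
        aligned_fraction. Each (read_id, transcript_id) pair is unique.
    """
    if not catalog:
        raise DataError("catalog is empty")
    for name, rate in (
        ("multimap_rate", multimap_rate),
        ("qc_fail_rate", qc_fail_rate),
        ("align_fail_rate", align_fail_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {rate}")

    rng = np.random.default_rng(seed)
    tids = np.array([r.transcript_id for r in catalog])
    lengths = np.array([r.length for r in catalog], dtype=float)
    rpkm = truth.true_rpkm.reindex(tids)
    n = len(tids)
    groups = _homology_groups(n, rng)
    group_of = np.empty(n, dtype=object)
    for g in groups:
        for idx in g:
            group_of[idx] = g

    read_rows: list[pd.DataFrame] = []
    cand_rows: list[pd.DataFrame] = []
    for stage in STAGES:
        w = rpkm[stage].to_numpy() * lengths
        total = w.sum()
        if total <= 0:
            raise DataError(f"stage {stage}: all true RPKM are zero")
        counts = rng.multinomial(reads_per_stage, w / total)
        source = np.repeat(np.arange(n), counts)
        m = source.size
        read_ids = np.array([f"{stage}_r{i:07d}" for i in range(m)])

        # read QC attributes
        length_after_trim = rng.integers(80, 97, size=m)
        ambiguous = rng.choice([0, 1, 2], size=m, p=[0.90, 0.08, 0.02])
        qc_fail = rng.random(m) < qc_fail_rate
        short_fail = qc_fail & (rng.random(m) < 0.5)
        ambig_fail = qc_fail & ~short_fail
        length_after_trim[short_fail] = rng.integers(20, 60, size=int(short_fail.sum()))
        ambiguous[ambig_fail] = rng.integers(3, 6, size=int(ambig_fail.sum()))
        read_rows.append(
            pd.DataFrame(
                {
                    "read_id": read_ids,
                    "stage": stage,
                    "length_after_trim": length_after_trim,
                    "ambiguous_count": ambiguous,
                }
            )
        )

        # primary candidates; a fraction deliberately fails the filters
        identity = rng.uniform(0.985, 1.0, size=m)
        frac = rng.uniform(0.6, 1.0, size=m)
        afail = rng.random(m) < align_fail_rate
        low_ident = afail & (rng.random(m) < 0.5)
        low_frac = afail & ~low_ident
        identity[low_ident] = rng.uniform(0.90, 0.979, size=int(low_ident.sum()))
        frac[low_frac] = rng.uniform(0.2, 0.49, size=int(low_frac.sum()))

        cand_rows.append(
            pd.DataFrame(
                {
                    "read_id": read_ids,
                    "transcript_id": tids[source],
                    "percent_identity": identity,
                    "aligned_fraction": frac,
                }
            )
        )

        # secondary candidates for multi-mapped reads: rest of homology group
        if multimap_rate > 0:
            multi = np.flatnonzero((rng.random(m) < multimap_rate) & ~afail)
            extra_read, extra_t = [], []
            for i in multi:
                for partner in group_of[source[i]]:
                    if partner != source[i]:
                        extra_read.append(read_ids[i])
                        extra_t.append(tids[partner])
            if extra_read:
                k = len(extra_read)
                cand_rows.append(
                    pd.DataFrame(
                        {
                            "read_id": extra_read,
                            "transcript_id": extra_t,
                            "percent_identity": rng.uniform(0.985, 1.0, size=k),
                            "aligned_fraction": rng.uniform(0.6, 1.0, size=k),
                        }
                    )
                )

    reads = pd.concat(read_rows, ignore_index=True)
    candidates = pd.concat(cand_rows, ignore_index=True)
    return reads, candidates


def calibrated_noise_sd(
    x: np.ndarray,
    rho: float,
    eps: np.ndarray,
    retained_base: np.ndarray,
    intensity_percentile: float = 25.0,
) -> float:
    """Gaussian noise SD that plants Spearman ``rho`` on the retained pairs.

    The downstream platform comparison measures rank correlation only on
    pairs clearing both expression floors (probeset mean intensity above its
    25th percentile, mean RPKM above 0.5), and that truncation depresses the
    correlation relative to the full cohort. The SD is therefore solved
    numerically: for a fixed standard-normal noise draw ``eps`` (the one the
    generator will actually add, scaled), bisect the SD until the mean
    per-stage Spearman between noisy intensity and ``x`` over the retained
    set hits the target. ``retained_base`` marks rows passing the RPKM floor.

    A bivariate-normal first guess, r = 2 sin(pi rho / 6) and
    ``sd = s_x sqrt(1/r^2 - 1)``, brackets the search.
    """
    from scipy.optimize import brentq
    from scipy.stats import spearmanr

    if not 0.0 < rho <= 1.0:
        raise ConfigurationError(f"platform rho must be in (0, 1], got {rho}")
    if rho >= 1.0:
        return 0.0

    def measured_minus_target(sd: float) -> float:
        intensity = x + sd * eps
        keep = retained_base & (
            intensity.mean(axis=1)
            >= np.percentile(intensity.mean(axis=1), intensity_percentile)
        )
        rhos = [
            spearmanr(intensity[keep, j], x[keep, j]).statistic for j in range(x.shape[1])
        ]
        return float(np.mean(rhos)) - rho

    r = 2.0 * math.sin(math.pi * rho / 6.0)
    guess = float(np.std(x)) * math.sqrt(1.0 / r**2 - 1.0)
    hi = max(4.0 * guess, 1.0)
    while measured_minus_target(hi) > 0:
        hi *= 2.0
        if hi > 1e3:
            raise ConfigurationError("noise calibration failed to bracket the target")
    return float(brentq(measured_minus_target, 0.0, hi, xtol=1e-4))


def generate_probeset_data(
    truth: SyntheticTruth,
    catalog: list[TranscriptRecord],
    crosshyb_fraction: float = 0.1,
    noise_sd: float | None = None,
    seed: int = 0,
    *,
    evalue_positive_fraction: float = 0.05,
    duplicate_fraction: float = 0.05,
    intercept: float = 2.0,
    slope: float = 1.0,
) -> pd.DataFrame:
    """Microarray-style probeset intensities linked to the catalog.

    Intensities are ``intercept + slope * log2(true_rpkm + 1)`` plus Gaussian
    noise, i.e. already on the log2 (RMA-like) scale. When ``noise_sd`` is
    None the SD is calibrated so the Spearman correlation between intensity
    and log2(RPKM + 1) over expressed transcripts (mean RPKM >= 0.5, the
    subset the platform comparison retains) targets ``truth.platform_rho``.

    A ``crosshyb_fraction`` of probesets carries a cross-hybridisation suffix
    class (_s, _x or _a); an ``evalue_positive_fraction`` carries a non-zero
    probeset-to-transcript match e-value; a ``duplicate_fraction`` of linked
    transcripts receives a second, noisier probeset — each feature exercises
    one of the matched-pair filters.

    Columns: probeset_id, suffix_class, transcript_id, evalue, EL31..EL38.
    """
    for name, value in (
        ("crosshyb_fraction", crosshyb_fraction),
        ("evalue_positive_fraction", evalue_positive_fraction),
        ("duplicate_fraction", duplicate_fraction),
    ):
        if not 0.0 <= value <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
    if noise_sd is not None and noise_sd < 0:
        raise ConfigurationError(f"noise_sd must be >= 0, got {noise_sd}")

    rng = np.random.default_rng(seed)
    linked = [r for r in catalog if r.probeset_id is not None]
    if not linked:
        raise DataError("no transcript in the catalog carries a probeset link")
    tids = [r.transcript_id for r in linked]
    x = np.log2(truth.true_rpkm.reindex(tids).to_numpy() + 1.0)

    m = len(linked)
    eps = rng.normal(0.0, 1.0, size=(m, 4))
    if noise_sd is None:
        expressed = truth.true_rpkm.reindex(tids).mean(axis=1).to_numpy() >= 0.5
        noise_sd = calibrated_noise_sd(
            slope * x, truth.platform_rho, eps, retained_base=expressed
        )
    intensities = intercept + slope * x + noise_sd * eps
    suffix = np.where(
        rng.random(m) < crosshyb_fraction,
        rng.choice(["_s", "_x", "_a"], size=m),
        "",
    )
    evalue = np.where(
        rng.random(m) < evalue_positive_fraction,
        10.0 ** rng.uniform(-50, -10, size=m),
        0.0,
    )
    table = pd.DataFrame(
        {
            "probeset_id": [r.probeset_id for r in linked],
            "suffix_class": suffix,
            "transcript_id": tids,
            "evalue": evalue,
        }
    )
    table[list(STAGES)] = intensities

    if duplicate_fraction > 0:
        dup = np.flatnonzero(rng.random(m) < duplicate_fraction)
        if dup.size:
            noisy = (
                intercept
                + slope * x[dup]
                + rng.normal(0.0, noise_sd + 0.5, size=(dup.size, 4))
            )
            extra = pd.DataFrame(
                {
                    "probeset_id": [f"{linked[i].probeset_id}b" for i in dup],
                    "suffix_class": "",
                    "transcript_id": [tids[i] for i in dup],
                    "evalue": 0.0,
                }
            )
            extra[list(STAGES)] = noisy
            table = pd.concat([table, extra], ignore_index=True)
    return table
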