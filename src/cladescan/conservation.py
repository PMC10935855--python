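"""Clade-conservation calls per gene and motif, and Table-style summaries.

A motif counts as *conserved* for a gene when it is present in at least
``presence_threshold`` (default 75%, inclusive) of the gene's collected
ortholog promoters at a similar position to the start codon, operationalized
as within ``position_window`` bp of the focal species' hit nearest the start
codon.  *Majority* presence is the weaker call: a hit anywhere in more than
half of the collected promoters, with no positional constraint.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import InputError
from .expression import GeneSet
from .io import OrthologGroup, PromoterRecord
from .motif import Motif, conservation_counts, scan

DEFAULT_PRESENCE_THRESHOLD = 0.75
DEFAULT_POSITION_WINDOW = 200
DEFAULT_MIN_ORTHOLOGS = 8


@dataclass(frozen=True)
class ConservationCall:
    """Outcome of the conservation criterion for one (gene, motif) pair."""

    focal_gene_id: str
    motif: str
    n_orthologs_collected: int
    n_with_hit_anywhere: int
    n_with_hit_in_window: int
    presence_fraction: float
    reference_offset: int | None
    conserved: bool
    majority: bool
    evaluable: bool

    def __post_init__(self):
        ok = (
            0
            <= self.n_with_hit_in_window
            <= self.n_with_hit_anywhere
            <= self.n_orthologs_collected
        )
        if not ok:
            raise InputError("inconsistent conservation counts")
        if self.conserved and not self.evaluable:
            raise InputError("conserved call requires an evaluable group")


@dataclass(frozen=True)
class MotifSummaryRow:
    """One row of the three-column motif summary.

    Column 1 counts regulated genes whose focal promoter carries the motif
    (denominator: regulated genes with a focal promoter).  Columns 2-3 count
    conserved / majority calls over genes with enough collected ortholog
    promoters (a separate, smaller denominator — the ortholog-availability
    funnel).  Percentages are rounded half-up to integers.
    """

    motif: str
    n_present_focal: int
    n_with_promoter: int
    n_conserved: int
    n_evaluable: int
    n_majority: int
    pct_present_focal: int
    pct_conserved: int
    pct_majority: int


def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half-up (0 when the denominator is 0)."""
    if denominator == 0:
        return 0
    frac = Decimal(numerator * 100) / Decimal(denominator)
    return int(frac.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def classify_conservation(
    group: OrthologGroup,
    motif: Motif | str,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    position_window: int = DEFAULT_POSITION_WINDOW,
    min_orthologs: int = DEFAULT_MIN_ORTHOLOGS,
) -> ConservationCall:
    """Apply the clade-conservation criterion to one ortholog group.

    The reference offset is the focal-species hit nearest the start codon; a
    collected promoter agrees when any of its hits (either strand) lies
    within ``position_window`` bp of the reference.  ``conserved`` requires
    the group to be evaluable (at least ``min_orthologs`` collected
    promoters and a focal hit) and the in-window presence fraction to reach
    ``presence_threshold`` (inclusive).  ``majority`` needs a hit anywhere in
    strictly more than half of the collected promoters and is computed even
    when the focal promoter lacks the motif.
    """
    if isinstance(motif, str):
        motif = Motif(motif)
    if group.focal_promoter is None:
        raise InputError(
            f"group {group.focal_gene_id!r} has no focal promoter "
            f"(species {group.focal_species!r})"
        )
    offsets_by_species = {
        sp: sorted(h.offset for h in scan(rec, motif, both_strands=True))
        for sp, rec in group.promoters.items()
    }
    ref, n_collected, n_anywhere, n_in_window = conservation_counts(
        offsets_by_species, group.focal_species, position_window
    )
    evaluable = n_collected >= min_orthologs and ref is not None
    presence_fraction = n_in_window / n_collected if n_collected else 0.0
    conserved = evaluable and presence_fraction >= presence_threshold
    majority = n_anywhere > n_collected / 2
    return ConservationCall(
        focal_gene_id=group.focal_gene_id,
        motif=motif.pattern,
        n_orthologs_collected=n_collected,
        n_with_hit_anywhere=n_anywhere,
        n_with_hit_in_window=n_in_window,
        presence_fraction=presence_fraction,
        reference_offset=ref,
        conserved=conserved,
        majority=majority,
        evaluable=evaluable,
    )


def summarize_motifs(
    regulated: GeneSet,
    focal_promoters: dict[str, PromoterRecord],
    groups: list[OrthologGroup],
    motifs: list[Motif | str],
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    position_window: int = DEFAULT_POSITION_WINDOW,
    min_orthologs: int = DEFAULT_MIN_ORTHOLOGS,
) -> tuple[list[MotifSummaryRow], list[ConservationCall], list[str]]:
    """Three-column summary of motif presence over a regulated gene set.

    Returns ``(rows, per_gene_calls, missing_genes)``: one row per motif,
    the underlying per-gene conservation calls, and the regulated genes with
    no focal promoter (reported, never silently dropped).  Column
    denominators differ by design: column 1 uses regulated genes with a
    focal promoter; columns 2-3 use regulated genes whose ortholog group has
    at least ``min_orthologs`` collected promoters.
    """
    if not motifs:
        raise InputError("summarize_motifs requires at least one motif")
    motifs = [Motif(m) if isinstance(m, str) else m for m in motifs]
    groups_by_gene = {g.focal_gene_id: g for g in groups}

    with_promoter = [g for g in regulated.genes if g in focal_promoters]
    missing = [g for g in regulated.genes if g not in focal_promoters]
    evaluable_genes = [
        g
        for g in with_promoter
        if g in groups_by_gene and groups_by_gene[g].n_collected >= min_orthologs
    ]

    rows: list[MotifSummaryRow] = []
    all_calls: list[ConservationCall] = []
    for motif in motifs:
        n_present = sum(
            1 for g in with_promoter if scan(focal_promoters[g], motif, both_strands=True)
        )
        n_conserved = 0
        n_majority = 0
        for g in evaluable_genes:
            call = classify_conservation(
                groups_by_gene[g],
                motif,
                presence_threshold=presence_threshold,
                position_window=position_window,
                min_orthologs=min_orthologs,
            )
            all_calls.append(call)
            n_conserved += call.conserved
            n_majority += call.majority
        rows.append(
            MotifSummaryRow(
                motif=motif.pattern,
                n_present_focal=n_present,
                n_with_promoter=len(with_promoter),
                n_conserved=n_conserved,
                n_evaluable=len(evaluable_genes),
                n_majority=n_majority,
                pct_present_focal=percent(n_present, len(with_promoter)),
                pct_conserved=percent(n_conserved, len(evaluable_genes)),
                pct_majority=percent(n_majority, len(evaluable_genes)),
            )
        )
    return rows, all_calls, missing


def calls_to_frame(calls: list[ConservationCall]) -> pd.DataFrame:
    """Per-gene conservation calls as a flat table (one row per gene x motif)."""
    return pd.DataFrame(
        [
            {
                "gene_id": c.focal_gene_id,
                "motif": c.motif,
                "n_orthologs_collected": c.n_orthologs_collected,
                "n_with_hit_anywhere": c.n_with_hit_anywhere,
                "n_with_hit_in_window": c.n_with_hit_in_window,
                "presence_fraction": c.presence_fraction,
                "reference_offset": c.reference_offset,
                "conserved": c.conserved,
                "majority": c.majority,
                "evaluable": c.evaluable,
            }
            for c in calls
        ],
        columns=[
            "gene_id",
            "motif",
            "n_orthologs_collected",
            "n_with_hit_anywhere",
            "n_with_hit_in_window",
            "presence_fraction",
            "reference_offset",
            "conserved",
            "majority",
            "evaluable",
        ],
    )


def summary_to_frame(rows: list[MotifSummaryRow]) -> pd.DataFrame:
    """Summary rows as a table mirroring the three-column motif summary."""
    return pd.DataFrame(
        [
            {
                "motif": r.motif,
                "present_in_focal_promoter": f"{r.n_present_focal} ({r.pct_present_focal}%)",
                "conserved_in_clade": f"{r.n_conserved} ({r.pct_conserved}%)",
                "present_in_majority": f"{r.n_majority} ({r.pct_majority}%)",
                "n_with_promoter": r.n_with_promoter,
                "n_evaluable": r.n_evaluable,
            }
            for r in rows
        ],
        columns=[
            "motif",
            "present_in_focal_promoter",
            "conserved_in_clade",
            "present_in_majority",
            "n_with_promoter",
            "n_evaluable",
        ],
    )
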