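"""Counts normalization, regulated-gene selection, overlaps, heatmap matrices.

Selection applies the study's printed thresholds with inclusive operators:
``p <= p_max`` and ``log2FC >= lfc_min`` for up-regulation (``<= -lfc_min``
for down).  The DE statistic itself is consumed, never computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import InputError
from .io import CountsMatrix

#: Default selection thresholds (inclusive, as printed).
DEFAULT_P_MAX = 0.01
DEFAULT_LFC_MIN = 1.5


@dataclass(frozen=True)
class GeneSet:
    """Regulated genes for one comparison and direction."""

    comparison: str
    direction: str  # 'up' = higher expression in the regulator-functional strain
    genes: tuple[str, ...]

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise InputError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if len(set(self.genes)) != len(self.genes):
            raise InputError("gene set members must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass(frozen=True)
class OverlapSummary:
    """Cross-condition overlap accounting for same-direction gene sets.

    ``exclusive`` maps each non-empty subset of comparison ids to the number
    of genes in exactly those sets (disjoint regions, as drawn in a Venn
    diagram); ``intersections`` maps each subset to the plain intersection
    size of its sets.
    """

    comparisons: tuple[str, ...]
    exclusive: dict[frozenset, int]
    intersections: dict[frozenset, int]


def compute_tpm(counts: CountsMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates rescaled to 1e6 per sample.

    Per sample: ``rate_g = count_g / length_g(kb)``; ``TPM_g = rate_g /
    sum(rate) * 1e6``.  An all-zero sample yields an all-zero column with a
    warning.  The returned frame carries ``attrs['unit'] = 'TPM'``.
    """
    rate = counts.counts.div(counts.lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero_samples = totals[totals == 0].index
    if len(zero_samples):
        warnings.warn(f"all-zero sample(s) {list(zero_samples)}: TPM left at zero")
        totals = totals.replace(0, np.nan)
    tpm = rate.div(totals, axis=1) * 1e6
    tpm = tpm.fillna(0.0)
    tpm.attrs["unit"] = "TPM"
    return tpm


def compute_fpkm(counts: CountsMatrix, allow_zero_samples: bool = False) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    ``FPKM_g = count_g * 1e9 / (length_g(bp) * library_size)``.  An all-zero
    sample makes the division undefined and raises unless
    ``allow_zero_samples`` is set (then the column is all zeros).
    """
    totals = counts.counts.sum(axis=0)
    zero_samples = totals[totals == 0].index
    if len(zero_samples):
        if not allow_zero_samples:
            raise InputError(
                f"all-zero sample(s) {list(zero_samples)}: FPKM undefined "
                "(pass allow_zero_samples=True to emit zeros)"
            )
        totals = totals.replace(0, np.nan)
    fpkm = counts.counts.div(totals, axis=1).div(counts.lengths, axis=0) * 1e9
    fpkm = fpkm.fillna(0.0)
    fpkm.attrs["unit"] = "FPKM"
    return fpkm


def select_regulated(
    de: pd.DataFrame,
    comparison: str,
    direction: str = "up",
    p_max: float = DEFAULT_P_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
    p_column: str = "pvalue",
) -> GeneSet:
    """Apply the inclusive p-value and fold-change cutoffs to one comparison.

    Up-regulated: ``p <= p_max`` and ``log2FC >= lfc_min``; down-regulated:
    ``p <= p_max`` and ``log2FC <= -lfc_min``.  Boundary values are included,
    matching the printed "<=" / ">=" operators.  ``p_column`` selects which
    p-value column the cutoff reads (raw vs adjusted is a caller choice).
    """
    if p_max <= 0 or lfc_min <= 0:
        raise InputError("thresholds must be positive")
    if direction not in ("up", "down"):
        raise InputError(f"direction must be 'up' or 'down', got {direction!r}")
    if comparison not in set(de["comparison"]):
        raise InputError(f"unknown comparison id {comparison!r}")
    if p_column not in de.columns:
        raise InputError(f"DE table has no column {p_column!r}")
    sub = de[de["comparison"] == comparison]
    passed_p = sub[p_column] <= p_max
    if direction == "up":
        passed_fc = sub["log2fc"] >= lfc_min
    else:
        passed_fc = sub["log2fc"] <= -lfc_min
    genes = tuple(sub.loc[passed_p & passed_fc, "gene_id"])
    return GeneSet(comparison=comparison, direction=direction, genes=genes)


def overlap_summary(sets: list[GeneSet]) -> OverlapSummary:
    """Exact overlap counts for every combination of same-direction gene sets."""
    if len(sets) < 2:
        raise InputError("overlap_summary requires at least 2 gene sets")
    directions = {s.direction for s in sets}
    if len(directions) > 1:
        raise InputError(f"mixed directions {sorted(directions)} in overlap_summary")
    comparisons = tuple(s.comparison for s in sets)
    if len(set(comparisons)) != len(comparisons):
        raise InputError("duplicate comparison ids in overlap_summary")

    membership = {s.comparison: set(s.genes) for s in sets}
    all_genes = set().union(*membership.values())
    exclusive: dict[frozenset, int] = {}
    for gene in all_genes:
        signature = frozenset(c for c in comparisons if gene in membership[c])
        exclusive[signature] = exclusive.get(signature, 0) + 1
    intersections: dict[frozenset, int] = {}
    for r in range(1, len(comparisons) + 1):
        for combo in combinations(comparisons, r):
            inter = set.intersection(*(membership[c] for c in combo))
            intersections[frozenset(combo)] = len(inter)
    return OverlapSummary(
        comparisons=comparisons, exclusive=exclusive, intersections=intersections
    )


def row_normalize(matrix: pd.DataFrame, method: str = "zscore") -> pd.DataFrame:
    """Normalize within rows for heatmap display.

    ``zscore``: ``(x - row mean) / row SD`` with population SD (divisor n);
    constant rows become all zeros with a warning.  ``minmax``: ``(x - row
    min) / (row max - row min)``; constant rows likewise become zeros.
    """
    if matrix.size == 0:
        raise InputError("cannot row-normalize an empty matrix")
    values = matrix.to_numpy(dtype=float)
    if method == "zscore":
        center = values.mean(axis=1, keepdims=True)
        scale = values.std(axis=1, ddof=0, keepdims=True)
    elif method == "minmax":
        center = values.min(axis=1, keepdims=True)
        scale = values.max(axis=1, keepdims=True) - center
    else:
        raise InputError(f"unknown row-normalization method {method!r}")
    constant = (scale == 0).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant row(s) set to all zeros")
        scale[constant] = 1.0
    out = (values - center) / scale
    out[constant, :] = 0.0
    result = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    result.attrs["unit"] = "row-normalized"
    return result


def gene_sets_to_manifest(sets: list[GeneSet]) -> dict:
    """JSON-serializable manifest of gene sets keyed by comparison id."""
    return {
        s.comparison: {"direction": s.direction, "n": len(s), "genes": list(s.genes)}
        for s in sets
    }
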