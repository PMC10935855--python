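"""Short-motif scanning on promoter fragments and conserved k-mer discovery.

Offsets follow the start-codon-anchored convention used throughout the
package: position ``-1`` is the base immediately 5' of the start codon, so a
hit whose 5'-most base sits at offset ``o`` occupies ``[o, o+k-1]`` and a hit
flush against the start codon has offset ``-k``.  Within a promoter fragment
of length ``L`` (whose last base abuts the start codon), a 0-based window
start ``i`` corresponds to offset ``i - L``.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

from .errors import InputError

#: IUPAC nucleotide codes and the set of plain bases each one matches.
IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(_IUPAC_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (involution)."""
    seq = seq.upper()
    bad = set(seq) - set(IUPAC_EXPAND)
    if bad:
        raise InputError(f"non-IUPAC character(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Fold a k-mer with its reverse complement into one canonical key.

    The lexicographically smaller of the pair is used, so a motif and its
    reverse are one identity (e.g. ATGCA and TGCAT both map to ATGCA).
    """
    rc = reverse_complement(kmer)
    return min(kmer.upper(), rc)


@dataclass(frozen=True)
class Motif:
    """A short degenerate pattern matched on both strands.

    ``canonical=True`` folds reverse-complement hits into the same motif
    identity, which is how the clade analysis treats each motif/reverse pair.
    """

    pattern: str
    canonical: bool = True

    def __post_init__(self):
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if not pat:
            raise InputError("motif pattern must be non-empty")
        bad = set(pat) - set(IUPAC_EXPAND)
        if bad:
            raise InputError(f"non-IUPAC character(s) {sorted(bad)} in motif {pat!r}")
        if not 3 <= len(pat) <= 12:
            raise InputError(f"motif length must be in [3, 12], got {len(pat)}")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def reverse(self) -> str:
        return reverse_complement(self.pattern)

    @property
    def is_palindromic(self) -> bool:
        return self.pattern == self.reverse


@dataclass(frozen=True)
class MotifHit:
    """One motif match in a promoter fragment.

    ``offset`` is the start-codon-anchored position of the match's 5'-most
    base on the promoter's sense strand; ``strand`` is '+' when the window
    matches the pattern and '-' when it matches the reverse complement.
    """

    gene_id: str
    species_id: str
    offset: int
    strand: str
    matched: str


@dataclass(frozen=True)
class RepeatCount:
    gene_id: str
    motif: str
    count: int


@dataclass
class DiscoveredMotif:
    """A candidate k-mer that passed the cluster-wide conservation screen."""

    kmer: str  # canonical key
    score: float  # fraction of cluster genes for which the k-mer is conserved
    calls: dict[str, bool] = field(default_factory=dict)  # focal gene -> conserved
    background_occurrences: int = 0


def _pattern_regex(pattern: str) -> re.Pattern:
    # Lookahead so overlapping windows are all reported.  Character classes
    # contain plain bases only, so N in the *sequence* never matches.
    body = "".join(f"[{IUPAC_EXPAND[c]}]" for c in pattern.upper())
    return re.compile(f"(?=({body}))")


def scan_sequence(seq: str, pattern: str, both_strands: bool = True) -> list[tuple[int, str, str]]:
    """Scan a raw sequence; return ``(offset, strand, matched)`` triples.

    Offsets are start-codon anchored assuming the sequence's final base abuts
    the start codon.  Palindromic patterns report each window once (strand +).
    """
    seq = seq.upper()
    L = len(seq)
    k = len(pattern)
    if k > L:
        raise InputError(f"motif length {k} exceeds sequence length {L}")
    out = []
    for m in _pattern_regex(pattern).finditer(seq):
        out.append((m.start() - L, "+", m.group(1)))
    rc = reverse_complement(pattern)
    if both_strands and rc != pattern.upper():
        for m in _pattern_regex(rc).finditer(seq):
            out.append((m.start() - L, "-", m.group(1)))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def scan(promoter, motif: Motif | str, both_strands: bool = True) -> list[MotifHit]:
    """Scan one promoter fragment for a motif on one or both strands.

    ``promoter`` is a :class:`~cladescan.io.PromoterRecord` (or anything with
    ``sequence``, ``gene_id`` and ``species_id`` attributes).  Every matching
    window is reported, overlaps included, sorted by offset.
    """
    if isinstance(motif, str):
        motif = Motif(motif)
    seq = promoter.sequence
    if not seq:
        raise InputError(f"promoter for gene {promoter.gene_id!r} is empty")
    triples = scan_sequence(seq, motif.pattern, both_strands=both_strands)
    return [
        MotifHit(promoter.gene_id, promoter.species_id, off, strand, matched)
        for off, strand, matched in triples
    ]


def count_repeats(hits: list[MotifHit], motif: Motif | str | None = None) -> RepeatCount:
    """Greedy left-to-right non-overlapping repeat count for one gene.

    Hits from both strands are merged by offset first.  Greedy selection of
    equal-length intervals is optimal, so the count equals the maximum number
    of non-overlapping occurrences.
    """
    if isinstance(motif, Motif):
        motif = motif.pattern
    if not hits:
        return RepeatCount(gene_id="", motif=motif or "", count=0)
    genes = {h.gene_id for h in hits}
    if len(genes) > 1:
        raise InputError(f"count_repeats requires hits from one gene, got {sorted(genes)}")
    ks = {len(h.matched) for h in hits}
    if len(ks) > 1:
        raise InputError("count_repeats requires hits of a single motif length")
    k = ks.pop()
    offsets = sorted({h.offset for h in hits})
    count = 0
    cursor = None
    for off in offsets:
        if cursor is None or off >= cursor:
            count += 1
            cursor = off + k
    return RepeatCount(gene_id=hits[0].gene_id, motif=motif or hits[0].matched, count=count)


# ---------------------------------------------------------------------------
# Conserved k-mer discovery
# ---------------------------------------------------------------------------

def conservation_counts(
    offsets_by_species: dict[str, list[int]],
    focal_species: str,
    position_window: int,
):
    """Core positional-agreement bookkeeping shared by classification and discovery.

    ``offsets_by_species`` maps every *collected* species (including the
    focal one) to the sorted hit offsets of a motif in that species' promoter
    (empty list = promoter collected but no hit).  Returns
    ``(reference_offset, n_collected, n_anywhere, n_in_window)`` where the
    reference is the focal hit nearest the start codon (largest offset, all
    offsets being negative) and a species counts as in-window when any of its
    hits lies within ``position_window`` bp of the reference.
    """
    focal = offsets_by_species.get(focal_species)
    if focal is None:
        raise InputError(f"focal species {focal_species!r} has no collected promoter")
    ref = max(focal) if focal else None
    n_collected = len(offsets_by_species)
    n_anywhere = sum(1 for v in offsets_by_species.values() if v)
    if ref is None:
        n_in_window = 0
    else:
        n_in_window = sum(
            1
            for v in offsets_by_species.values()
            if any(abs(o - ref) <= position_window for o in v)
        )
    return ref, n_collected, n_anywhere, n_in_window


def _index_words(seq: str, k: int) -> dict[str, list[int]]:
    """All plain-ACGT k-mer occurrences of ``seq`` keyed by word, offsets anchored."""
    L = len(seq)
    idx: dict[str, list[int]] = defaultdict(list)
    valid = set("ACGT")
    for i in range(L - k + 1):
        word = seq[i : i + k]
        if set(word) <= valid:
            idx[word].append(i - L)
    return idx


def discover_conserved_kmers(
    cluster,
    kmin: int = 5,
    kmax: int = 6,
    min_cluster_fraction: float = 0.8,
    presence_threshold: float = 0.75,
    position_window: int = 200,
    min_orthologs: int = 8,
) -> list[DiscoveredMotif]:
    """Screen every focal-promoter k-mer for conservation across a gene cluster.

    Candidates are all k-mers (``kmin <= k <= kmax``) occurring in the focal
    species promoters of the cluster, folded with their reverse complements
    into canonical keys.  Each candidate is classified against every cluster
    gene's ortholog group with the same rule as
    :func:`cladescan.conservation.classify_conservation`; candidates conserved
    in at least ``min_cluster_fraction`` of cluster genes are returned, ranked
    by conservation score, then fewer total occurrences across the cluster's
    promoters (rarer = more specific), then lexicographically.
    """
    cluster = list(cluster)
    if not cluster:
        raise InputError("discover_conserved_kmers requires a non-empty cluster")
    evaluable_groups = [g for g in cluster if g.focal_promoter is not None]
    if len(evaluable_groups) < 2:
        raise InputError("discovery requires >= 2 cluster genes with focal promoters")
    if not (3 <= kmin <= kmax <= 12):
        raise InputError("k range must satisfy 3 <= kmin <= kmax <= 12")

    n_genes = len(cluster)
    results: list[DiscoveredMotif] = []
    for k in range(kmin, kmax + 1):
        # Per group, per species: word index of the promoter at this k.
        group_indexes = []
        for grp in cluster:
            group_indexes.append(
                {sp: _index_words(rec.sequence, k) for sp, rec in grp.promoters.items()}
            )
        candidates: set[str] = set()
        for grp, idx in zip(cluster, group_indexes):
            focal_idx = idx.get(grp.focal_species, {})
            candidates.update(canonical_kmer(w) for w in focal_idx)

        for cand in sorted(candidates):
            rc = reverse_complement(cand)
            calls: dict[str, bool] = {}
            background = 0
            for grp, idx in zip(cluster, group_indexes):
                offsets_by_species = {}
                for sp in grp.promoters:
                    offs = list(idx[sp].get(cand, ()))
                    if rc != cand:
                        offs += idx[sp].get(rc, ())
                    offs.sort()
                    offsets_by_species[sp] = offs
                    background += len(offs)
                if grp.focal_species not in offsets_by_species:
                    calls[grp.focal_gene_id] = False
                    continue
                ref, n_coll, n_any, n_win = conservation_counts(
                    offsets_by_species, grp.focal_species, position_window
                )
                evaluable = n_coll >= min_orthologs and ref is not None
                frac = n_win / n_coll if n_coll else 0.0
                calls[grp.focal_gene_id] = evaluable and frac >= presence_threshold
            score = sum(calls.values()) / n_genes
            if score >= min_cluster_fraction:
                results.append(
                    DiscoveredMotif(
                        kmer=cand,
                        score=score,
                        calls=calls,
                        background_occurrences=background,
                    )
                )
    results.sort(key=lambda d: (-d.score, d.background_occurrences, d.kmer))
    return results
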