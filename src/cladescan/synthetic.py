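"""Synthetic promoters, ortholog groups, genomes and DE tables with known truth.

The generator states a simple world: i.i.d. base composition with
``P(G) = P(C) = gc/2``, a single planted motif per ortholog group at a fixed
anchor offset with Gaussian positional jitter, and per-species presence drawn
independently.  No phylogenetic correlation, indels or read-level noise are
simulated; see docs/methods.md for what that does and does not establish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .io import GeneAnnotation, OrthologGroup, PromoterRecord
from .motif import reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one planted-motif ortholog-group world.

    ``anchor_offset`` uses the start-codon-anchored convention (negative,
    with -1 the base immediately 5' of the start codon).  Every species
    carries the planted motif independently with ``presence_prob``;
    ``focal_presence_prob``, when set, overrides that probability for the
    focal species alone (set it to 1.0 to model a motif already observed in
    the focal promoter and ask whether it is conserved).
    """

    n_species: int = 12
    promoter_length: int = 1000
    gc_content: float = 0.5
    motif: str = "ATGCA"
    presence_prob: float = 0.9
    anchor_offset: int = -200
    jitter_sd: float = 30.0
    seed: int = 0
    focal_presence_prob: float | None = None

    def __post_init__(self):
        k = len(self.motif)
        if self.n_species < 1:
            raise InputError("n_species must be >= 1")
        if self.promoter_length < k:
            raise InputError("promoter_length must be >= motif length")
        if not 0.0 <= self.gc_content <= 1.0:
            raise InputError("gc_content must be in [0, 1]")
        if not 0.0 <= self.presence_prob <= 1.0:
            raise InputError("presence_prob must be in [0, 1]")
        if self.focal_presence_prob is not None and not 0.0 <= self.focal_presence_prob <= 1.0:
            raise InputError("focal_presence_prob must be in [0, 1]")
        if not -self.promoter_length <= self.anchor_offset <= -k:
            raise InputError("anchor_offset must lie in [-promoter_length, -motif length]")
        if self.jitter_sd < 0:
            raise InputError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class PlantTruth:
    """Ground truth of one generated ortholog group."""

    group_id: str
    carriers: tuple[str, ...]  # species ids carrying the planted motif
    offsets: dict[str, int] = field(default_factory=dict)  # species -> planted offset
    strands: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class RegulationTruth:
    """Ground truth of a generated DE table."""

    regulated: tuple[str, ...]
    directions: dict[str, str] = field(default_factory=dict)  # gene -> up/down


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_promoter(length: int, gc: float, seed) -> str:
    """Random uppercase ACGT sequence with expected G+C fraction ``gc``."""
    if length < 1:
        raise InputError("promoter length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise InputError("gc must be in [0, 1]")
    rng = _rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def plant_motif(sequence: str, motif: str, offset: int, strand: str = "+") -> str:
    """Overwrite the window ``[offset, offset+k-1]`` with the motif.

    Offset convention: -1 is the base immediately 5' of the start codon (the
    sequence's last base).  Strand '-' plants the reverse complement.
    """
    seq = sequence.upper()
    motif = motif.upper()
    k = len(motif)
    L = len(seq)
    start = L + offset  # 0-based window start
    if not (0 <= start and start + k <= L):
        raise InputError(
            f"window [{offset}, {offset + k - 1}] outside sequence of length {L}"
        )
    if strand == "+":
        insert = motif
    elif strand == "-":
        insert = reverse_complement(motif)
    else:
        raise InputError(f"strand must be '+' or '-', got {strand!r}")
    return seq[:start] + insert + seq[start + k :]


def species_ids(n_species: int) -> list[str]:
    return [f"sp{i:02d}" for i in range(1, n_species + 1)]


def generate_ortholog_group(
    spec: SyntheticSpec,
    group_id: str = "g1",
    rng: np.random.Generator | None = None,
) -> tuple[OrthologGroup, PlantTruth]:
    """One promoter per clade species, the motif planted per presence draws.

    The first species is the focal one; planted positions are the anchor
    offset plus rounded Gaussian jitter, clipped to the valid window, on a
    uniformly random strand.  Reproducible: the same spec (same seed) yields
    byte-identical promoters and truth.
    """
    rng = _rng(spec.seed if rng is None else rng)
    sps = species_ids(spec.n_species)
    focal = sps[0]
    k = len(spec.motif)
    L = spec.promoter_length

    group = OrthologGroup(
        focal_gene_id=f"{group_id}_{focal}",
        focal_species=focal,
        gene_ids={sp: f"{group_id}_{sp}" for sp in sps},
    )
    carriers: list[str] = []
    offsets: dict[str, int] = {}
    strands: dict[str, str] = {}
    for sp in sps:
        seq = generate_promoter(L, spec.gc_content, rng)
        prob = spec.presence_prob
        if sp == focal and spec.focal_presence_prob is not None:
            prob = spec.focal_presence_prob
        if rng.random() < prob:
            jitter = int(round(rng.normal(0.0, spec.jitter_sd))) if spec.jitter_sd else 0
            off = int(np.clip(spec.anchor_offset + jitter, -L, -k))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = plant_motif(seq, spec.motif, off, strand)
            carriers.append(sp)
            offsets[sp] = off
            strands[sp] = strand
        group.promoters[sp] = PromoterRecord(
            gene_id=group.gene_ids[sp],
            species_id=sp,
            sequence=seq,
            requested_length=L,
        )
    truth = PlantTruth(group_id=group_id, carriers=tuple(carriers), offsets=offsets, strands=strands)
    return group, truth


def generate_de_table(
    n_genes: int,
    n_regulated: int,
    p_alt_shape: float = 0.05,
    lfc_alt_mean: float = 4.0,
    seed=0,
    comparison: str = "cmp1",
    gene_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, RegulationTruth]:
    """Simulate a DE table at the statistics level (p-value, log2FC).

    Null genes draw ``p ~ Uniform(0,1)`` and ``log2FC ~ Normal(0, 0.3)``;
    regulated genes draw ``p ~ Beta(p_alt_shape, 1)`` (small shape -> small
    p) and ``log2FC ~ Normal(+-lfc_alt_mean, 0.3)`` with the sign recorded in
    the truth.  The first ``n_regulated`` gene ids are the regulated set.
    """
    if n_regulated > n_genes:
        raise InputError("n_regulated cannot exceed n_genes")
    if n_genes < 1:
        raise InputError("n_genes must be >= 1")
    if p_alt_shape <= 0:
        raise InputError("p_alt_shape must be > 0")
    rng = _rng(seed)
    if gene_ids is None:
        width = max(4, len(str(n_genes)))
        gene_ids = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    elif len(gene_ids) != n_genes:
        raise InputError("gene_ids length must equal n_genes")

    pvals = np.empty(n_genes)
    lfcs = np.empty(n_genes)
    signs = rng.random(n_regulated) < 0.5  # True -> down-regulated
    if n_regulated:
        pvals[:n_regulated] = rng.beta(p_alt_shape, 1.0, size=n_regulated)
        means = np.where(signs, -lfc_alt_mean, lfc_alt_mean)
        lfcs[:n_regulated] = rng.normal(means, 0.3)
    n_null = n_genes - n_regulated
    if n_null:
        pvals[n_regulated:] = rng.uniform(0.0, 1.0, size=n_null)
        lfcs[n_regulated:] = rng.normal(0.0, 0.3, size=n_null)

    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "comparison": comparison,
            "log2fc": lfcs,
            "pvalue": pvals,
        }
    )
    regulated = tuple(gene_ids[:n_regulated])
    directions = {
        g: ("down" if s else "up") for g, s in zip(regulated, signs)
    }
    truth = RegulationTruth(regulated=regulated, directions=directions)
    return table, truth


# ---------------------------------------------------------------------------
# Fixture genomes
# ---------------------------------------------------------------------------

@dataclass
class FixtureGene:
    """Intended layout of one gene in a written fixture genome.

    ``start`` (1-based annotation start of the gene span) may be left None
    for automatic sequential placement with the promoter fully upstream.
    """

    gene_id: str
    promoter: str
    strand: str = "+"
    gene_seq: str | None = None
    contig: str = "chr1"
    start: int | None = None


def write_fixture_genome(
    genes: list[FixtureGene],
    out_prefix,
    seed=0,
    gene_length: int = 120,
    spacer: int = 25,
) -> tuple[str, str]:
    """Write FASTA + GFF3 such that promoter extraction round-trips exactly.

    Each gene occupies its own block (promoter + gene body on the gene's
    strand); for a minus-strand gene the promoter's reverse complement is
    placed 3' of the gene on the reference strand.  Auto-placed blocks are
    separated by random spacer bases; explicitly placed blocks must not
    collide.  Returns ``(fasta_path, gff_path)``.
    """
    if not genes:
        raise InputError("fixture layout must contain at least one gene")
    rng = _rng(seed)
    contigs: dict[str, list] = {}
    annotations: list[GeneAnnotation] = []
    occupied: dict[str, list[tuple[int, int]]] = {}

    # First pass: resolve explicit placements into (block_start_1based, block).
    placements = []
    for g in genes:
        gseq = g.gene_seq
        if gseq is None:
            gseq = "ATG" + generate_promoter(gene_length - 3, 0.5, rng)
        gseq = gseq.upper()
        prom = g.promoter.upper()
        if g.strand == "+":
            block = prom + gseq
            gene_off = len(prom)  # 0-based offset of gene start within block
        elif g.strand == "-":
            block = reverse_complement(gseq) + reverse_complement(prom)
            gene_off = 0
        else:
            raise InputError(f"gene {g.gene_id!r}: invalid strand {g.strand!r}")
        placements.append((g, block, gene_off, len(gseq)))

    cursors: dict[str, int] = {}
    parts: dict[str, list[str]] = {}
    explicit = [p for p in placements if p[0].start is not None]
    if explicit:
        # Explicit placement: assemble sparse blocks, error on overlap.
        blocks_by_contig: dict[str, list[tuple[int, str, FixtureGene, int, int]]] = {}
        for g, block, gene_off, glen in placements:
            if g.start is None:
                raise InputError("mix of explicit and automatic placement is not supported")
            if g.strand == "+":
                block_start = g.start - len(g.promoter)  # 1-based
            else:
                block_start = g.start
            if block_start < 1:
                raise InputError(f"gene {g.gene_id!r}: promoter extends past contig start")
            blocks_by_contig.setdefault(g.contig, []).append(
                (block_start, block, g, gene_off, glen)
            )
        for contig, blocks in blocks_by_contig.items():
            blocks.sort(key=lambda b: b[0])
            prev_end = 0
            seq_parts = []
            for block_start, block, g, gene_off, glen in blocks:
                if block_start <= prev_end:
                    raise InputError(
                        f"layout collision at contig {contig!r}, gene {g.gene_id!r}"
                    )
                gap = block_start - prev_end - 1
                if gap:
                    seq_parts.append(generate_promoter(gap, 0.5, rng))
                seq_parts.append(block)
                gstart = block_start + gene_off
                annotations.append(
                    GeneAnnotation(g.gene_id, contig, gstart, gstart + glen - 1, g.strand)
                )
                prev_end = block_start + len(block) - 1
            parts[contig] = seq_parts
    else:
        for g, block, gene_off, glen in placements:
            cur = cursors.get(g.contig, 0)
            seq_parts = parts.setdefault(g.contig, [])
            if cur:
                seq_parts.append(generate_promoter(spacer, 0.5, rng))
                cur += spacer
            block_start = cur + 1  # 1-based
            seq_parts.append(block)
            gstart = block_start + gene_off
            annotations.append(
                GeneAnnotation(g.gene_id, g.contig, gstart, gstart + glen - 1, g.strand)
            )
            cursors[g.contig] = cur + len(block)

    fasta_path = f"{out_prefix}.fasta"
    gff_path = f"{out_prefix}.gff3"
    with open(fasta_path, "w") as fh:
        for contig, seq_parts in parts.items():
            seq = "".join(seq_parts)
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            fh.write(
                f"{ann.contig}\tcladescan\tgene\t{ann.start}\t{ann.end}\t.\t"
                f"{ann.strand}\t.\tID={ann.gene_id}\n"
            )
    return fasta_path, gff_path


def expected_background_hit_rate(length: int, kmer: str, gc: float) -> float:
    """Closed-form approximation of P(>=1 hit) per promoter for a plain k-mer.

    Linear (union-bound) approximation ``2 * (L-k+1) * prod(p_base)`` of the
    both-strand expected window count; adequate for calibration checks at
    small per-window probabilities.
    """
    k = len(kmer)
    p = 1.0
    for base in kmer.upper():
        p *= gc / 2 if base in "GC" else (1 - gc) / 2
    return 2 * (length - k + 1) * p


__all__ = [
    "SyntheticSpec",
    "PlantTruth",
    "RegulationTruth",
    "FixtureGene",
    "generate_promoter",
    "plant_motif",
    "generate_ortholog_group",
    "generate_de_table",
    "write_fixture_genome",
    "expected_background_hit_rate",
    "species_ids",
]
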