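"""Genome, annotation and table input; strand-aware promoter extraction.

Coordinate contract: GFF3 coordinates are 1-based inclusive externally and
kept that way on :class:`GeneAnnotation`; slicing is done internally in
0-based half-open coordinates; motif hit offsets downstream use the
start-codon-anchored signed convention (see :mod:`cladescan.motif`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

from .errors import FormatError, InputError
from .motif import reverse_complement

logger = logging.getLogger(__name__)

_VALID_GENOME_CHARS = set("ACGTN")


@dataclass(frozen=True)
class GeneAnnotation:
    """One `gene` feature: 1-based inclusive coordinates, as in the GFF3."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    species_id: str = ""


@dataclass(frozen=True)
class PromoterRecord:
    """One upstream fragment, written 5'->3' on the gene's coding strand.

    The sequence ends at the base immediately before the start codon.
    ``truncated`` is set when the contig boundary clipped the fragment below
    the requested length; ``upstream_gene_in_window`` flags another gene's
    span intersecting the window (the fragment is not clipped for it).
    """

    gene_id: str
    species_id: str
    sequence: str
    requested_length: int
    truncated: bool = False
    upstream_gene_in_window: bool = False

    @property
    def actual_length(self) -> int:
        return len(self.sequence)

    def __post_init__(self):
        if self.actual_length > self.requested_length:
            raise InputError("promoter longer than requested length")
        if self.truncated != (self.actual_length < self.requested_length):
            raise InputError("truncated flag inconsistent with lengths")


@dataclass
class OrthologGroup:
    """A focal gene plus its per-species orthologs and resolved promoters.

    The focal species' own promoter counts among the collected fragments,
    mirroring clade comparisons run on up to one fragment per clade species.
    """

    focal_gene_id: str
    focal_species: str
    gene_ids: dict[str, str] = field(default_factory=dict)  # species -> gene id
    promoters: dict[str, PromoterRecord] = field(default_factory=dict)

    @property
    def focal_promoter(self) -> PromoterRecord | None:
        return self.promoters.get(self.focal_species)

    @property
    def n_collected(self) -> int:
        return len(self.promoters)


@dataclass
class CountsMatrix:
    """Raw read counts (genes x samples) with per-gene effective lengths."""

    counts: pd.DataFrame
    lengths: pd.Series
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.counts.index.equals(self.lengths.index):
            raise InputError("counts and lengths are indexed by different genes")
        if (self.lengths <= 0).any():
            raise InputError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts must be non-negative")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_genome_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA into ``{contig id: uppercase sequence}``."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in genome:
            raise FormatError(f"duplicate contig id {rec.id!r}", path=path)
        bad = set(seq) - _VALID_GENOME_CHARS
        if bad:
            raise FormatError(
                f"illegal character(s) {sorted(bad)} in contig {rec.id!r}", path=path
            )
        genome[rec.id] = seq
    if not genome:
        raise FormatError("no FASTA records found", path=path)
    return genome


def read_annotations_gff3(path, species_id: str = "") -> list[GeneAnnotation]:
    """Parse `gene` features (with ``ID=``) from a GFF3 file.

    Other feature types are ignored; a file without any `gene` feature
    yields an empty list and a logged warning.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(f"unparseable GFF3 line: {exc}", path=path, line=lineno)
            if feat.featuretype != "gene":
                continue
            if "ID" not in feat.attributes:
                raise FormatError("gene feature lacks ID attribute", path=path, line=lineno)
            gid = feat.attributes["ID"][0]
            if feat.end < feat.start:
                raise FormatError(
                    f"gene {gid!r} has end < start ({feat.end} < {feat.start})",
                    path=path,
                    line=lineno,
                )
            if feat.strand not in "+-":
                raise FormatError(f"gene {gid!r} has no strand", path=path, line=lineno)
            if gid in seen:
                raise FormatError(f"duplicate gene id {gid!r}", path=path, line=lineno)
            seen.add(gid)
            genes.append(
                GeneAnnotation(gid, feat.seqid, feat.start, feat.end, feat.strand, species_id)
            )
    if not genes:
        logger.warning("no `gene` features found in %s", path)
    return genes


def extract_promoters(
    genome: dict[str, str],
    annotations: list[GeneAnnotation],
    length: int = 1000,
) -> list[PromoterRecord]:
    """Extract a fixed-length upstream fragment for every annotated gene.

    For a plus-strand gene the fragment is the reference slice
    ``[start-length, start-1]`` (1-based); for a minus-strand gene it is the
    reverse complement of ``[end+1, end+length]``.  Fragments are clipped at
    contig boundaries (``truncated=True``) and never include the start codon.
    """
    if length < 1:
        raise InputError("promoter length must be >= 1")
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for ann in annotations:
        by_contig.setdefault(ann.contig, []).append(ann)

    records: list[PromoterRecord] = []
    for ann in annotations:
        if ann.contig not in genome:
            raise InputError(f"contig {ann.contig!r} for gene {ann.gene_id!r} not in genome")
        contig_seq = genome[ann.contig]
        clen = len(contig_seq)
        if not (1 <= ann.start <= ann.end <= clen):
            raise InputError(
                f"gene {ann.gene_id!r} coordinates [{ann.start}, {ann.end}] "
                f"outside contig of length {clen}"
            )
        if ann.strand == "+":
            lo = max(ann.start - length, 1)  # 1-based inclusive window
            hi = ann.start - 1
            frag = contig_seq[lo - 1 : hi]
        elif ann.strand == "-":
            lo = ann.end + 1
            hi = min(ann.end + length, clen)
            frag = reverse_complement(contig_seq[lo - 1 : hi])
        else:
            raise InputError(f"gene {ann.gene_id!r} has invalid strand {ann.strand!r}")
        overlap = any(
            other.gene_id != ann.gene_id and other.start <= hi and other.end >= lo
            for other in by_contig[ann.contig]
        ) if hi >= lo else False
        records.append(
            PromoterRecord(
                gene_id=ann.gene_id,
                species_id=ann.species_id,
                sequence=frag,
                requested_length=length,
                truncated=len(frag) < length,
                upstream_gene_in_window=overlap,
            )
        )
    return records


def read_ortholog_table(path, focal_species: str | None = None) -> list[OrthologGroup]:
    """Read a TSV mapping each focal gene to its per-species ortholog ids.

    Header: the focal gene id column first, then one column per species;
    empty cells mean "no ortholog identified".  The focal species defaults to
    the first species column.  Promoters are attached separately with
    :func:`resolve_promoters`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("ortholog table needs a focal column plus species columns", path=path)
    species_cols = list(df.columns[1:])
    if focal_species is None:
        focal_species = species_cols[0]
    if focal_species not in species_cols:
        raise FormatError(f"unknown focal species column {focal_species!r}", path=path)
    focal_col = df.columns[0]
    dup = df[focal_col][df[focal_col].duplicated()]
    if not dup.empty:
        raise FormatError(f"duplicate focal gene id(s) {sorted(set(dup))}", path=path)
    groups = []
    for _, row in df.iterrows():
        gene_ids = {sp: row[sp] for sp in species_cols if row[sp] != ""}
        groups.append(
            OrthologGroup(
                focal_gene_id=row[focal_col],
                focal_species=focal_species,
                gene_ids=gene_ids,
            )
        )
    return groups


def resolve_promoters(
    groups: list[OrthologGroup],
    promoters_by_species: dict[str, dict[str, PromoterRecord]],
) -> list[OrthologGroup]:
    """Attach extracted promoters to ortholog groups (in place; returns groups)."""
    for grp in groups:
        for sp, gid in grp.gene_ids.items():
            rec = promoters_by_species.get(sp, {}).get(gid)
            if rec is not None:
                if rec.gene_id != gid:
                    raise InputError(
                        f"promoter gene id {rec.gene_id!r} does not match mapping {gid!r}"
                    )
                grp.promoters[sp] = rec
    return groups


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression table (gene_id, comparison, log2fc, pvalue)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "comparison", "log2fc", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"DE table missing column(s) {sorted(missing)}", path=path)
    if ((df["pvalue"] < 0) | (df["pvalue"] > 1)).any():
        raise FormatError("p-values outside [0, 1]", path=path)
    if df.duplicated(subset=["gene_id", "comparison"]).any():
        raise FormatError("duplicate (gene, comparison) rows", path=path)
    return df


def read_counts(path, metadata_path=None) -> CountsMatrix:
    """Read a counts TSV: gene_id, length, then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id" or "length" not in df.columns[:2]:
        raise FormatError("counts table must start with gene_id, length columns", path=path)
    df = df.set_index("gene_id")
    lengths = df["length"].astype(float)
    counts = df.drop(columns=["length"])
    meta = pd.read_csv(metadata_path, sep="\t") if metadata_path else None
    return CountsMatrix(counts=counts, lengths=lengths, metadata=meta)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_promoters_fasta(records: list[PromoterRecord], path) -> None:
    """Write promoters as FASTA with structured ``gene|species|...`` headers."""
    with open(path, "w") as fh:
        for rec in records:
            header = (
                f"{rec.gene_id}|{rec.species_id}|len={rec.actual_length}"
                f"|truncated={int(rec.truncated)}"
            )
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def hits_to_frame(hits) -> pd.DataFrame:
    """Anchored signed-offset table of motif hits."""
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "species_id": h.species_id,
                "offset": h.offset,
                "strand": h.strand,
                "matched": h.matched,
            }
            for h in hits
        ],
        columns=["gene_id", "species_id", "offset", "strand", "matched"],
    )


def hits_to_bed(hits, promoter_lengths: dict[str, int]) -> pd.DataFrame:
    """BED-like table: promoter-local 0-based half-open coordinates per gene."""
    rows = []
    for h in hits:
        L = promoter_lengths[h.gene_id]
        start = L + h.offset
        rows.append(
            {
                "chrom": h.gene_id,
                "start": start,
                "end": start + len(h.matched),
                "name": h.matched,
                "score": 0,
                "strand": h.strand,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
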