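"""End-to-end orchestration: selection -> promoters -> scan -> conservation.

The pipeline sequences the stages on files, persists every intermediate as
TSV/JSON, and writes a manifest echoing every parameter (the positional
window and threshold defaults are analysis choices and must be visible in
outputs).  A one-command synthetic demonstration (:func:`make_demo`) builds a
12-species fixture with planted motifs and known truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conservation as cons
from . import expression as expr
from . import io as cio
from . import motif as cmotif
from . import synthetic as syn
from .errors import CladescanError, InputError

logger = logging.getLogger(__name__)

DEFAULT_MOTIFS = ["ATGCA", "CGGAT", "CGGCTT"]


class StageError(CladescanError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (all paths must exist)."""

    genomes: dict[str, str]  # species -> FASTA path
    annotations: dict[str, str]  # species -> GFF3 path
    ortholog_table: str
    de_table: str
    outdir: str
    focal_species: str
    counts: str | None = None
    promoter_length: int = 1000
    p_max: float = expr.DEFAULT_P_MAX
    lfc_min: float = expr.DEFAULT_LFC_MIN
    comparisons: list[str] = field(default_factory=list)
    direction: str = "up"
    motifs: list[str] = field(default_factory=lambda: list(DEFAULT_MOTIFS))
    presence_threshold: float = cons.DEFAULT_PRESENCE_THRESHOLD
    position_window: int = cons.DEFAULT_POSITION_WINDOW
    min_orthologs: int = cons.DEFAULT_MIN_ORTHOLOGS
    cluster_genes: list[str] = field(default_factory=list)
    kmin: int = 5
    kmax: int = 6
    min_cluster_fraction: float = 0.8
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p):
            return str((base / p)) if p and not Path(p).is_absolute() else p

        raw["genomes"] = {sp: resolve(p) for sp, p in raw["genomes"].items()}
        raw["annotations"] = {sp: resolve(p) for sp, p in raw["annotations"].items()}
        for key in ("ortholog_table", "de_table", "counts", "outdir"):
            if raw.get(key):
                raw[key] = resolve(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        paths = list(self.genomes.values()) + list(self.annotations.values())
        paths += [self.ortholog_table, self.de_table]
        if self.counts:
            paths.append(self.counts)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise InputError(f"missing input file(s): {missing}")
        if set(self.genomes) != set(self.annotations):
            raise InputError("genomes and annotations must cover the same species")
        if self.focal_species not in self.genomes:
            raise InputError(f"focal species {self.focal_species!r} has no genome")
        if not self.comparisons:
            raise InputError("at least one comparison id is required")
        if not self.motifs:
            raise InputError("at least one motif is required")
        if not 0 < self.presence_threshold <= 1:
            raise InputError("presence_threshold must be in (0, 1]")
        if self.position_window < 0 or self.min_orthologs < 1:
            raise InputError("position_window must be >= 0 and min_orthologs >= 1")


@dataclass
class RunManifest:
    """Provenance of one run: parameters, input checksums, stage counts."""

    parameters: dict
    input_checksums: dict[str, str]
    stage_counts: dict[str, int]
    version: str
    timestamp: str
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every stage in order; outputs land in ``config.outdir``.

    Identical config and inputs give byte-identical outputs, except the
    manifest's timestamp field and the run log's timings.  Stage failures
    abort with the failing stage named; partial outputs and the manifest are
    retained.
    """
    from . import __version__

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("cladescan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    params = asdict(config)
    # Manifest paths are recorded as basenames so reruns in different
    # directories stay byte-comparable; checksums pin the actual content.
    params["genomes"] = {sp: Path(p).name for sp, p in config.genomes.items()}
    params["annotations"] = {sp: Path(p).name for sp, p in config.annotations.items()}
    for key in ("ortholog_table", "de_table", "counts", "outdir"):
        if params.get(key):
            params[key] = Path(params[key]).name
    checksums = {}
    for label, p in [("ortholog_table", config.ortholog_table), ("de_table", config.de_table)]:
        checksums[label] = _sha256(p)
    for sp, p in config.genomes.items():
        checksums[f"genome:{sp}"] = _sha256(p)
    for sp, p in config.annotations.items():
        checksums[f"annotations:{sp}"] = _sha256(p)
    if config.counts:
        checksums["counts"] = _sha256(config.counts)

    stage_counts: dict[str, int] = {}
    manifest = RunManifest(
        parameters=params,
        input_checksums=checksums,
        stage_counts=stage_counts,
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def finish(stage: str | None = None):
        manifest.failed_stage = stage
        (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
        root.removeHandler(handler)
        handler.close()

    stage = "select"
    try:
        t0 = time.perf_counter()
        de = cio.read_de_table(config.de_table)
        sets = [
            expr.select_regulated(
                de, cmp, direction=config.direction,
                p_max=config.p_max, lfc_min=config.lfc_min,
            )
            for cmp in config.comparisons
        ]
        combined: list[str] = []
        for s in sets:
            for g in s.genes:
                if g not in combined:
                    combined.append(g)
        regulated = expr.GeneSet(
            comparison="+".join(config.comparisons),
            direction=config.direction,
            genes=tuple(combined),
        )
        (outdir / "gene_sets.json").write_text(
            json.dumps(expr.gene_sets_to_manifest(sets), indent=2, sort_keys=True) + "\n"
        )
        (outdir / "selected_genes.txt").write_text("".join(g + "\n" for g in combined))
        if len(sets) >= 2:
            ov = expr.overlap_summary(sets)
            ov_json = {
                "exclusive": {"+".join(sorted(k)): v for k, v in ov.exclusive.items()},
                "intersections": {
                    "+".join(sorted(k)): v for k, v in ov.intersections.items()
                },
            }
            (outdir / "overlaps.json").write_text(
                json.dumps(ov_json, indent=2, sort_keys=True) + "\n"
            )
        stage_counts["genes_selected"] = len(regulated)
        logger.info("select: %d genes in %.2fs", len(regulated), time.perf_counter() - t0)

        stage = "extract"
        t0 = time.perf_counter()
        promoters_by_species: dict[str, dict[str, cio.PromoterRecord]] = {}
        all_records = []
        for sp in sorted(config.genomes):
            genome = cio.read_genome_fasta(config.genomes[sp])
            anns = cio.read_annotations_gff3(config.annotations[sp], species_id=sp)
            recs = cio.extract_promoters(genome, anns, length=config.promoter_length)
            promoters_by_species[sp] = {r.gene_id: r for r in recs}
            all_records.extend(recs)
        cio.write_promoters_fasta(all_records, outdir / "promoters.fasta")
        focal_promoters = promoters_by_species.get(config.focal_species, {})
        n_with_prom = sum(1 for g in regulated.genes if g in focal_promoters)
        stage_counts["promoters_extracted"] = len(all_records)
        stage_counts["regulated_with_promoter"] = n_with_prom
        logger.info(
            "extract: %d promoters, %d regulated genes with a focal promoter (%.2fs)",
            len(all_records), n_with_prom, time.perf_counter() - t0,
        )

        stage = "orthologs"
        t0 = time.perf_counter()
        groups = cio.read_ortholog_table(
            config.ortholog_table, focal_species=config.focal_species
        )
        cio.resolve_promoters(groups, promoters_by_species)
        groups_by_gene = {g.focal_gene_id: g for g in groups}
        n_evaluable = sum(
            1
            for g in regulated.genes
            if g in focal_promoters
            and g in groups_by_gene
            and groups_by_gene[g].n_collected >= config.min_orthologs
        )
        stage_counts["ortholog_groups"] = len(groups)
        stage_counts["regulated_evaluable"] = n_evaluable
        logger.info(
            "orthologs: %d groups, %d evaluable regulated genes (%.2fs)",
            len(groups), n_evaluable, time.perf_counter() - t0,
        )

        stage = "scan"
        t0 = time.perf_counter()
        hits = []
        repeat_rows = []
        for gname in regulated.genes:
            rec = focal_promoters.get(gname)
            if rec is None or not rec.sequence:
                continue
            for pattern in config.motifs:
                m = cmotif.Motif(pattern)
                if len(m) > rec.actual_length:
                    continue
                gene_hits = cmotif.scan(rec, m, both_strands=True)
                hits.extend(gene_hits)
                if gene_hits:
                    rc = cmotif.count_repeats(gene_hits, m)
                    repeat_rows.append(
                        {"gene_id": rc.gene_id, "motif": rc.motif, "count": rc.count}
                    )
        _write_tsv(cio.hits_to_frame(hits), outdir / "hits.tsv")
        lengths = {g: focal_promoters[g].actual_length for g in regulated.genes
                   if g in focal_promoters}
        _write_tsv(cio.hits_to_bed(hits, lengths), outdir / "hits.bed")
        _write_tsv(
            pd.DataFrame(repeat_rows, columns=["gene_id", "motif", "count"]),
            outdir / "repeat_counts.tsv",
        )
        stage_counts["motif_hits"] = len(hits)
        logger.info("scan: %d hits (%.2fs)", len(hits), time.perf_counter() - t0)

        stage = "conserve"
        t0 = time.perf_counter()
        rows, calls, missing = cons.summarize_motifs(
            regulated,
            focal_promoters,
            groups,
            config.motifs,
            presence_threshold=config.presence_threshold,
            position_window=config.position_window,
            min_orthologs=config.min_orthologs,
        )
        _write_tsv(cons.calls_to_frame(calls), outdir / "conservation_calls.tsv")
        _write_tsv(cons.summary_to_frame(rows), outdir / "motif_summary.tsv")
        summary_json = {
            "parameters": {
                "presence_threshold": config.presence_threshold,
                "position_window": config.position_window,
                "min_orthologs": config.min_orthologs,
                "promoter_length": config.promoter_length,
                "p_max": config.p_max,
                "lfc_min": config.lfc_min,
            },
            "denominators": {
                "regulated_with_promoter": rows[0].n_with_promoter,
                "evaluable_groups": rows[0].n_evaluable,
            },
            "missing_promoters": missing,
            "rows": [asdict(r) for r in rows],
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary_json, indent=2, sort_keys=True) + "\n"
        )
        stage_counts["conservation_calls"] = len(calls)
        logger.info("conserve: %d calls (%.2fs)", len(calls), time.perf_counter() - t0)

        stage = "discover"
        if config.cluster_genes:
            t0 = time.perf_counter()
            cluster = [groups_by_gene[g] for g in config.cluster_genes if g in groups_by_gene]
            discovered = cmotif.discover_conserved_kmers(
                cluster,
                kmin=config.kmin,
                kmax=config.kmax,
                min_cluster_fraction=config.min_cluster_fraction,
                presence_threshold=config.presence_threshold,
                position_window=config.position_window,
                min_orthologs=config.min_orthologs,
            )
            disc_rows = []
            for d in discovered:
                row = {
                    "kmer": d.kmer,
                    "score": d.score,
                    "background_occurrences": d.background_occurrences,
                }
                row.update({f"call:{g}": int(v) for g, v in d.calls.items()})
                disc_rows.append(row)
            _write_tsv(pd.DataFrame(disc_rows), outdir / "discovered_motifs.tsv")
            stage_counts["discovered_motifs"] = len(discovered)
            logger.info(
                "discover: %d motifs (%.2fs)", len(discovered), time.perf_counter() - t0
            )

        stage = "normalize"
        if config.counts:
            t0 = time.perf_counter()
            cm = cio.read_counts(config.counts)
            tpm = expr.compute_tpm(cm)
            fpkm = expr.compute_fpkm(cm)
            tpm.to_csv(outdir / "tpm.tsv", sep="\t")
            fpkm.to_csv(outdir / "fpkm.tsv", sep="\t")
            heat_genes = [g for g in regulated.genes if g in fpkm.index]
            if heat_genes:
                heat = expr.row_normalize(fpkm.loc[heat_genes], method="zscore")
                heat.to_csv(outdir / "heatmap_zscore.tsv", sep="\t")
            stage_counts["normalized_genes"] = int(tpm.shape[0])
            logger.info("normalize: %d genes (%.2fs)", tpm.shape[0], time.perf_counter() - t0)
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        finish(stage)
        raise StageError(stage, exc) from exc

    finish(None)
    return manifest


# ---------------------------------------------------------------------------
# Synthetic demonstration fixture
# ---------------------------------------------------------------------------

def make_demo(outdir, seed: int = 0, n_regulated: int = 150, n_genes: int = 300):
    """Build a ready-to-run 12-species fixture with known planted truth.

    The fixture emulates the study's layout: a five-gene cluster whose
    promoters carry all three motifs in every species, a regulated gene set
    with the lead motif planted at high per-species presence, background-only
    null genes, a two-comparison DE table with known regulated ids, and a
    counts matrix.  Returns ``(config_path, truth)`` where ``truth`` maps
    gene ids to their :class:`~cladescan.synthetic.PlantTruth`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_species = 12
    L = 1000
    sps = syn.species_ids(n_species)
    focal = sps[0]

    width = max(4, len(str(n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    cluster_genes = genes[:5]
    regulated_genes = genes[:n_regulated]

    # Funnel tails, scaled to fixture size: a few regulated genes lack a
    # promoter entirely, a few more have too few orthologs to be evaluable.
    n_missing = n_regulated // 30
    n_low_ortho = n_regulated // 30
    promoterless = set(regulated_genes[-n_missing:]) if n_missing else set()
    low_ortho = set(
        regulated_genes[-(n_missing + n_low_ortho) : len(regulated_genes) - n_missing]
    ) if n_low_ortho else set()
    in_genome = [g for g in regulated_genes if g not in promoterless]
    in_genome += genes[n_regulated : n_regulated + min(15, n_genes - n_regulated)]

    # motif -> (anchor offset, per-species presence probability)
    plant_plan = {
        "ATGCA": (-200, 0.9),
        "CGGAT": (-350, 0.5),
        "CGGCTT": (-500, 0.25),
    }

    species_layout: dict[str, list[syn.FixtureGene]] = {sp: [] for sp in sps}
    ortho_rows = []
    truth: dict[str, dict] = {}
    for gene in in_genome:
        if gene in cluster_genes:
            present = list(sps)
        else:
            n_present = int(rng.integers(9, 13))
            if gene in low_ortho:  # below the evaluability minimum
                n_present = int(rng.integers(3, 8))
            others = [sp for sp in sps[1:]]
            rng.shuffle(others)
            present = [focal] + sorted(others[: n_present - 1])
        gene_truth = {}
        for sp in present:
            seq = syn.generate_promoter(L, 0.5, rng)
            planted = {}
            if gene in regulated_genes:
                for pattern, (anchor, prob) in plant_plan.items():
                    always = gene in cluster_genes
                    if always or rng.random() < prob:
                        jitter = int(round(rng.normal(0.0, 30.0)))
                        off = int(np.clip(anchor + jitter, -L, -len(pattern)))
                        strand = "+" if rng.random() < 0.5 else "-"
                        seq = syn.plant_motif(seq, pattern, off, strand)
                        planted[pattern] = off
                if gene in cluster_genes:  # lead motif occurs in 2-4 repeats
                    extra = int(rng.integers(1, 4))
                    for j in range(extra):
                        off = int(np.clip(-700 - 60 * j, -L, -5))
                        seq = syn.plant_motif(seq, "ATGCA", off, "+")
            gene_truth[sp] = planted
            strand = "+" if rng.random() < 0.5 else "-"
            species_layout[sp].append(
                syn.FixtureGene(gene_id=f"{gene}_{sp}", promoter=seq, strand=strand)
            )
        truth[gene] = gene_truth
        ortho_rows.append(
            {"gene": gene, **{sp: (f"{gene}_{sp}" if sp in present else "") for sp in sps}}
        )

    genome_paths, ann_paths = {}, {}
    for sp in sps:
        prefix = outdir / f"genome_{sp}"
        fasta, gff = syn.write_fixture_genome(
            species_layout[sp], prefix, seed=int(rng.integers(0, 2**31))
        )
        genome_paths[sp] = Path(fasta).name
        ann_paths[sp] = Path(gff).name

    # Focal gene ids in the ortholog table are the focal species' gene ids.
    for row in ortho_rows:
        row["gene"] = f"{row['gene']}_{focal}"
    ortho_df = pd.DataFrame(ortho_rows, columns=["gene"] + sps)
    ortho_df.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)

    # DE tables: regulated ids must be the focal-species gene ids so selection
    # joins cleanly with extracted promoters.
    focal_ids = [f"{g}_{focal}" for g in genes]
    ery, _ = syn.generate_de_table(
        n_genes, n_regulated, p_alt_shape=0.001, lfc_alt_mean=4.0,
        seed=int(rng.integers(0, 2**31)), comparison="ery_33h", gene_ids=focal_ids,
    )
    # The second comparison regulates a subset of the first (partial overlap).
    shift = n_regulated // 3
    glc_order = focal_ids[shift:n_regulated] + focal_ids[:shift] + focal_ids[n_regulated:]
    glc, _ = syn.generate_de_table(
        n_genes, n_regulated - shift, p_alt_shape=0.001, lfc_alt_mean=4.0,
        seed=int(rng.integers(0, 2**31)), comparison="glc_33h", gene_ids=glc_order,
    )
    # The demo's planted world is an up-regulated set: fold the simulated
    # regulated effects onto the positive side.
    ery.loc[: n_regulated - 1, "log2fc"] = ery.loc[: n_regulated - 1, "log2fc"].abs()
    glc.loc[: n_regulated - shift - 1, "log2fc"] = glc.loc[
        : n_regulated - shift - 1, "log2fc"
    ].abs()
    de = pd.concat([ery, glc], ignore_index=True)
    de.to_csv(outdir / "de_table.tsv", sep="\t", index=False)

    # Counts: regulated genes high in the regulator-functional strain.
    samples = [f"{strain}_{med}_r{r}" for strain in ("MK1", "K1")
               for med in ("ery", "glc") for r in (1, 2)]
    lengths = rng.integers(500, 2500, size=n_genes)
    lam = np.full((n_genes, len(samples)), 50.0)
    for i, g in enumerate(genes):
        if g in set(regulated_genes):
            for j, s in enumerate(samples):
                if s.startswith("MK1"):
                    lam[i, j] = 400.0
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, columns=samples)
    counts_df.insert(0, "length", lengths)
    counts_df.insert(0, "gene_id", focal_ids)
    counts_df.to_csv(outdir / "counts.tsv", sep="\t", index=False)

    config = {
        "genomes": genome_paths,
        "annotations": ann_paths,
        "ortholog_table": "orthologs.tsv",
        "de_table": "de_table.tsv",
        "counts": "counts.tsv",
        "outdir": "results",
        "focal_species": focal,
        "promoter_length": L,
        "comparisons": ["ery_33h", "glc_33h"],
        "direction": "up",
        "motifs": list(DEFAULT_MOTIFS),
        "cluster_genes": [f"{g}_{focal}" for g in cluster_genes],
        "seed": int(seed),
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path, truth
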