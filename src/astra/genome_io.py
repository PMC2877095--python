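"""Domain types and I/O for gene models, probe signals, small-RNA signatures,
hairpins and gold-standard miRNA/target pairs.

All internal coordinates are 0-based half-open. GFF3 (1-based closed) is
converted at the read boundary; BED12 is native. Tabular formats are plain TSV
with a header, and every writer emits the dialect its reader accepts, so
write -> read round-trips are exact at field level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger("astra")

#: log2 signal threshold separating expressed probes from promoter background.
DEFAULT_SIGNAL_CUTOFF = 0.73

#: default C-fraction above which a probe is treated as amplification-artifact
#: prone and removed. Configurable; the artifact is documented upstream but no
#: published cutoff exists.
DEFAULT_MAX_C_FRACTION = 0.40

Interval = tuple[int, int]


class ParseError(ValueError):
    """Raised for malformed records in any of the supported file formats."""


def _check_interval(iv: Interval, what: str) -> None:
    if iv[0] >= iv[1]:
        raise ValueError(f"{what}: interval start must be < end, got {iv}")


@dataclass
class GeneModel:
    """An annotated gene: strand, exon structure and class tags.

    Introns are derived, not stored: they are exactly the gaps between
    consecutive exons. Class tags carry gene-class membership used by the
    enrichment analysis (e.g. ``ribosomal``, ``target``, ``unknown``,
    ``star:0`` .. ``star:5``, ``sORF``, ``as-TU``, ``as-smRNA``, ``qRT-PCR``).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    class_tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene with zero exons rejected")
        self.exons = sorted(tuple(e) for e in self.exons)
        for e in self.exons:
            _check_interval(e, self.gene_id)
        for a, b in zip(self.exons, self.exons[1:]):
            if b[0] < a[1]:
                raise ValueError(f"{self.gene_id}: overlapping exons {a}, {b}")

    @property
    def introns(self) -> list[Interval]:
        return [
            (a[1], b[0])
            for a, b in zip(self.exons, self.exons[1:])
            if b[0] > a[1]
        ]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class ProbeSignalTable:
    """Strand-specific log2 probe signals across samples.

    ``frame`` holds one row per probe with columns ``probe_id, chrom, start,
    end, strand, sequence`` followed by one float column per sample name in
    ``samples``. Missing signals are NaN.
    """

    frame: pd.DataFrame
    samples: list[str]
    signal_cutoff: float = DEFAULT_SIGNAL_CUTOFF

    META_COLUMNS = ["probe_id", "chrom", "start", "end", "strand", "sequence"]

    def __post_init__(self) -> None:
        if self.signal_cutoff <= 0:
            raise ValueError("signal_cutoff must be > 0")
        missing = [c for c in self.META_COLUMNS + self.samples
                   if c not in self.frame.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        if ((self.frame["end"] - self.frame["start"]) <= 0).any():
            raise ValueError("every probe must have positive length")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_sequences(self) -> bool:
        return self.frame["sequence"].notna().all() and len(self.frame) > 0


@dataclass
class SmallRNASignature:
    """One distinct small-RNA sequence with genomic matches and library counts.

    ``locations`` lists perfect genomic matches as (chrom, start, end, strand);
    ``genome_hits`` is their count (a signature may carry hits without explicit
    locations when only the count is known).
    """

    seq: str
    genome_hits: int
    counts: dict[str, int]
    library_sizes: dict[str, int]
    phosphate_class: str = "unknown"
    locations: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("T", "U")
        if self.genome_hits < 1:
            raise ValueError("genome_hits must be >= 1")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.phosphate_class not in ("mono", "tri", "unknown"):
            raise ValueError(f"bad phosphate_class {self.phosphate_class!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class Hairpin:
    """A miRNA hairpin: sequence plus miRNA and miRNA* sub-intervals.

    The two sub-intervals define the normalized topology axis (miRNA start
    maps to 0, miRNA* start to 1). ``genomic_placement`` locates the hairpin
    on the genome as (chrom, start, end, strand).
    """

    hairpin_id: str
    seq: str
    mirna_interval: Interval
    mirstar_interval: Interval
    genomic_placement: tuple[str, int, int, str]

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("T", "U")
        n = len(self.seq)
        for name, iv in (("miRNA", self.mirna_interval),
                         ("miRNA*", self.mirstar_interval)):
            _check_interval(iv, f"{self.hairpin_id} {name}")
            if iv[0] < 0 or iv[1] > n:
                raise ValueError(f"{self.hairpin_id}: {name} interval {iv} "
                                 f"outside hairpin of length {n}")
        a, b = self.mirna_interval, self.mirstar_interval
        if not (a[1] <= b[0] or b[1] <= a[0]):
            raise ValueError(f"{self.hairpin_id}: miRNA and miRNA* overlap")
        if a[0] == b[0]:
            raise ValueError(f"{self.hairpin_id}: identical arm starts")


@dataclass
class GoldPair:
    """A gold-standard (miRNA, gene) pair with class label.

    Targets carry the validated binding-site interval; paralog pseudo-targets
    carry a mock site; *MIRNA*-gene entries use the miRNA* site and are grouped
    ``mirna_ancient`` / ``mirna_new``. ``site_seq`` is the sense-strand target
    sequence at the site, used for duplex-energy features.
    """

    mirna_id: str
    mirna_seq: str
    gene_id: str
    site_chrom: str
    site_interval: Interval
    site_seq: str
    label: int
    group: str

    VALID_GROUPS = ("target", "paralog", "mirna_ancient", "mirna_new")

    def __post_init__(self) -> None:
        self.mirna_seq = self.mirna_seq.upper().replace("T", "U")
        self.site_seq = self.site_seq.upper().replace("T", "U")
        if self.group not in self.VALID_GROUPS:
            raise ValueError(f"bad group {self.group!r}")
        if self.label not in (+1, -1):
            raise ValueError("label must be +1 or -1")
        if self.group == "paralog" and self.label != -1:
            raise ValueError("paralogs carry label -1")
        if self.group == "target" and self.label != +1:
            raise ValueError("targets carry label +1")
        _check_interval(self.site_interval, f"{self.mirna_id}/{self.gene_id}")


# ---------------------------------------------------------------------------
# Gene model I/O
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (``.gff``/``.gff3``) or BED12 (``.bed``).

    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    Class tags are taken from a ``class_tags`` attribute (GFF3, comma
    separated) when present.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _read_bed12(path)
    return _read_gff3(path)


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises various internal errors
        raise ParseError(f"{path}: failed to parse GFF3 ({exc})") from exc

    genes = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.children(gene, featuretype="exon")
        )
        if not exons:
            # single-feature gene records double as their own exon
            exons = [(gene.start - 1, gene.end)]
        tags: set[str] = set()
        if "class_tags" in gene.attributes:
            for v in gene.attributes["class_tags"]:
                tags.update(t for t in v.split(",") if t)
        genes.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            exons=_merge_adjacent(exons), class_tags=tags,
        ))
    return genes


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns, "
                                 f"got {len(fields)}")
            try:
                chrom, start = fields[0], int(fields[1])
                name, strand = fields[3], fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            exons = [(start + s, start + s + sz)
                     for s, sz in zip(starts, sizes)]
            genes.append(GeneModel(name, chrom, strand, exons))
    return genes


def write_gene_models_bed12(genes: Iterable[GeneModel],
                            path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e[1] - e[0]) for e in g.exons)
            starts = ",".join(str(e[0] - g.start) for e in g.exons)
            fh.write("\t".join(map(str, [
                g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                g.start, g.end, "0,0,0", len(g.exons), sizes, starts,
            ])) + "\n")


def write_gene_classes(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write a two-column gene_id -> comma-joined class tags TSV."""
    with open(path, "w") as fh:
        fh.write("gene_id\tclass_tags\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{','.join(sorted(g.class_tags))}\n")


def read_gene_classes(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {
        r.gene_id: set(t for t in r.class_tags.split(",") if t)
        for r in df.itertuples()
    }


def _merge_adjacent(exons: list[Interval]) -> list[Interval]:
    """Merge book-ended/overlapping exon records from multi-isoform GFF3."""
    merged: list[Interval] = []
    for s, e in exons:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# Probe table I/O
# ---------------------------------------------------------------------------

def read_probe_table(path: str | Path,
                     signal_cutoff: float = DEFAULT_SIGNAL_CUTOFF
                     ) -> ProbeSignalTable:
    df = pd.read_csv(path, sep="\t")
    meta = ProbeSignalTable.META_COLUMNS
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    samples = [c for c in df.columns if c not in meta]
    return ProbeSignalTable(df, samples, signal_cutoff)


def write_probe_table(table: ProbeSignalTable, path: str | Path) -> None:
    cols = ProbeSignalTable.META_COLUMNS + table.samples
    table.frame[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Small-RNA signature I/O
# ---------------------------------------------------------------------------

def _fmt_locations(locs: list[tuple[str, int, int, str]]) -> str:
    return ";".join(f"{c}:{s}-{e}:{st}" for c, s, e, st in locs)


def _parse_locations(txt: str) -> list[tuple[str, int, int, str]]:
    out = []
    if not txt:
        return out
    for tok in txt.split(";"):
        chrom, span, strand = tok.rsplit(":", 2)
        s, e = span.split("-")
        out.append((chrom, int(s), int(e), strand))
    return out


def read_smrna_table(path: str | Path) -> list[SmallRNASignature]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    libraries = sorted(
        {c[len("count_"):] for c in df.columns if c.startswith("count_")}
    )
    sigs = []
    for r in df.itertuples():
        counts = {lib: int(getattr(r, f"count_{lib}")) for lib in libraries}
        sizes = {lib: int(getattr(r, f"libsize_{lib}")) for lib in libraries}
        sigs.append(SmallRNASignature(
            seq=r.sequence,
            genome_hits=int(r.genome_hits),
            counts=counts,
            library_sizes=sizes,
            phosphate_class=r.phosphate_class or "unknown",
            locations=_parse_locations(r.locations),
        ))
    return sigs


def write_smrna_table(sigs: Sequence[SmallRNASignature],
                      path: str | Path) -> None:
    libraries = sorted({lib for s in sigs for lib in s.counts})
    cols = (["sequence", "genome_hits", "phosphate_class", "locations"]
            + [f"count_{l}" for l in libraries]
            + [f"libsize_{l}" for l in libraries])
    rows = []
    for s in sigs:
        row = [s.seq, s.genome_hits, s.phosphate_class,
               _fmt_locations(s.locations)]
        row += [s.counts.get(l, 0) for l in libraries]
        row += [s.library_sizes.get(l, 0) for l in libraries]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hairpin I/O (FASTA sequence + TSV coordinates)
# ---------------------------------------------------------------------------

def read_hairpins(fasta_path: str | Path,
                  coords_path: str | Path) -> list[Hairpin]:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path),
                                                        "fasta")}
    df = pd.read_csv(coords_path, sep="\t")
    hairpins = []
    for r in df.itertuples():
        if r.hairpin_id not in seqs:
            raise ParseError(f"{coords_path}: hairpin {r.hairpin_id} "
                             f"missing from FASTA")
        hairpins.append(Hairpin(
            hairpin_id=r.hairpin_id,
            seq=seqs[r.hairpin_id],
            mirna_interval=(int(r.mirna_start), int(r.mirna_end)),
            mirstar_interval=(int(r.mirstar_start), int(r.mirstar_end)),
            genomic_placement=(r.chrom, int(r.start), int(r.end), r.strand),
        ))
    return hairpins


def write_hairpins(hairpins: Sequence[Hairpin], fasta_path: str | Path,
                   coords_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        for hp in hairpins:
            fh.write(f">{hp.hairpin_id}\n{hp.seq}\n")
    rows = [
        (hp.hairpin_id, hp.mirna_interval[0], hp.mirna_interval[1],
         hp.mirstar_interval[0], hp.mirstar_interval[1],
         *hp.genomic_placement)
        for hp in hairpins
    ]
    pd.DataFrame(rows, columns=[
        "hairpin_id", "mirna_start", "mirna_end", "mirstar_start",
        "mirstar_end", "chrom", "start", "end", "strand",
    ]).to_csv(coords_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gold-pair I/O
# ---------------------------------------------------------------------------

def read_gold_pairs(path: str | Path) -> list[GoldPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        GoldPair(
            mirna_id=r.mirna_id, mirna_seq=r.mirna_seq, gene_id=r.gene_id,
            site_chrom=r.site_chrom,
            site_interval=(int(r.site_start), int(r.site_end)),
            site_seq=r.site_seq, label=int(r.label), group=r.group,
        )
        for r in df.itertuples()
    ]


def write_gold_pairs(pairs: Sequence[GoldPair], path: str | Path) -> None:
    rows = [
        (p.mirna_id, p.mirna_seq, p.gene_id, p.site_chrom,
         p.site_interval[0], p.site_interval[1], p.site_seq, p.label, p.group)
        for p in pairs
    ]
    pd.DataFrame(rows, columns=[
        "mirna_id", "mirna_seq", "gene_id", "site_chrom", "site_start",
        "site_end", "site_seq", "label", "group",
    ]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Probe filtering and probe-to-gene assignment
# ---------------------------------------------------------------------------

def filter_c_rich_probes(
    table: ProbeSignalTable,
    max_c_fraction: float = DEFAULT_MAX_C_FRACTION,
) -> tuple[ProbeSignalTable, pd.DataFrame]:
    """Drop probes whose cytosine fraction exceeds ``max_c_fraction``.

    C-rich probes are prone to a sample-amplification artifact and are removed
    before any signal statistics. Returns the filtered table and a report of
    removed probes. If sequences are unavailable the filter is skipped with a
    warning and the table returned unchanged.
    """
    if not (0 < max_c_fraction <= 1):
        raise ValueError("max_c_fraction must be in (0, 1]")
    if not table.has_sequences:
        logger.warning("probe sequences absent; C-rich filter skipped")
        return table, table.frame.iloc[0:0]
    seqs = table.frame["sequence"].str.upper()
    c_frac = seqs.str.count("C") / seqs.str.len()
    removed = table.frame[c_frac > max_c_fraction]
    kept = table.frame[c_frac <= max_c_fraction].reset_index(drop=True)
    logger.info("C-rich filter removed %d of %d probes (C fraction > %.2f)",
                len(removed), len(table.frame), max_c_fraction)
    return (ProbeSignalTable(kept, table.samples, table.signal_cutoff),
            removed)


def _overlap_len(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def assign_probes(table: ProbeSignalTable,
                  genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Assign each probe to a unique overlapping gene, region and orientation.

    Orientation is ``sense`` when probe and gene strands agree. Region is
    ``exon`` when the probe's overlap with the exon union is at least its
    overlap with the intron union (ties go to exon), else ``intron``. Probes
    overlapping more than one gene are flagged non-unique and excluded from
    per-gene statistics; probes overlapping none get no assignment.

    Returns a DataFrame with columns ``probe_id, gene_id, orientation,
    region, unique`` containing one row per gene-overlapping probe. The result
    is independent of input ordering.
    """
    trees: dict[str, IntervalTree] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start, g.end, g.gene_id)

    rows = []
    frame = table.frame
    for probe_id, chrom, start, end, strand in zip(
            frame["probe_id"], frame["chrom"], frame["start"],
            frame["end"], frame["strand"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = sorted(iv.data for iv in tree.overlap(start, end))
        if not hits:
            continue
        if len(hits) > 1:
            for gid in hits:
                rows.append((probe_id, gid, "", "", False))
            continue
        g = gene_by_id[hits[0]]
        orientation = "sense" if strand == g.strand else "antisense"
        exon_ov = sum(_overlap_len((start, end), e) for e in g.exons)
        intron_ov = sum(_overlap_len((start, end), i) for i in g.introns)
        region = "exon" if exon_ov >= intron_ov else "intron"
        rows.append((probe_id, g.gene_id, orientation, region, True))

    out = pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "orientation", "region",
                       "unique"],
    )
    return out.sort_values(["probe_id", "gene_id"]).reset_index(drop=True)
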