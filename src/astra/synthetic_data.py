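"""Synthetic genomes, tiling-probe signals, small-RNA libraries and gold sets.

The generator reproduces the statistical structure the downstream analysis
assumes, so every stage is testable without array or sequencing data:

* genes with exon/intron structure and class tags, a subset designated miRNA
  targets with embedded binding sites complementary to generated 21-nt miRNAs,
  and paralog pseudo-targets whose sites are shuffled away;
* hairpin loci whose miRNA* arm is the reverse complement of the miRNA with a
  controlled number of mismatches, split into an "ancient" group (ping-pong
  expression topology, abundant small RNAs) and a "new" group (a lone signal
  peak at the miRNA* anchor, sparse small RNAs);
* strand-specific log2 probe signals: class-dependent exon/intron/antisense
  means plus a ping-pong term (sense boost downstream of the binding site,
  antisense boost upstream) and Gaussian noise;
* negative-binomial small-RNA counts across the five libraries (FLR, RDR,
  SD1, SD2 and a pooled pyrosequencing set), with antisense signature density
  on hairpins biased 5' of the miRNA* site.

Everything is driven by one integer seed through numpy's seed-sequence
spawning, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    GeneModel,
    GoldPair,
    Hairpin,
    ProbeSignalTable,
    SmallRNASignature,
    write_gene_models_bed12,
    write_gene_classes,
    write_gold_pairs,
    write_hairpins,
    write_probe_table,
    write_smrna_table,
)

RNA = "ACGU"
_COMP = str.maketrans("ACGU", "UGCA")

#: the five tiling-array biological samples: three plant parts plus two
#: independent suspension-cultured callus lines.
DEFAULT_SAMPLES = ["flower", "leaf", "root", "callus1", "callus2"]

DEFAULT_LIBRARIES = {"FLR": 250_000, "RDR": 250_000, "SD1": 250_000,
                     "SD2": 250_000, "P454": 250_000}

#: libraries treated as the pooled pyrosequencing feature rather than MPSS.
PYRO_LIBRARIES = ("P454",)


def revcomp(seq: str) -> str:
    return seq.upper().replace("T", "U").translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Signal means are on the log2 scale, matching how tiling-array signal is
    stored and summarized. ``antisense_exon_mu`` maps gene-class name to the
    class's mean antisense exon signal ("default" covers the rest): classes
    with genuinely antisense-transcribed loci sit above the default, highly
    expressed protein-coding classes below it, which is what places them in
    the low / high halves of the sense:antisense ranking.
    """

    seed: int = 7
    n_genes: int = 200
    class_mix: dict[str, float] = field(default_factory=lambda: {
        "ribosomal": 0.10, "target": 0.15, "paralog": 0.15,
        "unknown_star0": 0.10, "unknown_star1": 0.10,
        "unknown_star4": 0.10, "unknown_star5": 0.10,
        "protein_coding": 0.20,
    })
    n_hairpins_ancient: int = 12
    n_hairpins_new: int = 12
    probe_length: int = 25
    probe_spacing: int = 25
    flank: int = 800
    samples: list[str] = field(default_factory=lambda: list(DEFAULT_SAMPLES))
    sense_exon_mu: float = 4.0
    antisense_exon_mu: dict[str, float] = field(default_factory=lambda: {
        "default": 1.0, "ribosomal": 0.4, "target": 2.5,
        "unknown_star0": 2.0, "unknown_star1": 1.8,
        "unknown_star4": 0.8, "unknown_star5": 0.8,
    })
    intron_mu: float = 1.0
    background_mu: float = 0.2
    noise_sd: float = 0.25
    pingpong_effect: float = 1.5
    smrna_dispersion: float = 5.0          # negative-binomial size
    smrna_count_mu: float = 20.0           # mean raw count per signature/lib
    smrna_per_target: int = 8              # signatures per target gene
    smrna_per_ancient: int = 20            # signatures per ancient hairpin
    smrna_per_new: int = 3                 # signatures per new hairpin
    mirstar_bias: float = 3.0
    mismatches_ancient: int = 1
    mismatches_new: int = 4
    library_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LIBRARIES))

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if self.noise_sd < 0 or self.smrna_dispersion <= 0:
            raise ValueError("noise_sd must be >= 0, dispersion > 0")
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library sizes must be > 0")

    def rng(self, stage: int) -> np.random.Generator:
        """A stage-scoped child generator of the run seed."""
        return np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(stage,)))


def allocate_class_counts(mix: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n genes to classes (deterministic)."""
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    items = sorted(mix.items())
    counts = {k: math.floor(p * n) for k, p in items}
    leftover = n - sum(counts.values())
    by_frac = sorted(items, key=lambda kv: (-(kv[1] * n % 1), kv[0]))
    for k, _ in by_frac[:leftover]:
        counts[k] += 1
    return counts


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(RNA[i] for i in rng.integers(0, 4, size=length))


def _mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    """Introduce exactly k substitutions at distinct positions."""
    s = list(seq)
    for pos in rng.choice(len(s), size=k, replace=False):
        s[pos] = rng.choice([b for b in RNA if b != s[pos]])
    return "".join(s)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SimConfig,
) -> tuple[list[GeneModel], list[Hairpin], list[GoldPair]]:
    """Generate genes, hairpins and the gold-standard pair set.

    Gene loci are laid out non-overlapping with enough intergenic space that
    no probe (gene body plus flank) can touch two genes. Each target gene
    embeds a 21-nt binding site perfectly complementary to its miRNA inside
    an exon; each paralog copies a target layout but carries a mock site
    whose nucleotides are shuffled until the Hamming distance to the cognate
    complement is at least 8.
    """
    rng = config.rng(0)
    counts = allocate_class_counts(config.class_mix, config.n_genes)

    class_of: list[str] = []
    for cls in sorted(counts):
        class_of += [cls] * counts[cls]
    rng.shuffle(class_of)

    gap = 2 * config.flank + 400
    chroms = [f"chr{i}" for i in range(1, 6)]
    cursor = {c: 1000 for c in chroms}

    genes: list[GeneModel] = []
    gold: list[GoldPair] = []
    target_sites: list[tuple[str, GeneModel, str, tuple[int, int]]] = []

    n_targets = counts.get("target", 0)
    mirnas = [(f"miR{i + 1:03d}", _random_seq(rng, 21))
              for i in range(max(n_targets, 1))]

    for idx, cls in enumerate(class_of):
        chrom = chroms[idx % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 9))
        start = cursor[chrom]
        exons = []
        pos = start
        for j in range(n_exons):
            exon_len = int(rng.integers(150, 401))
            exons.append((pos, pos + exon_len))
            pos += exon_len
            if j < n_exons - 1:
                pos += int(rng.integers(80, 301))
        cursor[chrom] = pos + gap
        tags = _class_tags(cls)
        gene = GeneModel(f"G{idx + 1:04d}", chrom, strand, exons, tags)
        genes.append(gene)

        if cls == "target":
            mir_id, mir_seq = mirnas[len(target_sites) % len(mirnas)]
            exon = exons[int(rng.integers(0, len(exons)))]
            if exon[1] - exon[0] < 61:
                exon = max(exons, key=lambda e: e[1] - e[0])
            off = int(rng.integers(20, exon[1] - exon[0] - 41))
            site = (exon[0] + off, exon[0] + off + 21)
            site_seq = revcomp(mir_seq)
            gold.append(GoldPair(mir_id, mir_seq, gene.gene_id, chrom,
                                 site, site_seq, +1, "target"))
            target_sites.append((mir_id, gene, mir_seq, site))

    # paralogs reuse target layouts with shuffled (ablated) sites
    paralog_genes = [g for g in genes if "paralog" in g.class_tags]
    for i, gene in enumerate(paralog_genes):
        if not target_sites:
            break
        mir_id, _, mir_seq, _ = target_sites[i % len(target_sites)]
        exon = max(gene.exons, key=lambda e: e[1] - e[0])
        off = int(rng.integers(20, exon[1] - exon[0] - 41))
        site = (exon[0] + off, exon[0] + off + 21)
        perfect = revcomp(mir_seq)
        mock = perfect
        while _hamming(mock, perfect) < 8:
            mock = "".join(rng.permutation(list(perfect)))
        gold.append(GoldPair(mir_id, mir_seq, gene.gene_id, gene.chrom,
                             site, mock, -1, "paralog"))

    hairpins, hp_gold = _simulate_hairpins(config, rng)
    return genes, hairpins, gold + hp_gold


def _class_tags(cls: str) -> set[str]:
    tags = {cls}
    if cls.startswith("unknown_star"):
        tags.add("unknown")
        tags.add(f"star:{cls[-1]}")
    return tags


def _simulate_hairpins(
    config: SimConfig, rng: np.random.Generator,
) -> tuple[list[Hairpin], list[GoldPair]]:
    hairpins: list[Hairpin] = []
    gold: list[GoldPair] = []
    cursor = 1000
    groups = (["mirna_ancient"] * config.n_hairpins_ancient
              + ["mirna_new"] * config.n_hairpins_new)
    for i, group in enumerate(groups):
        mir_seq = _random_seq(rng, 21)
        n_mm = (config.mismatches_ancient if group == "mirna_ancient"
                else config.mismatches_new)
        star_seq = _mutate(rng, revcomp(mir_seq), n_mm)
        loop = _random_seq(rng, 30)
        lead, tail = _random_seq(rng, 10), _random_seq(rng, 10)
        seq = lead + mir_seq + loop + star_seq + tail
        mirna_iv = (len(lead), len(lead) + 21)
        mirstar_iv = (len(lead) + 21 + len(loop),
                      len(lead) + 21 + len(loop) + 21)
        placement = ("chrH", cursor, cursor + len(seq), "+")
        cursor += len(seq) + 2 * config.flank + 400
        hp_id = f"HP{i + 1:03d}"
        hairpins.append(Hairpin(hp_id, seq, mirna_iv, mirstar_iv, placement))
        site = (placement[1] + mirstar_iv[0], placement[1] + mirstar_iv[1])
        gold.append(GoldPair(f"hp-miR{i + 1:03d}", mir_seq, hp_id, "chrH",
                             site, star_seq, +1, group))
    return hairpins, gold


# ---------------------------------------------------------------------------
# Probe signal simulation
# ---------------------------------------------------------------------------

def _tile(start: int, end: int, config: SimConfig):
    for s in range(start, end - config.probe_length + 1,
                   config.probe_spacing):
        yield s, s + config.probe_length


def simulate_probe_signals(
    genes: Sequence[GeneModel],
    gold: Sequence[GoldPair],
    config: SimConfig,
    hairpins: Sequence[Hairpin] = (),
) -> ProbeSignalTable:
    """Tile every locus (gene or hairpin, plus flanks) on both strands and
    draw per-sample log2 signals.

    Signal = class mean for the probe's (orientation, region) cell, plus the
    ping-pong term for target genes and ancient hairpins (sense boost
    downstream of the binding-site anchor, antisense boost upstream, windowed
    to the flank width), plus Gaussian noise. New hairpins instead get a lone
    sense peak on probes overlapping the miRNA* anchor.
    """
    rng = config.rng(1)
    site_of = {p.gene_id: p for p in gold}

    rows = []
    means = []

    def emit_locus(locus_id, chrom, start, end, strand, exons, cls):
        pair = site_of.get(locus_id)
        anchor = None
        pingpong = False
        new_peak = False
        if pair is not None:
            anchor = (pair.site_interval[0] + pair.site_interval[1]) // 2
            if pair.group in ("target", "mirna_ancient"):
                pingpong = True
            elif pair.group == "mirna_new":
                new_peak = True
        anti_mu = config.antisense_exon_mu.get(
            cls, config.antisense_exon_mu["default"])
        for ps, pe in _tile(start - config.flank, end + config.flank,
                            config):
            for pstrand in "+-":
                orient_sense = pstrand == strand
                ov_exon = sum(max(0, min(pe, e) - max(ps, s))
                              for s, e in exons)
                inside = start <= ps and pe <= end
                if ov_exon > 0:
                    mu = config.sense_exon_mu if orient_sense else anti_mu
                elif inside:
                    mu = config.intron_mu
                else:
                    mu = config.background_mu
                center = (ps + pe) // 2
                if anchor is not None and abs(center - anchor) <= config.flank:
                    downstream = (center >= anchor) == (strand == "+")
                    if pingpong and (orient_sense == downstream):
                        mu += config.pingpong_effect
                    if new_peak and orient_sense and \
                            max(0, min(pe, pair.site_interval[1])
                                - max(ps, pair.site_interval[0])) > 0:
                        mu += config.pingpong_effect
                rows.append((f"p_{chrom}_{ps}_{pstrand}", chrom, ps, pe,
                             pstrand, None))
                means.append(mu)

    for g in genes:
        cls = next((t for t in g.class_tags
                    if t in config.class_mix), "protein_coding")
        emit_locus(g.gene_id, g.chrom, g.start, g.end, g.strand,
                   g.exons, cls)
    for hp in hairpins:
        chrom, start, end, strand = hp.genomic_placement
        emit_locus(hp.hairpin_id, chrom, start, end, strand,
                   [(start, end)], "default")

    frame = pd.DataFrame(
        rows, columns=["probe_id", "chrom", "start", "end", "strand",
                       "sequence"])
    mu_arr = np.asarray(means, dtype=float)
    for sample in config.samples:
        noise = (rng.normal(0.0, config.noise_sd, size=len(mu_arr))
                 if config.noise_sd > 0 else 0.0)
        frame[sample] = mu_arr + noise
    # fill probe sequences so the C-rich filter is exercisable
    seq_rng = config.rng(3)
    frame["sequence"] = [
        _random_seq(seq_rng, config.probe_length).replace("U", "T")
        for _ in range(len(frame))
    ]
    return ProbeSignalTable(frame, list(config.samples))


# ---------------------------------------------------------------------------
# Small-RNA library simulation
# ---------------------------------------------------------------------------

def simulate_smrna_libraries(
    genes: Sequence[GeneModel],
    hairpins: Sequence[Hairpin],
    gold: Sequence[GoldPair],
    config: SimConfig,
) -> list[SmallRNASignature]:
    """Draw small-RNA signatures for target genes and hairpin loci.

    Counts are negative binomial (size ``smrna_dispersion``, locus-specific
    mean). Hairpin signatures take their sequence verbatim from the hairpin
    (reverse complement for antisense reads), so exact-substring matching
    recovers them; antisense start positions 5' of the miRNA* site are
    weighted ``mirstar_bias``-fold relative to downstream positions.
    Signature lengths are drawn from {17, 21, 24}. Loci with zero small-RNA
    mean (paralogs, plain protein-coding genes) produce no signatures.
    """
    rng = config.rng(2)
    sigs: list[SmallRNASignature] = []
    gene_by_id = {g.gene_id: g for g in genes}
    lengths = np.array([17, 21, 24])

    def nb_counts() -> dict[str, int]:
        size = config.smrna_dispersion
        p = size / (size + config.smrna_count_mu)
        return {lib: int(rng.negative_binomial(size, p))
                for lib in config.library_sizes}

    def draw_length() -> int:
        return int(lengths[rng.integers(0, len(lengths))])

    for pair in gold:
        if pair.group == "target":
            gene = gene_by_id[pair.gene_id]
            lo = max(gene.start, pair.site_interval[0] - config.flank)
            hi = min(gene.end, pair.site_interval[1] + config.flank)
            for _ in range(config.smrna_per_target):
                ln = draw_length()
                s = int(rng.integers(lo, max(lo + 1, hi - ln)))
                strand = "+" if rng.random() < 0.5 else "-"
                sigs.append(SmallRNASignature(
                    seq=_random_seq(rng, ln), genome_hits=1,
                    counts=nb_counts(),
                    library_sizes=dict(config.library_sizes),
                    phosphate_class="mono" if rng.random() < 0.5 else "tri",
                    locations=[(gene.chrom, s, s + ln, strand)],
                ))

    for hp in hairpins:
        group = next((p.group for p in gold if p.gene_id == hp.hairpin_id),
                     "mirna_new")
        n_sigs = (config.smrna_per_ancient if group == "mirna_ancient"
                  else config.smrna_per_new)
        chrom, hstart, _, _ = hp.genomic_placement
        star_start = hp.mirstar_interval[0]
        for _ in range(n_sigs):
            ln = draw_length()
            antisense = rng.random() < 0.5
            n_pos = len(hp.seq) - ln + 1
            if antisense and config.mirstar_bias != 1.0:
                w = np.ones(n_pos)
                w[:min(star_start, n_pos)] *= config.mirstar_bias
                w /= w.sum()
                start = int(rng.choice(n_pos, p=w))
            else:
                start = int(rng.integers(0, n_pos))
            subseq = hp.seq[start:start + ln]
            seq = revcomp(subseq) if antisense else subseq
            sigs.append(SmallRNASignature(
                seq=seq, genome_hits=1, counts=nb_counts(),
                library_sizes=dict(config.library_sizes),
                phosphate_class="mono" if rng.random() < 0.5 else "tri",
                locations=[(chrom, hstart + start, hstart + start + ln,
                            "-" if antisense else "+")],
            ))
    return sigs


# ---------------------------------------------------------------------------
# Whole-simulation convenience
# ---------------------------------------------------------------------------

@dataclass
class Simulation:
    config: SimConfig
    genes: list[GeneModel]
    hairpins: list[Hairpin]
    gold: list[GoldPair]
    probes: ProbeSignalTable
    smrnas: list[SmallRNASignature]


def simulate(config: SimConfig | None = None, **overrides) -> Simulation:
    """Run the full generator and return all artifacts in memory."""
    config = replace(config or SimConfig(), **overrides)
    genes, hairpins, gold = simulate_genome(config)
    probes = simulate_probe_signals(genes, gold, config, hairpins)
    smrnas = simulate_smrna_libraries(genes, hairpins, gold, config)
    return Simulation(config, genes, hairpins, gold, probes, smrnas)


def save_simulation(sim: Simulation, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact in the standard dialects; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.bed",
        "classes": outdir / "gene_classes.tsv",
        "probes": outdir / "probes.tsv",
        "smrnas": outdir / "smrnas.tsv",
        "hairpin_fasta": outdir / "hairpins.fa",
        "hairpin_coords": outdir / "hairpins.tsv",
        "gold": outdir / "gold_pairs.tsv",
    }
    write_gene_models_bed12(sim.genes, paths["genes"])
    write_gene_classes(sim.genes, paths["classes"])
    write_probe_table(sim.probes, paths["probes"])
    write_smrna_table(sim.smrnas, paths["smrnas"])
    write_hairpins(sim.hairpins, paths["hairpin_fasta"],
                   paths["hairpin_coords"])
    write_gold_pairs(sim.gold, paths["gold"])
    return paths
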