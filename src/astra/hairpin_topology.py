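"""Small-RNA topology on miRNA hairpins and hairpin-region probe statistics.

Signatures are mapped onto hairpins by exact substring matching (sense) or
exact matching of the reverse complement (antisense), with match positions
expressed on a normalized axis where the first nucleotide of the mature miRNA
is 0 and the first nucleotide of the miRNA* is 1. Tiling probes overlapping a
hairpin are assigned to one of four regions (miRNA, miRNA*, other small RNAs,
no small RNA) by contiguous-overlap rules, and each region's signal is
compared to the pooled no-smRNA probes with an equal-variance two-tailed
t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import Hairpin, Interval, ProbeSignalTable, SmallRNASignature
from .synthetic_data import revcomp

#: minimum contiguous probe overlap (nt) with a 21-nt miRNA or miRNA* site
MIN_MIRNA_OVERLAP = 11
#: minimum contiguous probe overlap (nt) with a 17-nt MPSS signature site
MIN_MPSS_OVERLAP = 7

QUARTER_MILLION = 250_000


def tpq(count: int, library_size: int) -> float:
    """Transcripts per quarter-million reads: count * 250000 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count * QUARTER_MILLION / library_size


def total_tpq(sig: SmallRNASignature) -> float:
    """Summed TPQ of one signature across all its libraries."""
    return sum(tpq(c, sig.library_sizes[lib])
               for lib, c in sig.counts.items())


@dataclass
class SignatureMatch:
    """One placement of a signature on a hairpin, in sense coordinates."""

    signature: SmallRNASignature
    hairpin: Hairpin
    start: int
    orientation: str  # sense | antisense
    norm_pos: float
    tpq: float


def match_signature(sig: SmallRNASignature,
                    hp: Hairpin) -> list[SignatureMatch]:
    """All perfect matches of a signature on a hairpin.

    Sense matches are exact substrings of the hairpin; antisense matches are
    exact substrings of its reverse complement, reported by the start of the
    matched region in hairpin (sense) coordinates. A signature longer than
    the hairpin yields no matches.
    """
    if len(sig.seq) > len(hp.seq):
        return []
    out = []
    abundance = total_tpq(sig)
    for orientation, query in (("sense", sig.seq),
                               ("antisense", revcomp(sig.seq))):
        pos = hp.seq.find(query)
        while pos != -1:
            m = SignatureMatch(sig, hp, pos, orientation, 0.0, abundance)
            m.norm_pos = normalize_position(m, hp)
            out.append(m)
            pos = hp.seq.find(query, pos + 1)
    return out


def normalize_position(match: SignatureMatch, hp: Hairpin) -> float:
    """Map a hairpin offset to the miRNA/miRNA* axis (miRNA start -> 0,
    miRNA* start -> 1). Affine in the raw coordinate, so shifting the whole
    hairpin leaves it unchanged."""
    m0 = hp.mirna_interval[0]
    s0 = hp.mirstar_interval[0]
    return (match.start - m0) / (s0 - m0)


def topology_profile(matches: Iterable[SignatureMatch],
                     unique_only: bool = True,
                     group_by: str = "orientation") -> pd.DataFrame:
    """Tabulate matches as (normalized position, log2 TPQ, group).

    ``unique_only`` keeps signatures with a single perfect genomic match.
    Matches with zero abundance are dropped (log2 undefined). ``group_by``
    is ``orientation`` or ``phosphate_class``.
    """
    if group_by not in ("orientation", "phosphate_class"):
        raise ValueError("group_by must be orientation or phosphate_class")
    rows = []
    for m in matches:
        if unique_only and m.signature.genome_hits != 1:
            continue
        if m.tpq <= 0:
            continue
        group = (m.orientation if group_by == "orientation"
                 else m.signature.phosphate_class)
        rows.append((m.norm_pos, math.log2(m.tpq), group))
    return pd.DataFrame(rows, columns=["norm_pos", "log2_tpq", group_by])


# ---------------------------------------------------------------------------
# Probe-region assignment on hairpins
# ---------------------------------------------------------------------------

def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def assign_probe_region(
    probe: Interval,
    hp_placement: Interval,
    mirna_site: Interval,
    mirstar_site: Interval,
    mpss_sites: Sequence[Interval] = (),
) -> str | None:
    """Assign a hairpin-overlapping probe to one region (genomic intervals).

    miRNA or miRNA* require >= 11 contiguous nt of overlap; MPSS signature
    sites require >= 7. When both arm rules fire, the larger overlap wins
    and ties go to miRNA. Probes not overlapping the hairpin get ``None``;
    overlapping probes matching no site are ``no_smRNA``, so regions
    partition the hairpin-overlapping probes.
    """
    if _overlap(probe, hp_placement) == 0:
        return None
    ov_mi = _overlap(probe, mirna_site)
    ov_star = _overlap(probe, mirstar_site)
    if ov_mi >= MIN_MIRNA_OVERLAP and ov_star >= MIN_MIRNA_OVERLAP:
        return "miRNA" if ov_mi >= ov_star else "miRNA*"
    if ov_mi >= MIN_MIRNA_OVERLAP:
        return "miRNA"
    if ov_star >= MIN_MIRNA_OVERLAP:
        return "miRNA*"
    if any(_overlap(probe, s) >= MIN_MPSS_OVERLAP for s in mpss_sites):
        return "other_smRNA"
    return "no_smRNA"


def assign_hairpin_probes(
    probes: ProbeSignalTable,
    hairpins: Sequence[Hairpin],
    gold_sites: dict[str, Interval] | None = None,
    mpss_sites_by_hairpin: dict[str, list[Interval]] | None = None,
) -> pd.DataFrame:
    """Assign every probe overlapping some hairpin to a region.

    ``gold_sites`` optionally overrides the miRNA-site genomic interval per
    hairpin (defaults derive both arm sites from the hairpin placement).
    Returns columns ``probe_id, hairpin_id, region, orientation``.
    """
    rows = []
    frame = probes.frame
    for hp in hairpins:
        chrom, hstart, hend, hstrand = hp.genomic_placement
        mirna_site = (hstart + hp.mirna_interval[0],
                      hstart + hp.mirna_interval[1])
        mirstar_site = (hstart + hp.mirstar_interval[0],
                        hstart + hp.mirstar_interval[1])
        mpss = (mpss_sites_by_hairpin or {}).get(hp.hairpin_id, [])
        sel = frame[(frame["chrom"] == chrom)
                    & (frame["end"] > hstart) & (frame["start"] < hend)]
        for r in sel.itertuples():
            region = assign_probe_region(
                (r.start, r.end), (hstart, hend), mirna_site, mirstar_site,
                mpss)
            if region is None:
                continue
            orientation = "sense" if r.strand == hstrand else "antisense"
            rows.append((r.probe_id, hp.hairpin_id, region, orientation))
    return pd.DataFrame(
        rows, columns=["probe_id", "hairpin_id", "region", "orientation"])


@dataclass
class RegionSignalSummary:
    """Mean log2 signal per probe for one (region, orientation) cell, with a
    two-sample equal-variance two-tailed t-test against the pooled no-smRNA
    probes."""

    region: str
    orientation: str
    mean_log2_per_probe: float
    n_probes: int
    t_statistic: float
    p_value: float
    test_computable: bool


def region_signal_table(
    assignments: pd.DataFrame,
    probes: ProbeSignalTable,
) -> list[RegionSignalSummary]:
    """Summarize probe signal by hairpin region and orientation.

    Each probe contributes its mean log2 signal across samples. Every
    (region, orientation) cell is compared to the pooled no-smRNA probes
    (both orientations combined) with Student's equal-variance two-tailed
    t-test; cells where either group has fewer than two probes carry the
    mean but are flagged not computable.
    """
    frame = probes.frame.set_index("probe_id")
    per_probe = frame[probes.samples].mean(axis=1)
    merged = assignments.copy()
    merged["signal"] = per_probe.reindex(merged["probe_id"]).to_numpy()
    baseline = merged.loc[merged["region"] == "no_smRNA", "signal"].dropna()

    out = []
    for (region, orientation), grp in merged.groupby(
            ["region", "orientation"], sort=True):
        vals = grp["signal"].dropna()
        n = len(vals)
        mean = float(vals.mean()) if n else float("nan")
        computable = n >= 2 and len(baseline) >= 2 and region != "no_smRNA"
        if computable:
            t, p = stats.ttest_ind(vals, baseline, equal_var=True)
            t, p = float(t), float(p)
        else:
            t, p = float("nan"), float("nan")
        out.append(RegionSignalSummary(region, orientation, mean, n, t, p,
                                       computable))
    return out


# ---------------------------------------------------------------------------
# Averaged strand profiles around anchor sites
# ---------------------------------------------------------------------------

@dataclass
class LocusAnchor:
    """A locus with the genomic anchor its profile window is centred on:
    the miRNA* start for hairpin loci, the binding-site start for targets."""

    locus_id: str
    chrom: str
    anchor: int
    strand: str


def averaged_strand_profile(
    loci: Sequence[LocusAnchor],
    probes: ProbeSignalTable,
    window: int = 800,
    bin_size: int = 25,
) -> pd.DataFrame:
    """Summed position-wise normalized expression per strand around anchors.

    For each locus and sample, the signals of probes within ``window`` of
    the anchor (both strands, log2 values clipped below at zero so absent
    signal contributes nothing) are normalized to sum to 1, then summed
    position-wise across loci and samples. Offsets are transcript-relative
    (minus-strand loci flipped) and binned at ``bin_size``. Samples in which
    a locus has an all-zero window are skipped for that locus. Returns
    columns ``offset, strand, value`` where strand is sense/antisense
    relative to the locus.
    """
    frame = probes.frame
    centers = (frame["start"] + frame["end"]) // 2
    acc: dict[tuple[int, str], float] = {}
    for locus in loci:
        mask = ((frame["chrom"] == locus.chrom)
                & ((centers - locus.anchor).abs() <= window))
        sel = frame[mask]
        if sel.empty:
            continue
        offs = (centers[mask] - locus.anchor).to_numpy()
        if locus.strand == "-":
            offs = -offs
        offs = (np.floor_divide(offs + window, bin_size) * bin_size
                - window)
        sense = (sel["strand"] == locus.strand).to_numpy()
        for sample in probes.samples:
            lin = np.maximum(sel[sample].to_numpy(dtype=float), 0.0)
            lin = np.nan_to_num(lin, nan=0.0)
            tot = lin.sum()
            if tot <= 0:
                continue
            lin = lin / tot
            for off, is_sense, v in zip(offs, sense, lin):
                key = (int(off), "sense" if is_sense else "antisense")
                acc[key] = acc.get(key, 0.0) + float(v)
    rows = sorted(acc.items())
    return pd.DataFrame(
        [(off, strand, val) for (off, strand), val in rows],
        columns=["offset", "strand", "value"])
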