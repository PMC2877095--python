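"""The 136-value feature encoding for the miRNA-target classifier.

Per (miRNA, gene) pair:

* 130 expression-topology features: probe signals in a +/-800 bp window
  around the binding site, binned at 25 bp on each strand (65 bins x 2
  strands), summed on the linear scale per sample, normalized so the
  130-vector sums to 1 per sample, then averaged across samples;
* 5 small-RNA features: summed TPQ of genome-unique signatures overlapping
  the locus, one per MPSS library (FLR, RDR, SD1, SD2) plus the pooled
  pyrosequencing sum;
* 1 thermodynamic feature: percent minimum free energy, the ratio of the
  miRNA:site duplex free energy to the energy of the miRNA bound to its
  perfect complement, from a nearest-neighbor duplex dynamic program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GoldPair, ProbeSignalTable, SmallRNASignature
from .hairpin_topology import tpq
from .synthetic_data import PYRO_LIBRARIES, revcomp

WINDOW = 800
BIN_SIZE = 25
N_BINS = WINDOW * 2 // BIN_SIZE + 1        # 65: [-800, +800] inclusive
N_EXPR = 2 * N_BINS                        # 130
MPSS_LIBRARIES = ("FLR", "RDR", "SD1", "SD2")

EXPR_COLUMNS = ([f"expr_sense_{i:02d}" for i in range(N_BINS)]
                + [f"expr_anti_{i:02d}" for i in range(N_BINS)])
SMRNA_COLUMNS = [f"smrna_{lib}" for lib in MPSS_LIBRARIES] + ["smrna_P454"]
FEATURE_COLUMNS = EXPR_COLUMNS + SMRNA_COLUMNS + ["energy"]

FEATURE_SUBSETS = {
    "expr": EXPR_COLUMNS,
    "smrna": SMRNA_COLUMNS,
    "energy": ["energy"],
}


# ---------------------------------------------------------------------------
# Expression topology
# ---------------------------------------------------------------------------

def expression_topology_features(
    pair: GoldPair,
    probes: ProbeSignalTable,
    gene_strand: str = "+",
    window: int = WINDOW,
    bin_size: int = BIN_SIZE,
) -> np.ndarray:
    """The 130-bin strand-specific expression vector around the site.

    Bin i covers [-window + bin_size*i, -window + bin_size*(i+1)) of
    transcript-relative offset from the site anchor (the site midpoint),
    with the final bin closed at +window. Per sample, linear-scale signals
    (2**log2) are summed per bin, the full two-strand vector is normalized
    to sum to 1, and vectors are averaged across samples. Empty bins are 0;
    a window without probes in every sample yields the all-zero vector.
    """
    n_bins = window * 2 // bin_size + 1
    frame = probes.frame
    anchor = (pair.site_interval[0] + pair.site_interval[1]) // 2
    centers = (frame["start"] + frame["end"]) // 2
    mask = ((frame["chrom"] == pair.site_chrom)
            & ((centers - anchor).abs() <= window))
    sel = frame[mask]
    if sel.empty:
        return np.zeros(2 * n_bins)
    offs = (centers[mask] - anchor).to_numpy()
    if gene_strand == "-":
        offs = -offs
    idx = np.minimum((offs + window) // bin_size, n_bins - 1).astype(int)
    sense = (sel["strand"] == gene_strand).to_numpy()

    acc = np.zeros(2 * n_bins)
    n_used = 0
    for sample in probes.samples:
        lin = np.exp2(sel[sample].to_numpy(dtype=float))
        lin = np.nan_to_num(lin, nan=0.0)
        vec = np.zeros(2 * n_bins)
        np.add.at(vec, np.where(sense, idx, idx + n_bins), lin)
        total = vec.sum()
        if total <= 0:
            continue
        acc += vec / total
        n_used += 1
    return acc / n_used if n_used else acc


# ---------------------------------------------------------------------------
# Small-RNA counts
# ---------------------------------------------------------------------------

def smrna_count_features(
    pair: GoldPair,
    signatures: Sequence[SmallRNASignature],
    libraries: Sequence[str] = MPSS_LIBRARIES,
    pooled: Sequence[str] = PYRO_LIBRARIES,
    window: int = WINDOW,
) -> np.ndarray:
    """Summed TPQ of genome-unique signatures overlapping the pair's locus.

    One value per MPSS library plus the pooled pyrosequencing sum; both
    strands count. Loci without signatures give zeros.
    """
    lo = pair.site_interval[0] - window
    hi = pair.site_interval[1] + window
    out = np.zeros(len(libraries) + 1)
    for sig in signatures:
        if sig.genome_hits != 1:
            continue
        if not any(chrom == pair.site_chrom and s < hi and e > lo
                   for chrom, s, e, _ in sig.locations):
            continue
        for i, lib in enumerate(libraries):
            if lib in sig.counts:
                out[i] += tpq(sig.counts[lib], sig.library_sizes[lib])
        for lib in pooled:
            if lib in sig.counts:
                out[-1] += tpq(sig.counts[lib], sig.library_sizes[lib])
    return out


# ---------------------------------------------------------------------------
# Duplex free energy (nearest-neighbor dynamic program)
# ---------------------------------------------------------------------------

#: Watson-Crick nearest-neighbor stack free energies, kcal/mol at 37 C,
#: keyed by (top 5'->3' dinucleotide, bottom 3'->5' dinucleotide). The ten
#: unique values cover all sixteen WC stacks through the rotational symmetry
#: dG(XY/WZ) = dG(ZW/YX).
_WC_STACKS = {
    ("AA", "UU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08,
    ("CA", "GU"): -2.11,
    ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
}

#: flat stack value applied when either pair of the stack is a GU wobble
GU_STACK = -1.0

#: affine internal-loop/bulge penalty: init + per-unpaired-nucleotide term
LOOP_INIT = 3.0
LOOP_PER_NT = 0.5

_CANONICAL = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
              ("G", "U"), ("U", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def default_params() -> dict:
    """The built-in energy parameter set (copy; safe to modify)."""
    return {
        "wc_stacks": dict(_WC_STACKS),
        "gu_stack": GU_STACK,
        "loop_init": LOOP_INIT,
        "loop_per_nt": LOOP_PER_NT,
    }


def stack_energy(pair1: tuple[str, str], pair2: tuple[str, str],
                 params: Mapping | None = None) -> float:
    """Free energy of stacking pair2 directly 3' (on the top strand) of
    pair1. Pairs are (top base, bottom base); wobble-containing stacks take
    the flat GU value."""
    p = params or default_params()
    if pair1 in _WOBBLE or pair2 in _WOBBLE:
        return p["gu_stack"]
    key = (pair1[0] + pair2[0], pair1[1] + pair2[1])
    table = p["wc_stacks"]
    if key in table:
        return table[key]
    # rotational symmetry: dG(XY/WZ) = dG(ZW/YX)
    alt = (key[1][::-1], key[0][::-1])
    return table[alt]


def _validate_rna(seq: str, what: str) -> str:
    seq = seq.upper().replace("T", "U")
    if not seq:
        raise ValueError(f"{what}: empty sequence")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"{what}: invalid bases {sorted(bad)}")
    return seq


def pseudo_hairpin(target_site_seq: str, mirna_seq: str) -> str:
    """Join the target site to the miRNA with a seven-uridine linker, the
    construct used for reproducible duplex folding."""
    target = _validate_rna(target_site_seq, "target")
    mirna = _validate_rna(mirna_seq, "miRNA")
    return target + "U" * 7 + mirna


@dataclass
class DuplexEnergyResult:
    """Observed and perfect-complement duplex energies and their ratio."""

    dG_obs: float
    dG_perfect: float
    percent_mfe: float


def _duplex_min_energy(top: str, bottom3to5: str,
                       params: Mapping) -> float:
    """Minimum free energy of an antiparallel duplex of ``top`` (5'->3')
    with ``bottom3to5`` (given 3'->5', i.e. aligned index-wise with top).

    Pairs must be canonical (WC or GU). Consecutive pairs at adjacent
    indices contribute stack energies; interior unpaired stretches an affine
    loop penalty. A lone pair carries zero energy. Returns the minimum over
    all monotone pairings (always <= 0).
    """
    n, m = len(top), len(bottom3to5)
    loop_init = params["loop_init"]
    loop_nt = params["loop_per_nt"]
    INF = math.inf

    # E[i][j]: min energy of a duplex whose last (3'-most on top) pair is
    # (i, j). The affine loop cost init + per_nt*((i-ip-1)+(j-jp-1))
    # separates as (E[ip][jp] - per_nt*(ip+jp)) + init + per_nt*(i+j-2),
    # so a 2-D prefix minimum of the shifted energies G gives the best
    # loop predecessor in O(1) per cell.
    E = [[INF] * m for _ in range(n)]
    P = [[INF] * m for _ in range(n)]  # prefix min of G over [0..i]x[0..j]
    best = 0.0
    for i in range(n):
        ti = top[i]
        for j in range(m):
            bj = bottom3to5[j]
            if (ti, bj) in _CANONICAL:
                e = 0.0  # the pair alone
                if i > 0 and j > 0:
                    prev = E[i - 1][j - 1]
                    if prev < INF:
                        e = min(e, prev + stack_energy(
                            (top[i - 1], bottom3to5[j - 1]), (ti, bj),
                            params))
                    pm = P[i - 1][j - 1]
                    if pm < INF:
                        e = min(e, pm + loop_init + loop_nt * (i + j - 2))
                E[i][j] = e
                if e < best:
                    best = e
            g = E[i][j] - loop_nt * (i + j) if E[i][j] < INF else INF
            p = g
            if i > 0:
                p = min(p, P[i - 1][j])
            if j > 0:
                p = min(p, P[i][j - 1])
            P[i][j] = p
    return best


def duplex_energy(mirna_seq: str, target_seq: str,
                  params: Mapping | None = None) -> DuplexEnergyResult:
    """Percent minimum free energy of a miRNA bound to a target site.

    The observed duplex is the miRNA paired antiparallel to the target
    (GU wobble allowed, bulges/internal loops penalized affinely, dangling
    ends ignored); positive totals clip to zero. The reference duplex is the
    same miRNA on its exact reverse complement. percent_mfe is their ratio:
    1 for a perfect-complement target, 0 when no stabilizing duplex exists.
    """
    p = params or default_params()
    mirna = _validate_rna(mirna_seq, "miRNA")
    target = _validate_rna(target_seq, "target")
    # align index-wise: miRNA 5'->3' against target read 3'->5'
    dG_obs = min(0.0, _duplex_min_energy(mirna, target[::-1], p))
    perfect = revcomp(mirna)
    dG_perfect = _duplex_min_energy(mirna, perfect[::-1], p)
    if dG_perfect >= 0:
        raise ValueError("perfect-complement duplex must be stabilizing")
    return DuplexEnergyResult(dG_obs, dG_perfect, dG_obs / dG_perfect)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_features(
    pairs: Sequence[GoldPair],
    probes: ProbeSignalTable,
    signatures: Sequence[SmallRNASignature],
    strand_of: Mapping[str, str] | None = None,
    window: int = WINDOW,
    bin_size: int = BIN_SIZE,
) -> tuple[pd.DataFrame, pd.Series]:
    """Build the n x 136 feature matrix and the +/-1 label vector.

    Column order is fixed: 65 sense then 65 antisense expression bins, the
    four MPSS TPQ sums plus the pooled pyrosequencing sum, then percent
    minimum free energy. Rows are indexed ``mirna_id|gene_id`` in input
    order; ``strand_of`` maps gene_id to transcript strand (default '+').
    """
    strand_of = strand_of or {}
    rows, labels, index = [], [], []
    for pair in pairs:
        strand = strand_of.get(pair.gene_id, "+")
        expr = expression_topology_features(pair, probes, strand,
                                            window, bin_size)
        smrna = smrna_count_features(pair, signatures, window=window)
        energy = duplex_energy(pair.mirna_seq, pair.site_seq).percent_mfe
        rows.append(np.concatenate([expr, smrna, [energy]]))
        labels.append(pair.label)
        index.append(f"{pair.mirna_id}|{pair.gene_id}")
    X = pd.DataFrame(rows, columns=FEATURE_COLUMNS, index=index)
    y = pd.Series(labels, index=index, name="label")
    return X, y
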