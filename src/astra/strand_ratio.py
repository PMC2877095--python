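"""Genome-wide sense/antisense exon-signal ratio and class enrichment.

Each gene's ratio is built from per-probe mean log2 signals in the four
(orientation x region) cells:

    ratio = (sense_exon / antisense_exon) / (sense_intron / antisense_intron)

falling back to the exon-only quotient when intron terms are unavailable.
Genes are ranked ascending by ratio and split into low/high halves; a gene
class's over-representation in one half is tested with a one-tailed binomial
test (exact summation by default, normal approximation with continuity
correction as the alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import ProbeSignalTable

MEAN_COLUMNS = ["mean_sense_exon", "mean_anti_exon",
                "mean_sense_intron", "mean_anti_intron"]


def strand_means(assignment: pd.DataFrame,
                 probes: ProbeSignalTable) -> pd.DataFrame:
    """Per-gene mean log2 signal per probe in each orientation x region cell.

    Each probe contributes the arithmetic mean of its log2 signals across
    samples; cell means average those per-probe values. Only uniquely
    assigned probes count. Genes missing a sense-exon or antisense-exon
    probe are excluded, with the reason recorded.

    Returns a DataFrame indexed by gene_id with the four mean columns, the
    four probe counts (``n_*``) and an ``excluded_reason`` column (empty for
    retained genes).
    """
    frame = probes.frame.set_index("probe_id")
    per_probe = frame[probes.samples].mean(axis=1)
    assigned = assignment[assignment["unique"]].copy()
    assigned["signal"] = per_probe.reindex(assigned["probe_id"]).to_numpy()
    cell = (assigned
            .groupby(["gene_id", "orientation", "region"])["signal"]
            .agg(["mean", "count"]))

    rows = {}
    for gene_id, sub in cell.groupby(level="gene_id"):
        sub = sub.droplevel("gene_id")
        row: dict[str, float] = {}
        for col, key in zip(
                MEAN_COLUMNS + ["n_sense_exon", "n_anti_exon",
                                "n_sense_intron", "n_anti_intron"],
                [("sense", "exon"), ("antisense", "exon"),
                 ("sense", "intron"), ("antisense", "intron")] * 2):
            stat = "mean" if col.startswith("mean") else "count"
            row[col] = (sub.loc[key, stat] if key in sub.index
                        else (math.nan if stat == "mean" else 0))
        if row["n_sense_exon"] == 0 or row["n_anti_exon"] == 0:
            row["excluded_reason"] = "missing sense or antisense exon probes"
        else:
            row["excluded_reason"] = ""
        rows[gene_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out


def sense_antisense_ratio(row: Mapping[str, float]) -> tuple[float, str]:
    """Compute a gene's ratio from its four cell means.

    Returns ``(ratio, formula_used)``. The intron-normalized formula is
    primary; when either intron mean is missing or non-positive the exon-only
    quotient is used and recorded. A non-positive antisense exon mean leaves
    the ratio undefined (NaN, formula "undefined").
    """
    se, ae = row["mean_sense_exon"], row["mean_anti_exon"]
    si, ai = row.get("mean_sense_intron"), row.get("mean_anti_intron")
    if not np.isfinite(se) or not np.isfinite(ae) or ae <= 0:
        return math.nan, "undefined"
    exon_ratio = se / ae
    if (si is not None and ai is not None
            and np.isfinite(si) and np.isfinite(ai) and si > 0 and ai > 0):
        return exon_ratio / (si / ai), "full"
    return exon_ratio, "exon_only"


def ratio_table(means: pd.DataFrame) -> pd.DataFrame:
    """Attach ratio and formula columns; drop excluded/undefined genes."""
    kept = means[means["excluded_reason"] == ""].copy()
    ratios, formulas = [], []
    for _, row in kept.iterrows():
        r, f = sense_antisense_ratio(row)
        ratios.append(r)
        formulas.append(f)
    kept["ratio"] = ratios
    kept["formula_used"] = formulas
    return kept[kept["formula_used"] != "undefined"]


def rank_and_split(records: pd.DataFrame) -> pd.DataFrame:
    """Rank genes ascending by ratio and split into halves.

    Ties break on gene_id, so re-runs are identical. The first floor(n/2)
    genes form the low half, the last floor(n/2) the high half; with odd n
    the median gene is excluded.
    """
    if len(records) < 2:
        raise ValueError("need at least two ranked genes")
    out = records.copy()
    out["_gene_id"] = out.index
    out = out.sort_values(["ratio", "_gene_id"], kind="mergesort")
    out = out.drop(columns="_gene_id")
    n = len(out)
    half = n // 2
    out["rank"] = np.arange(1, n + 1)
    halves = np.array(["low"] * half
                      + ["excluded"] * (n - 2 * half)
                      + ["high"] * half, dtype=object)
    out["half"] = halves
    return out


def binomial_test(k_small: int, n: int, method: str = "exact") -> float:
    """One-tailed binomial p-value, P(X <= k_small) with X ~ Binomial(n, 1/2).

    ``exact`` sums the binomial tail; ``normal_approx`` applies the normal
    approximation with continuity correction, Phi((k + 0.5 - n/2)/sqrt(n/4)).
    Both are evaluated through log-space-capable scipy routines so extreme
    tails keep full floating-point range.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k_small <= n:
        raise ValueError("k_small must be within [0, n]")
    if method == "exact":
        return float(np.exp(stats.binom.logcdf(k_small, n, 0.5)))
    if method == "normal_approx":
        z = (k_small + 0.5 - n / 2) / math.sqrt(n / 4)
        return float(np.exp(stats.norm.logcdf(z)))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class EnrichmentResult:
    """Counts of one gene class in the low/high halves with the one-tailed
    binomial test of the observed imbalance."""

    class_tag: str
    count_low: int
    count_high: int
    ratio_low_high: float
    p_value: float
    method: str
    tail: str

    @property
    def empty(self) -> bool:
        return self.count_low + self.count_high == 0


def class_enrichment(
    class_tag: str,
    ranked: pd.DataFrame,
    classes: Mapping[str, set[str]],
    method: str = "exact",
) -> EnrichmentResult:
    """Count a class's members per half and test the imbalance.

    The tail is chosen by the observed majority side; the p-value tests the
    minority count against Binomial(n, 1/2).
    """
    members = [g for g in ranked.index if class_tag in classes.get(g, ())]
    low = int((ranked.loc[members, "half"] == "low").sum())
    high = int((ranked.loc[members, "half"] == "high").sum())
    return enrichment_from_counts(class_tag, low, high, method)


def enrichment_from_counts(class_tag: str, count_low: int, count_high: int,
                           method: str = "exact") -> EnrichmentResult:
    n = count_low + count_high
    ratio = count_low / count_high if count_high > 0 else math.nan
    if n == 0:
        return EnrichmentResult(class_tag, 0, 0, math.nan, math.nan,
                                method, "none")
    tail = "low-enriched" if count_low > count_high else "high-enriched"
    p = binomial_test(min(count_low, count_high), n, method)
    return EnrichmentResult(class_tag, count_low, count_high, ratio, p,
                            method, tail)


def enrichment_table(
    ranked: pd.DataFrame,
    classes: Mapping[str, set[str]],
    class_tags: Sequence[str],
    method: str = "exact",
) -> pd.DataFrame:
    rows = []
    for tag in class_tags:
        r = class_enrichment(tag, ranked, classes, method)
        rows.append((r.class_tag, r.count_low, r.count_high,
                     r.ratio_low_high, r.p_value, r.method, r.tail))
    return pd.DataFrame(rows, columns=[
        "class_tag", "count_low", "count_high", "ratio_low_high",
        "p_value", "method", "tail"])


def class_correlation(ordinals: Sequence[float],
                      low_frequencies: Sequence[float]) -> float:
    """Pearson r between class ordinal (e.g. star rating) and the class's
    low-half frequency. Returns NaN when either input has zero variance."""
    ordinals = np.asarray(ordinals, dtype=float)
    freqs = np.asarray(low_frequencies, dtype=float)
    if len(ordinals) < 3:
        raise ValueError("need at least three classes")
    if np.ptp(ordinals) == 0 or np.ptp(freqs) == 0:
        return math.nan
    r, _ = stats.pearsonr(ordinals, freqs)
    return float(r)
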