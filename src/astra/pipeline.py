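"""End-to-end orchestration: simulate -> ingest -> topology -> rank/enrich
-> features -> cv, with a manifest of inputs, outputs and timings.

Every stage reads its inputs from files in the run directory and writes TSV
outputs back to it, so any stage can be skipped when its inputs are supplied
externally. All randomness derives from the single run seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .genome_io import (
    filter_c_rich_probes,
    assign_probes,
    read_gene_classes,
    read_gene_models,
    read_gold_pairs,
    read_hairpins,
    read_probe_table,
    read_smrna_table,
)
from .synthetic_data import SimConfig, simulate, save_simulation
from .hairpin_topology import (
    LocusAnchor,
    assign_hairpin_probes,
    averaged_strand_profile,
    match_signature,
    region_signal_table,
    topology_profile,
)
from .strand_ratio import (
    enrichment_table,
    rank_and_split,
    ratio_table,
    strand_means,
)
from .feature_builder import assemble_features
from .classifier_eval import (
    evaluate_external,
    subset_metrics_table,
    train_model,
)

ALL_STAGES = ["simulate", "topology", "rank", "enrich", "features", "cv"]

#: files each stage consumes (relative to the run directory)
STAGE_INPUTS = {
    "simulate": [],
    "topology": ["probes.tsv", "smrnas.tsv", "hairpins.fa", "hairpins.tsv"],
    "rank": ["genes.bed", "probes.tsv"],
    "enrich": ["ranked.tsv", "gene_classes.tsv"],
    "features": ["probes.tsv", "smrnas.tsv", "gold_pairs.tsv", "genes.bed",
                 "hairpins.tsv"],
    "cv": ["features.tsv"],
}


@dataclass
class PipelineConfig:
    seed: int = 7
    outdir: str = "astra_run"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    sim: dict = field(default_factory=dict)
    folds: int = 10
    window: int = 800
    max_c_fraction: float = 0.40

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    inputs: dict[str, str]
    outputs: dict[str, str]
    stage_seconds: dict[str, float]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the requested stages in dependency order.

    Missing inputs for any non-skipped stage abort the run before any stage
    executes. Returns the manifest, which is also written to
    ``manifest.json`` in the run directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in config.stages]

    produced: set[str] = set()
    for s in stages:
        if s == "simulate":
            produced.update(["genes.bed", "gene_classes.tsv", "probes.tsv",
                             "smrnas.tsv", "hairpins.fa", "hairpins.tsv",
                             "gold_pairs.tsv"])
        elif s == "rank":
            produced.add("ranked.tsv")
        elif s == "features":
            produced.add("features.tsv")
    for s in stages:
        for dep in STAGE_INPUTS[s]:
            if dep not in produced and not (outdir / dep).exists():
                raise FileNotFoundError(
                    f"stage '{s}' requires {dep}, which no earlier stage "
                    f"produces and which is absent from {outdir}")

    timings: dict[str, float] = {}
    inputs: dict[str, str] = {
        dep: _sha256(outdir / dep)
        for s in stages for dep in STAGE_INPUTS[s]
        if (outdir / dep).exists()
    }
    outputs: dict[str, str] = {}

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[stage] = round(time.perf_counter() - self.t0, 3)
        return _T()

    if "simulate" in stages:
        with timed("simulate"):
            sim = simulate(SimConfig(seed=config.seed, **config.sim))
            save_simulation(sim, outdir)

    if "topology" in stages:
        with timed("topology"):
            probes = read_probe_table(outdir / "probes.tsv")
            smrnas = read_smrna_table(outdir / "smrnas.tsv")
            hairpins = read_hairpins(outdir / "hairpins.fa",
                                     outdir / "hairpins.tsv")
            matches = [m for sig in smrnas for hp in hairpins
                       for m in match_signature(sig, hp)]
            topology_profile(matches).to_csv(
                outdir / "topology_profile.tsv", sep="\t", index=False)
            # 17-nt MPSS signature placements define the other_smRNA sites
            mpss_sites: dict[str, list[tuple[int, int]]] = {}
            for hp in hairpins:
                chrom, hstart, hend, _ = hp.genomic_placement
                mpss_sites[hp.hairpin_id] = [
                    (s, e)
                    for sig in smrnas if sig.length == 17
                    for c, s, e, _str in sig.locations
                    if c == chrom and s < hend and e > hstart
                ]
            assignments = assign_hairpin_probes(
                probes, hairpins, mpss_sites_by_hairpin=mpss_sites)
            region = region_signal_table(assignments, probes)
            pd.DataFrame([asdict(r) for r in region]).to_csv(
                outdir / "region_signals.tsv", sep="\t", index=False)
            anchors = [
                LocusAnchor(hp.hairpin_id, hp.genomic_placement[0],
                            hp.genomic_placement[1] + hp.mirstar_interval[0],
                            hp.genomic_placement[3])
                for hp in hairpins
            ]
            averaged_strand_profile(
                anchors, probes, window=config.window).to_csv(
                outdir / "strand_profile.tsv", sep="\t", index=False)

    if "rank" in stages:
        with timed("rank"):
            genes = read_gene_models(outdir / "genes.bed")
            probes = read_probe_table(outdir / "probes.tsv")
            probes, _ = filter_c_rich_probes(probes, config.max_c_fraction)
            assignment = assign_probes(probes, genes)
            ranked = rank_and_split(ratio_table(
                strand_means(assignment, probes)))
            ranked.to_csv(outdir / "ranked.tsv", sep="\t")

    if "enrich" in stages:
        with timed("enrich"):
            ranked = pd.read_csv(outdir / "ranked.tsv", sep="\t",
                                 index_col=0)
            classes = read_gene_classes(outdir / "gene_classes.tsv")
            tags = sorted({t for tags in classes.values() for t in tags})
            enrichment_table(ranked, classes, tags).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False)

    if "features" in stages:
        with timed("features"):
            probes = read_probe_table(outdir / "probes.tsv")
            smrnas = read_smrna_table(outdir / "smrnas.tsv")
            gold = read_gold_pairs(outdir / "gold_pairs.tsv")
            genes = read_gene_models(outdir / "genes.bed")
            hairpins = read_hairpins(outdir / "hairpins.fa",
                                     outdir / "hairpins.tsv")
            strand_of = {g.gene_id: g.strand for g in genes}
            strand_of.update({hp.hairpin_id: hp.genomic_placement[3]
                              for hp in hairpins})
            X, y = assemble_features(gold, probes, smrnas, strand_of,
                                     window=config.window)
            out = X.copy()
            out["label"] = y
            out["group"] = [p.group for p in gold]
            out.to_csv(outdir / "features.tsv", sep="\t")

    if "cv" in stages:
        with timed("cv"):
            feats = pd.read_csv(outdir / "features.tsv", sep="\t",
                                index_col=0)
            train_mask = feats["group"].isin(["target", "paralog"])
            X = feats.drop(columns=["label", "group"])
            y = feats["label"]
            metrics = subset_metrics_table(X[train_mask], y[train_mask],
                                           k=config.folds, seed=config.seed)
            metrics.to_csv(outdir / "cv_metrics.tsv", sep="\t", index=False)
            ext_mask = feats["group"].isin(["mirna_ancient", "mirna_new"])
            if ext_mask.any():
                model = train_model(X[train_mask], y[train_mask])
                evaluate_external(
                    model, X[ext_mask], y[ext_mask],
                    feats.loc[ext_mask, "group"],
                ).to_csv(outdir / "external_accuracy.tsv", sep="\t",
                         index=False)

    for path in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.fa")) \
            + sorted(outdir.glob("*.bed")):
        outputs[path.name] = _sha256(path)

    config_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()
    manifest = RunManifest(config_hash, config.seed, __version__,
                           inputs, outputs, timings)
    (outdir / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2) + "\n")
    return manifest
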