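"""End-to-end orchestration: simulate -> finemap -> coloc -> annotate -> enrich.

A run is fully described by a RunConfig (loadable from YAML); every output
file is listed in a manifest with its SHA-256 digest, so reruns with the
same config are byte-verifiable.  Stages execute in dependency order; a
stage failure halts the run with the failing stage named, retaining partial
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, coloc, enrich, io
from .coloc import ColocThresholds, QTLSignal
from .finemap import FineMapConfig, finemap_locus
from .simulate import SimulationTruth, simulate_atlas, simulate_panel, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class LocusSpec:
    """Simulation plan for one locus shared by the paired studies."""

    locus_id: str
    variant_count: int = 50
    block_size: int = 10
    within_block_decay: float = 0.95
    maf_range: tuple = (0.05, 0.5)
    hap_count: int = 2000
    shared_causals: list = field(default_factory=list)
    study1_causals: list = field(default_factory=list)
    study2_causals: list = field(default_factory=list)
    variance_explained: float = 0.01

    def truth(self) -> SimulationTruth:
        ve, sg = self.variance_explained, 1.0
        s1 = {int(i): (ve, sg) for i in list(self.shared_causals) + list(self.study1_causals)}
        s2 = {int(i): (ve, sg) for i in list(self.shared_causals) + list(self.study2_causals)}
        return SimulationTruth.from_dicts(s1, s2)


@dataclass
class EnrichmentSpec:
    gene_count: int = 500
    cell_types: list = field(default_factory=lambda: [f"ct{i}" for i in range(1, 6)])
    markers_per_type: int = 20
    marker_fold: float = 8.0
    reps: int = 10_000
    seed: int = 1


@dataclass
class RunConfig:
    """Complete, validated description of a pipeline run."""

    seed: int = 1
    n_study1: int = 5000
    n_study2: int = 5000
    loci: list = field(default_factory=list)
    finemap: FineMapConfig = field(default_factory=FineMapConfig)
    thresholds: ColocThresholds = field(default_factory=ColocThresholds)
    enrichment: EnrichmentSpec = field(default_factory=EnrichmentSpec)

    def __post_init__(self):
        if self.n_study1 < 50 or self.n_study2 < 50:
            raise ValueError("study sample sizes must be >= 50")
        for spec in self.loci:
            spec.truth()  # validates the causal plan

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        loci = [LocusSpec(**ls) for ls in d.pop("loci", [])]
        fm = FineMapConfig(**d.pop("finemap", {}))
        th = ColocThresholds(**d.pop("thresholds", {}))
        en = EnrichmentSpec(**d.pop("enrichment", {}))
        return cls(loci=loci, finemap=fm, thresholds=th, enrichment=en, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["loci"] = [
            {**ls, "maf_range": list(ls["maf_range"])} for ls in d["loci"]
        ]
        return d


def demo_config(seed: int = 1) -> RunConfig:
    """Two-locus demo: one locus with a shared causal variant, one with
    distinct causals in separate LD blocks, plus a 200-gene atlas."""
    return RunConfig(
        seed=seed,
        n_study1=8000,
        n_study2=8000,
        loci=[
            LocusSpec(locus_id="locus1", variant_count=40, block_size=10,
                      shared_causals=[12], variance_explained=0.02),
            LocusSpec(locus_id="locus2", variant_count=40, block_size=10,
                      study1_causals=[5], study2_causals=[25],
                      variance_explained=0.02),
        ],
        enrichment=EnrichmentSpec(gene_count=200, markers_per_type=10,
                                  marker_fold=8.0, reps=2000, seed=1),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _pkg_version() -> str:
    try:
        return version("finecoloc")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages and return the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}

    def record(path: Path):
        outputs[str(path.relative_to(out))] = _sha256(path)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %s: failed", name)
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])
        return _Ctx()

    rng_seeds = np.random.SeedSequence(config.seed).generate_state(4 * max(len(config.loci), 1))
    loci_store = {}

    with stage("simulate"):
        for i, spec in enumerate(config.loci):
            panel = simulate_panel(
                spec.variant_count, spec.hap_count, spec.block_size,
                spec.within_block_decay, tuple(spec.maf_range),
                seed=int(rng_seeds[4 * i]) % (2**31),
                chrom=f"chr{i + 1}",
            )
            truth = spec.truth()
            s1 = simulate_study(panel, truth, config.n_study1, 1,
                                seed=int(rng_seeds[4 * i + 1]) % (2**31))
            s2 = simulate_study(panel, truth, config.n_study2, 2,
                                seed=int(rng_seeds[4 * i + 2]) % (2**31))
            loci_store[spec.locus_id] = (panel, truth, s1, s2)
            for study, label in ((s1, "study1"), (s2, "study2")):
                p = out / f"{spec.locus_id}_{label}.sumstats.tsv"
                io.write_sumstats(study, p)
                record(p)
                p = out / f"{spec.locus_id}_{label}.ld.txt"
                io.write_ld(study.ld, p)
                record(p)
            p = out / f"{spec.locus_id}.truth.json"
            io.write_truth(truth, p)
            record(p)

    results = {}
    with stage("finemap"):
        for spec in config.loci:
            _, _, s1, s2 = loci_store[spec.locus_id]
            r1 = finemap_locus(s1, config.finemap, locus_id=f"{spec.locus_id}_s1")
            r2 = finemap_locus(s2, config.finemap, locus_id=f"{spec.locus_id}_s2")
            results[spec.locus_id] = (r1, r2)
            for r, label in ((r1, "study1"), (r2, "study2")):
                p = out / f"{spec.locus_id}_{label}.credible_sets.tsv"
                io.write_credible_sets(r.credible_sets, p)
                record(p)

    with stage("coloc"):
        pair_rows = []
        called = {}
        for spec in config.loci:
            r1, r2 = results[spec.locus_id]
            for cs1 in r1.credible_sets:
                for cs2 in r2.credible_sets:
                    qtl = QTLSignal(cs=cs2, gene_id=f"GENE_{spec.locus_id}",
                                    tissue="tissue_1", qtl_fdr=0.01, effect_sign=1)
                    pair = coloc.colocalize(cs1, qtl, config.thresholds)
                    pair_rows.append(
                        {
                            "locus_id": spec.locus_id,
                            "gwas_cs_id": pair.gwas_cs_id,
                            "qtl_cs_id": pair.qtl_cs_id,
                            "gene": qtl.gene_id,
                            "tissue": qtl.tissue,
                            "n_shared": len(pair.shared_ids),
                            "clpp": pair.clpp,
                            "rcp_proxy": pair.rcp_proxy,
                            "shared_pip_sum_gwas": pair.shared_pip_sum_gwas,
                            "shared_pip_sum_qtl": pair.shared_pip_sum_qtl,
                            "pass_fdr": pair.pass_fdr,
                            "pass_pip_sum": pair.pass_pip_sum,
                            "tier": pair.tier,
                        }
                    )
                    if pair.tier != "none":
                        called.setdefault("clpp_rcp", []).append(pair)
        pairs_df = pd.DataFrame(pair_rows)
        p = out / "coloc_pairs.tsv"
        pairs_df.to_csv(p, sep="\t", index=False, float_format=io.FLOAT_FORMAT)
        record(p)
        consensus = coloc.consensus_table(called or {"clpp_rcp": []})
        p = out / "coloc_consensus.tsv"
        consensus.to_csv(p, sep="\t", index=False)
        record(p)

    with stage("annotate"):
        gene_rows, ocr_rows = [], []
        all_sets = []
        set_genes = {}
        for i, spec in enumerate(config.loci):
            panel, truth, _, _ = loci_store[spec.locus_id]
            lo = int(panel.positions.min())
            hi = int(panel.positions.max())
            mid = (lo + hi) // 2
            gene_rows += [
                {"gene_id": f"GENE_{spec.locus_id}", "gene_name": f"GENE_{spec.locus_id}",
                 "chrom": panel.chrom, "start": lo, "end": mid, "strand": "+",
                 "biotype": "protein_coding"},
                {"gene_id": f"LNC_{spec.locus_id}", "gene_name": f"LNC_{spec.locus_id}",
                 "chrom": panel.chrom, "start": mid + 1000, "end": hi + 2000,
                 "strand": "-", "biotype": "lncRNA"},
            ]
            # OCR intervals covering the true causal positions of study 1
            for j in truth.causal_indices[0]:
                pos = int(panel.positions[j])
                ocr_rows.append({"chrom": panel.chrom, "start": pos - 50, "end": pos + 50})
            r1, _ = results[spec.locus_id]
            for cs in r1.credible_sets:
                all_sets.append(cs)
                set_genes[cs.cs_id] = f"GENE_{spec.locus_id}"
        gene_models = pd.DataFrame(gene_rows).sort_values(
            ["chrom", "start"], kind="stable").reset_index(drop=True)
        ocr = pd.DataFrame(ocr_rows, columns=["chrom", "start", "end"])
        nearest = annotate.nearest_genes([cs.lead_id for cs in all_sets], gene_models)
        p = out / "nearest_genes.tsv"
        nearest.to_csv(p, sep="\t", index=False)
        record(p)
        per_set, per_gene = annotate.ocr_overlap(all_sets, ocr, gene_map=set_genes)
        p = out / "ocr_overlap.tsv"
        per_set.to_csv(p, sep="\t", index=False)
        record(p)
        p = out / "ocr_overlap_genes.tsv"
        per_gene.to_csv(p, sep="\t", index=False)
        record(p)

    with stage("enrich"):
        es = config.enrichment
        atlas = simulate_atlas(es.gene_count, es.cell_types, es.markers_per_type,
                               es.marker_fold, seed=config.seed)
        p = out / "atlas.csv"
        io.write_atlas(atlas.ctd, p)
        record(p)
        targets = atlas.markers[es.cell_types[0]]
        p = out / "target_genes.txt"
        io.write_gene_set(targets, p)
        record(p)
        table = enrich.bootstrap_enrichment(atlas.ctd, targets, reps=es.reps,
                                            seed=es.seed)
        p = out / "enrichment.tsv"
        table.to_csv(p, sep="\t", index=False, float_format=io.FLOAT_FORMAT)
        record(p)

    manifest = {
        "package_version": _pkg_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": outputs,
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n"
    )
    return manifest
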