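"""Benchmark experiments on synthetic ground truth.

These routines measure the statistical behavior of the pipeline under
known simulated conditions: CLPP arithmetic against a direct product-form
oracle, PIP calibration and credible-set coverage of the fine-mapper,
shared-vs-distinct causal discrimination of the colocalization caller,
bootstrap-enrichment calibration and power, and exactness of the
annotation primitives.  They are used by the test suite and by the
repository's reproduction script; problem sizes are arguments so callers
choose their own compute budget.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .annotate import nearest_gene, ocr_overlap, splice_window_hits
from .coloc import QTLSignal, clpp, colocalize, rcp_proxy
from .enrich import bootstrap_enrichment, conditional_enrichment, specificity
from .finemap import CredibleSet, FineMapConfig, finemap_locus
from .simulate import SimulationTruth, simulate_atlas, simulate_panel, simulate_study


def _random_credible_set(rng, cs_id, pool):
    size = int(rng.integers(1, 8))
    ids = rng.choice(pool, size=size, replace=False)
    pips = rng.uniform(0.001, 1.0, size=size)
    order = np.argsort(-pips)
    return CredibleSet(
        cs_id=cs_id, member_ids=ids[order].astype(object), pip=pips[order],
        signal_pip_total=float(pips.sum()), coverage_achieved=0.95,
        lead_id=str(ids[order][0]),
    )


def clpp_oracle_check(n_pairs: int = 10_000, seed: int = 0) -> dict:
    """Compare clpp() with a direct product-form evaluation and the bound chain.

    Returns the maximum absolute deviation from the oracle and the number of
    bound-chain violations over random credible-set pairs.
    """
    rng = np.random.default_rng(seed)
    pool = np.array([f"v{i}" for i in range(12)])
    max_diff = 0.0
    violations = 0
    for i in range(n_pairs):
        a = _random_credible_set(rng, "a:1", pool)
        b = _random_credible_set(rng, "b:1", pool)
        c = clpp(a, b)
        s = rcp_proxy(a, b)
        pa, pb = a.pip_map(), b.pip_map()
        shared = set(pa) & set(pb)
        prod = 1.0
        for v in shared:
            prod *= 1.0 - pa[v] * pb[v]
        oracle = 1.0 - prod
        max_diff = max(max_diff, abs(c - oracle))
        lo = max((pa[v] * pb[v] for v in shared), default=0.0)
        if not (lo - 1e-12 <= c <= min(1.0, s) + 1e-12):
            violations += 1
    return {"max_abs_diff": max_diff, "bound_violations": violations, "n": n_pairs}


def pip_calibration_experiment(n_loci: int = 500, m: int = 50,
                               n_individuals: int = 5000, seed: int = 0,
                               config: FineMapConfig | None = None) -> dict:
    """Fine-mapping calibration on simulated loci with 1-2 causal variants.

    Each locus carries one or two causal variants explaining 0.5-2% of
    phenotypic variance each.  Reports per-PIP-decile causal fractions, the
    maximum |causal fraction - bin midpoint| over bins holding at least 30
    variants, and the fraction of strong loci (lead |z| >= 6) whose true
    causal variant lies inside some credible set.
    """
    root = np.random.SeedSequence(seed)
    child = root.generate_state(3 * n_loci, dtype=np.uint32)
    rng = np.random.default_rng(root)
    pips_all, causal_all = [], []
    covered = total_strong = 0
    for i in range(n_loci):
        panel = simulate_panel(m, 2000, 10, 0.95, (0.05, 0.5),
                               seed=int(child[3 * i]))
        k = int(rng.integers(1, 3))
        cidx = rng.choice(m, k, replace=False)
        ve = rng.uniform(0.005, 0.02, k)
        truth = SimulationTruth.from_dicts(
            {int(c): (float(v), 1.0) for c, v in zip(cidx, ve)}, {}
        )
        locus = simulate_study(panel, truth, n_individuals, 1,
                               seed=int(child[3 * i + 1]))
        result = finemap_locus(locus, config)
        pips_all.append(result.pips.to_numpy())
        flag = np.zeros(m, dtype=bool)
        flag[cidx] = True
        causal_all.append(flag)
        if np.abs(locus.z).max() >= 6:
            total_strong += 1
            members = set()
            for cs in result.credible_sets:
                members.update(cs.member_ids)
            if members & set(locus.variant_ids[cidx]):
                covered += 1
    pips = np.concatenate(pips_all)
    causal = np.concatenate(causal_all)
    rows = []
    for lo in np.arange(0.0, 1.0, 0.1):
        upper = (pips < lo + 0.1) if lo < 0.85 else (pips <= 1.0)
        mask = (pips >= lo) & upper
        if mask.sum() == 0:
            continue
        rows.append(
            {"bin_low": lo, "bin_mid": lo + 0.05, "n_variants": int(mask.sum()),
             "causal_fraction": float(causal[mask].mean())}
        )
    bins = pd.DataFrame(rows)
    big = bins[bins["n_variants"] >= 30]
    max_err = float((big["causal_fraction"] - big["bin_mid"]).abs().max())
    return {
        "bins": bins,
        "max_calibration_error": max_err,
        "coverage_rate": covered / total_strong if total_strong else float("nan"),
        "n_strong_loci": total_strong,
        "n_loci": n_loci,
    }


def coloc_discrimination_experiment(n_reps: int = 100, m: int = 40,
                                    n_individuals: int = 10_000,
                                    variance_explained: float = 0.01,
                                    seed: int = 0) -> dict:
    """Call rates for designed shared vs distinct causal variants.

    ``n_reps`` replicates are run for each arm.  In the shared arm both
    studies share one causal variant; in the distinct arm the causals sit in
    different LD blocks (|r| <= 0.3 enforced by construction check).  A
    replicate counts as called when any credible-set pair reaches at least
    the credible tier.  Also returns the Pearson correlation between CLPP
    and the product-sum proxy across the shared arm's best pairs.
    """
    root = np.random.SeedSequence(seed)
    child = root.generate_state(6 * n_reps, dtype=np.uint32)
    shared_called = false_called = 0
    clpps, rcps = [], []
    ve = variance_explained
    for i in range(n_reps):
        for arm in ("shared", "distinct"):
            off = 6 * i + (0 if arm == "shared" else 3)
            panel = simulate_panel(m, 2000, 10, 0.95, (0.05, 0.5),
                                   seed=int(child[off]))
            if arm == "shared":
                truth = SimulationTruth.from_dicts(
                    {m // 2: (ve, 1.0)}, {m // 2: (ve, 1.0)}
                )
            else:
                a, b = m // 8, m - m // 8 - 1
                if abs(panel.ld[a, b]) > 0.3:  # different blocks: essentially never
                    continue
                truth = SimulationTruth.from_dicts({a: (ve, 1.0)}, {b: (ve, 1.0)})
            s1 = simulate_study(panel, truth, n_individuals, 1,
                                seed=int(child[off + 1]))
            s2 = simulate_study(panel, truth, n_individuals, 2,
                                seed=int(child[off + 2]))
            r1 = finemap_locus(s1, locus_id="gwas")
            r2 = finemap_locus(s2, locus_id="qtl")
            best = None
            called = False
            for cs1 in r1.credible_sets:
                for cs2 in r2.credible_sets:
                    qtl = QTLSignal(cs=cs2, gene_id="G", tissue="t",
                                    qtl_fdr=0.01, effect_sign=1)
                    pair = colocalize(cs1, qtl)
                    if pair.tier != "none":
                        called = True
                    if best is None or pair.clpp > best.clpp:
                        best = pair
            if arm == "shared":
                shared_called += int(called)
                if best is not None:
                    clpps.append(best.clpp)
                    rcps.append(best.rcp_proxy)
            else:
                false_called += int(called)
    r = float(pearsonr(clpps, rcps).statistic) if len(clpps) >= 3 else float("nan")
    return {
        "shared_call_rate": shared_called / n_reps,
        "false_call_rate": false_called / n_reps,
        "clpp_rcp_pearson": r,
        "n_reps": n_reps,
    }


def enrichment_calibration_experiment(n_targets: int = 200, target_size: int = 60,
                                      reps: int = 1000, n_genes: int = 400,
                                      n_types: int = 5, seed: int = 0) -> dict:
    """False-positive rate of the bootstrap test under a null atlas, plus
    planted-marker power and the two conditional-dependency patterns."""
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(
        rng.lognormal(0, 0.2, size=(n_genes, n_types)),
        index=[f"g{i:05d}" for i in range(n_genes)],
        columns=[f"ct{j}" for j in range(n_types)],
    )
    ctd = specificity(expr)
    n_sig = n_tests = 0
    for _ in range(n_targets):
        target = list(ctd.genes[rng.choice(len(ctd.genes), target_size,
                                           replace=False)])
        out = bootstrap_enrichment(ctd, target, reps=reps,
                                   seed=int(rng.integers(2**31)))
        n_sig += int(out["significant"].sum())
        n_tests += len(out)
    null_rate = n_sig / n_tests

    atlas = simulate_atlas(300, [f"c{i}" for i in range(5)], 15, 10.0,
                           seed=int(rng.integers(2**31)))
    power = bootstrap_enrichment(atlas.ctd, atlas.markers["c2"], reps=2000,
                                 seed=1).set_index("cell_type")
    home_significant = bool(power.loc["c2", "q_bh"] <= 0.05)
    home_top_z = bool(power["z_score"].idxmax() == "c2")

    genes = [f"g{i:04d}" for i in range(300)]
    shared_expr = pd.DataFrame(rng.lognormal(0, 0.15, (300, 5)), index=genes,
                               columns=[f"c{i}" for i in range(5)])
    shared = genes[:20]
    shared_expr.loc[shared, "c0"] *= 8
    shared_expr.loc[shared, "c1"] *= 8
    cond = conditional_enrichment(specificity(shared_expr), shared, "c0",
                                  reps=2000, bins=15, seed=1).set_index("cell_type")
    shared_dependency = bool(cond.loc["c1", "q_bh"] > 0.05)

    disj_expr = pd.DataFrame(rng.lognormal(0, 0.15, (300, 5)), index=genes,
                             columns=[f"c{i}" for i in range(5)])
    groups = {f"c{k}": genes[20 * k:20 * (k + 1)] for k in range(4)}
    for ct, gs in groups.items():
        disj_expr.loc[gs, ct] *= 8
    cond2 = conditional_enrichment(specificity(disj_expr),
                                   groups["c0"] + groups["c1"], "c0",
                                   reps=2000, bins=15, seed=1).set_index("cell_type")
    disjoint_independence = bool(cond2.loc["c1", "q_bh"] <= 0.05)

    return {
        "null_q05_rate": null_rate,
        "n_tests": n_tests,
        "planted_marker_home_significant": home_significant,
        "planted_marker_home_top_z": home_top_z,
        "shared_marker_dependency": shared_dependency,
        "disjoint_marker_independence": disjoint_independence,
    }


def nearest_gene_agreement(n_variants: int = 1000, n_genes: int = 200,
                           seed: int = 0) -> dict:
    """Agreement rate of nearest_gene with an exhaustive all-genes scan."""
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, 200_000, n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n_genes)],
            "gene_name": [f"g{i:04d}" for i in range(n_genes)],
            "chrom": "chr1",
            "start": starts,
            "end": starts + rng.integers(10, 5000, n_genes),
            "strand": "+",
            "biotype": "protein_coding",
        }
    )
    agree = 0
    for pos in rng.integers(0, 210_000, n_variants):
        pos = int(pos)
        gene, d = nearest_gene(("chr1", pos), genes)
        best = None
        for row in genes.itertuples(index=False):
            dd = 0 if row.start <= pos <= row.end else (
                -(pos - row.end) if row.end < pos else row.start - pos
            )
            key = (abs(dd), row.start, row.gene_id)
            if best is None or key < best[0]:
                best = (key, row.gene_id, dd)
        agree += int((gene["gene_id"], d) == (best[1], best[2]))
    return {"agreement_rate": agree / n_variants, "n": n_variants}


def interval_exactness(seed: int = 0) -> dict:
    """Brute-force agreement for splice windows and OCR membership."""
    rng = np.random.default_rng(seed)
    introns = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": (s := np.sort(rng.integers(1000, 100_000, 12))),
            "end": s + rng.integers(200, 3000, 12),
            "strand": rng.choice(["+", "-"], 12),
        }
    )
    positions = rng.integers(500, 105_000, 60)
    ids = [f"chr1_{p}_A_G_b38" for p in positions]
    hits = splice_window_hits(ids, introns, window=25)
    expected = 0
    for p in positions:
        for intron in introns.itertuples(index=False):
            expected += int(abs(int(p) - int(intron.start)) <= 25)
            expected += int(abs(int(p) - int(intron.end)) <= 25)
    splice_ok = len(hits) == expected

    intervals = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": (a := rng.integers(0, 50_000, 20)),
            "end": a + rng.integers(1, 2000, 20),
        }
    )
    sets = []
    for i in range(25):
        poss = rng.integers(0, 52_000, 4)
        pips = np.full(4, 0.2)
        vids = np.array([f"chr1_{int(p)}_A_G_b38" for p in poss], dtype=object)
        sets.append(CredibleSet(cs_id=f"s:{i}", member_ids=vids, pip=pips,
                                signal_pip_total=0.8, coverage_achieved=0.95,
                                lead_id=str(vids[0])))
    flags = ocr_overlap(sets, intervals).set_index("cs_id")["in_ocr"]
    ocr_ok = True
    for cs in sets:
        exp = any(
            iv.start <= int(m.split("_")[1]) < iv.end
            for m in cs.member_ids
            for iv in intervals.itertuples(index=False)
        )
        ocr_ok &= bool(flags[cs.cs_id] == exp)
    return {"splice_window_exact": splice_ok, "ocr_exact": ocr_ok}


def pipeline_determinism(seed: int = 1, workdir=None) -> dict:
    """Run the demo pipeline twice and compare output digests and runtime."""
    import tempfile
    from pathlib import Path

    from .pipeline import demo_config, run_pipeline

    base = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="finecoloc_"))
    t0 = time.perf_counter()
    m1 = run_pipeline(demo_config(seed), base / "run1")
    elapsed = time.perf_counter() - t0
    m2 = run_pipeline(demo_config(seed), base / "run2")
    return {
        "identical": m1["outputs"] == m2["outputs"],
        "runtime_s": elapsed,
        "n_outputs": len(m1["outputs"]),
    }
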