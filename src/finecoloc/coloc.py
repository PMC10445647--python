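"""Signal-level colocalization between two fine-mapped studies.

For a GWAS credible set and a QTL credible set sharing K variants, the
colocalization posterior probability is

    CLPP = 1 - prod_{i=1..K} (1 - PIP_gwas,i * PIP_qtl,i)

with per-variant PIPs used unnormalized as emitted by fine-mapping.  A
product-sum score (sum of PIP products over shared variants) serves as an
enrichment-free regional colocalization proxy; the two statistics coincide
at K = 1 and the sum bounds CLPP from above.  Calls are tiered by the union
rule — ``credible`` when CLPP >= 0.01 or the proxy >= 0.1, ``strong`` at
0.1 / 0.5 — after two quality filters: the QTL FDR must be <= 5% and the
shared variants must retain >= 50% of the PIP mass of each signal.  The
same 50% predicate also decides whether two credible sets from different
methods describe the same underlying signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .finemap import CredibleSet


@dataclass
class ColocThresholds:
    """Colocalization call thresholds and quality-filter levels."""

    clpp_credible: float = 0.01
    rcp_credible: float = 0.1
    clpp_strong: float = 0.1
    rcp_strong: float = 0.5
    fdr_max: float = 0.05
    pip_sum_min: float = 0.5

    def __post_init__(self):
        for name in ("clpp_credible", "rcp_credible", "clpp_strong", "rcp_strong",
                     "fdr_max", "pip_sum_min"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"threshold {name} must be in [0, 1], got {v}")


@dataclass
class QTLSignal:
    """A fine-mapped molecular-QTL signal with its target feature and metadata."""

    cs: CredibleSet
    gene_id: str
    tissue: str
    qtl_fdr: float | None
    effect_sign: int
    intron: str | None = None  # "chrom:start-end" for splicing QTLs

    def __post_init__(self):
        if self.qtl_fdr is not None and not (0 <= self.qtl_fdr <= 1):
            raise ValueError("qtl_fdr must be in [0, 1]")
        if self.intron is not None:
            chrom, span = self.intron.split(":")
            start, end = (int(x) for x in span.split("-"))
            if start >= end:
                raise ValueError(f"intron coordinates must satisfy start < end: {self.intron}")

    @property
    def target_feature(self) -> str:
        return self.gene_id if self.intron is None else f"{self.gene_id}@{self.intron}"


@dataclass
class ColocPair:
    """One GWAS-signal x QTL-signal comparison with statistics, filters and tier."""

    gwas_cs_id: str
    qtl_cs_id: str
    shared_ids: list
    clpp: float
    rcp_proxy: float
    shared_pip_sum_gwas: float
    shared_pip_sum_qtl: float
    qtl_fdr: float | None = None
    is_qtl: bool = True
    pass_fdr: bool | None = None
    pass_pip_sum: bool | None = None
    tier: str = "none"
    cs_gwas: CredibleSet | None = field(default=None, repr=False)
    cs_qtl: CredibleSet | None = field(default=None, repr=False)


def _shared(cs_a: CredibleSet, cs_b: CredibleSet):
    pa, pb = cs_a.pip_map(), cs_b.pip_map()
    shared = sorted(set(pa) & set(pb))
    return shared, pa, pb


def clpp(cs_gwas: CredibleSet, cs_qtl: CredibleSet) -> float:
    """Colocalization posterior probability over the shared credible-set variants."""
    shared, pa, pb = _shared(cs_gwas, cs_qtl)
    products = [pa[v] * pb[v] for v in shared]
    if any(p >= 1.0 for p in products):
        return 1.0
    log_surv = sum(np.log1p(-p) for p in products)
    return float(-np.expm1(log_surv))


def rcp_proxy(cs_gwas: CredibleSet, cs_qtl: CredibleSet) -> float:
    """Sum of per-variant PIP products over shared variants (regional proxy)."""
    shared, pa, pb = _shared(cs_gwas, cs_qtl)
    return float(sum(pa[v] * pb[v] for v in shared))


def shared_pip_sums(cs_gwas: CredibleSet, cs_qtl: CredibleSet):
    """Each study's PIP mass restricted to the shared variants."""
    shared, pa, pb = _shared(cs_gwas, cs_qtl)
    return (float(sum(pa[v] for v in shared)), float(sum(pb[v] for v in shared)))


def make_pair(cs_gwas: CredibleSet, cs_qtl: CredibleSet, qtl_fdr: float | None = None,
              is_qtl: bool = True) -> ColocPair:
    """Compute all pairwise statistics for one GWAS/QTL credible-set pair."""
    shared, _, _ = _shared(cs_gwas, cs_qtl)
    s_gwas, s_qtl = shared_pip_sums(cs_gwas, cs_qtl)
    return ColocPair(
        gwas_cs_id=cs_gwas.cs_id,
        qtl_cs_id=cs_qtl.cs_id,
        shared_ids=shared,
        clpp=clpp(cs_gwas, cs_qtl),
        rcp_proxy=rcp_proxy(cs_gwas, cs_qtl),
        shared_pip_sum_gwas=s_gwas,
        shared_pip_sum_qtl=s_qtl,
        qtl_fdr=qtl_fdr,
        is_qtl=is_qtl,
        cs_gwas=cs_gwas,
        cs_qtl=cs_qtl,
    )


def call_colocalization(pair: ColocPair,
                        thresholds: ColocThresholds | None = None) -> ColocPair:
    """Apply the quality filters and assign the colocalization tier.

    Statistics are always retained (filtered pairs are reported, not
    dropped); the tier is ``none`` unless both filters pass, then
    ``credible``/``strong`` by the union rule on CLPP and the RCP proxy.
    """
    t = thresholds or ColocThresholds()
    if pair.is_qtl and pair.qtl_fdr is None:
        raise ValueError(
            f"pair {pair.gwas_cs_id} x {pair.qtl_cs_id}: qtl_fdr is required "
            "when the second study is a molecular QTL"
        )
    pair.pass_fdr = True if not pair.is_qtl else bool(pair.qtl_fdr <= t.fdr_max)
    pair.pass_pip_sum = bool(
        pair.shared_pip_sum_gwas >= t.pip_sum_min
        and pair.shared_pip_sum_qtl >= t.pip_sum_min
    )
    tier = "none"
    if pair.pass_fdr and pair.pass_pip_sum:
        if pair.clpp >= t.clpp_strong or pair.rcp_proxy >= t.rcp_strong:
            tier = "strong"
        elif pair.clpp >= t.clpp_credible or pair.rcp_proxy >= t.rcp_credible:
            tier = "credible"
    pair.tier = tier
    return pair


def colocalize(cs_gwas: CredibleSet, qtl: QTLSignal,
               thresholds: ColocThresholds | None = None) -> ColocPair:
    """Convenience: statistics plus filters/tier for a GWAS CS against a QTL signal."""
    pair = make_pair(cs_gwas, qtl.cs, qtl_fdr=qtl.qtl_fdr, is_qtl=True)
    return call_colocalization(pair, thresholds)


def same_signal(cs_a: CredibleSet, cs_b: CredibleSet,
                pip_sum_min: float = 0.5) -> bool:
    """Whether two credible sets likely describe one underlying causal signal.

    True iff the shared variants retain at least ``pip_sum_min`` PIP mass in
    both sets.
    """
    s_a, s_b = shared_pip_sums(cs_a, cs_b)
    return bool(s_a >= pip_sum_min and s_b >= pip_sum_min)


def consensus_table(call_sets: dict) -> pd.DataFrame:
    """Tabulate colocalization calls across independently run methods.

    Parameters
    ----------
    call_sets : dict of method label -> list of ColocPair
        Each method's called pairs (typically tier != none, but any list is
        accepted).

    Returns
    -------
    DataFrame with one row per (gwas_cs_id, qtl_cs_id) in the union: the
    supporting method labels, a same-signal verdict comparing the methods'
    GWAS-side credible sets pairwise, and a low-confidence flag when any
    supporting method's pair fails the 50% shared-PIP criterion.
    """
    if not call_sets:
        raise ValueError("at least one labeled call set is required")
    union: dict[tuple, dict] = {}
    for label, pairs in call_sets.items():
        for pair in pairs:
            key = (pair.gwas_cs_id, pair.qtl_cs_id)
            union.setdefault(key, {})[label] = pair
    rows = []
    for (gwas_id, qtl_id), support in sorted(union.items()):
        labels = sorted(support)
        cs_list = [p.cs_gwas for p in support.values() if p.cs_gwas is not None]
        verdict = True
        for a, b in zip(cs_list, cs_list[1:]):
            if not same_signal(a, b):
                verdict = False
        fails_pip = any(
            p.pass_pip_sum is False or (
                p.pass_pip_sum is None
                and not (p.shared_pip_sum_gwas >= 0.5 and p.shared_pip_sum_qtl >= 0.5)
            )
            for p in support.values()
        )
        rows.append(
            {
                "gwas_cs_id": gwas_id,
                "qtl_cs_id": qtl_id,
                "methods": ",".join(labels),
                "n_methods": len(labels),
                "same_signal": verdict,
                "low_confidence": fails_pip,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gwas_cs_id", "qtl_cs_id", "methods", "n_methods",
                 "same_signal", "low_confidence"],
    )


def clpp_from_pip_tables(pip_table_gwas, pip_table_qtl) -> float:
    """CLPP directly from two variant_id -> PIP tables.

    Accepts pandas Series indexed by variant_id or DataFrames with columns
    (variant_id, pip); lets externally produced fine-mapping PIP files be
    consumed without constructing CredibleSet objects.
    """
    def as_series(t):
        if isinstance(t, pd.DataFrame):
            t = t.set_index("variant_id")["pip"]
        s = pd.Series(t, dtype=float)
        if s.index.has_duplicates:
            raise ValueError("PIP table has non-unique variant IDs")
        return s

    a, b = as_series(pip_table_gwas), as_series(pip_table_qtl)
    shared = a.index.intersection(b.index)
    products = (a[shared] * b[shared]).to_numpy()
    if np.any(products >= 1.0):
        return 1.0
    log_surv = np.log1p(-products).sum()
    return float(-np.expm1(log_surv))
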