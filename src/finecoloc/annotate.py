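"""Genomic annotation of fine-mapped and colocalized signals.

Conventions: variant positions and gene spans are 1-based inclusive (GTF
dialect); BED input is converted on read.  Nearest-gene signed distances
follow the closest-features dialect: 0 inside the gene, negative when the
gene lies upstream (left) of the variant, positive when downstream (right).
Open-chromatin membership is half-open [start, end).  Splice-junction
windows default to 25 bp around intron boundaries, with donor/acceptor side
assignment by gene strand when supplied (``+`` assumed otherwise, with a
logged caveat).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .finemap import CredibleSet, parse_variant_id

logger = logging.getLogger(__name__)

GENE_MODEL_COLUMNS = ["gene_id", "gene_name", "chrom", "start", "end", "strand", "biotype"]


def nearest_gene(variant, gene_models: pd.DataFrame, coding_only: bool = False):
    """Nearest gene (optionally protein-coding only) with signed distance.

    Parameters
    ----------
    variant : (chrom, pos) tuple or a ``chrom_pos_ref_alt_build`` variant ID
    gene_models : DataFrame with GENE_MODEL_COLUMNS (1-based inclusive spans)
    coding_only : restrict candidates to biotype == "protein_coding"

    Returns
    -------
    (gene, signed_distance) : (pandas.Series, int)
        distance 0 if the variant lies inside the gene span; otherwise the
        gap, negative when the gene is left of the variant.  Ties on
        |distance| are broken by smaller gene start, then lexical gene_id.
    """
    if isinstance(variant, str):
        chrom, pos, *_ = parse_variant_id(variant)
    else:
        chrom, pos = variant
    cand = gene_models[gene_models["chrom"] == chrom]
    if cand.empty:
        raise ValueError(f"chromosome {chrom!r} absent from gene models")
    if coding_only:
        cand = cand[cand["biotype"] == "protein_coding"]
        if cand.empty:
            raise ValueError(f"no protein_coding gene on chromosome {chrom!r}")
    start = cand["start"].to_numpy()
    end = cand["end"].to_numpy()
    dist = np.where(
        (start <= pos) & (pos <= end), 0,
        np.where(end < pos, -(pos - end), start - pos),
    )
    order = np.lexsort((cand["gene_id"].to_numpy(), start, np.abs(dist)))
    best = order[0]
    return cand.iloc[best], int(dist[best])


def nearest_genes(variants, gene_models: pd.DataFrame,
                  coding_only: bool = False) -> pd.DataFrame:
    """Vectorized convenience wrapper over nearest_gene for many variants."""
    rows = []
    for v in variants:
        if isinstance(v, str):
            chrom, pos, *_ = parse_variant_id(v)
            vid = v
        else:
            chrom, pos = v
            vid = f"{chrom}:{pos}"
        gene, d = nearest_gene((chrom, pos), gene_models, coding_only)
        rows.append(
            {"variant_id": vid, "gene_id": gene["gene_id"],
             "gene_name": gene["gene_name"], "signed_distance": d}
        )
    return pd.DataFrame(rows)


def _intron_frame(introns) -> pd.DataFrame:
    df = pd.DataFrame(introns) if not isinstance(introns, pd.DataFrame) else introns.copy()
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"intron table lacks column {col!r}")
    if "strand" not in df.columns:
        df["strand"] = "."
    if "event" not in df.columns:
        df["event"] = [
            f"{c}:{s}-{e}" for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]
    if (df["start"] >= df["end"]).any():
        bad = df.loc[df["start"] >= df["end"], "event"].iloc[0]
        raise ValueError(f"malformed intron coordinates (start >= end): {bad}")
    return df


def splice_window_hits(credible_set, introns, window: int = 25) -> pd.DataFrame:
    """Credible-set variants within ``window`` bp of intron boundaries.

    One record per (member variant, intron boundary) with |pos - boundary| <=
    window: the boundary side (donor = intron start on the + orientation,
    acceptor = intron end; swapped on -), the signed offset pos - boundary,
    and a canonical-dinucleotide flag for variants on the first or last two
    intronic bases.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    introns = _intron_frame(introns)
    if isinstance(credible_set, CredibleSet):
        members = list(credible_set.member_ids)
        cs_id = credible_set.cs_id
    else:
        members = list(credible_set)
        cs_id = ""
    if (introns["strand"] == ".").any():
        logger.warning(
            "splice_window_hits: intron strand missing; assuming + orientation "
            "for donor/acceptor side assignment"
        )
    rows = []
    for vid in members:
        chrom, pos, *_ = parse_variant_id(vid)
        sub = introns[introns["chrom"] == chrom]
        for intron in sub.itertuples(index=False):
            minus = intron.strand == "-"
            boundaries = (
                (intron.start, "acceptor" if minus else "donor",
                 {intron.start, intron.start + 1}),
                (intron.end, "donor" if minus else "acceptor",
                 {intron.end, intron.end - 1}),
            )
            for bpos, side, canon in boundaries:
                if abs(pos - bpos) <= window:
                    rows.append(
                        {
                            "cs_id": cs_id,
                            "variant_id": vid,
                            "event": intron.event,
                            "side": side,
                            "boundary_pos": int(bpos),
                            "offset": int(pos - bpos),
                            "canonical_dinucleotide": pos in canon,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["cs_id", "variant_id", "event", "side", "boundary_pos",
                 "offset", "canonical_dinucleotide"],
    )


def splice_concordance(hits: pd.DataFrame, scores: pd.DataFrame,
                       observed_direction: pd.DataFrame) -> pd.DataFrame:
    """Predicted-vs-observed splicing direction per (variant, event).

    ``scores`` carries precomputed predicted splicing-change scores for the
    alt vs ref allele (columns variant_id, event, score); ``observed_direction``
    the observed alt-allele effect sign on intron excision (columns
    variant_id, event, observed_sign).  Verdicts: concordant / discordant /
    indeterminate (score 0) / unscored (no score row).
    """
    score_map = {
        (r.variant_id, r.event): float(r.score)
        for r in scores.itertuples(index=False)
    }
    rows = []
    for r in observed_direction.itertuples(index=False):
        key = (r.variant_id, r.event)
        if key not in score_map:
            verdict = "unscored"
            score = np.nan
        else:
            score = score_map[key]
            if score == 0 or r.observed_sign == 0:
                verdict = "indeterminate"
            else:
                verdict = "concordant" if np.sign(score) == np.sign(r.observed_sign) \
                    else "discordant"
        rows.append(
            {"variant_id": r.variant_id, "event": r.event,
             "score": score, "observed_sign": r.observed_sign, "verdict": verdict}
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "event", "score", "observed_sign", "verdict"]
    )


def direction_concordance(pairs: pd.DataFrame) -> pd.DataFrame:
    """Cross-tissue effect-direction concordance per target feature.

    ``pairs`` needs columns (feature, tissue, effect_sign) with effect signs
    already expressed relative to the GWAS trait-increasing allele.  Returns
    per feature: tissue count, majority-sign fraction and an all-equal
    consistency flag (single-tissue features are consistent by definition).
    """
    rows = []
    for feature, grp in pairs.groupby("feature", sort=True):
        signs = np.sign(grp["effect_sign"].to_numpy(dtype=float))
        counts = pd.Series(signs).value_counts()
        rows.append(
            {
                "feature": feature,
                "n_tissues": int(grp["tissue"].nunique()),
                "majority_fraction": float(counts.iloc[0] / len(signs)),
                "consistent": bool(len(counts) == 1),
            }
        )
    return pd.DataFrame(
        rows, columns=["feature", "n_tissues", "majority_fraction", "consistent"]
    )


def ocr_overlap(credible_sets, intervals: pd.DataFrame,
                gene_map: dict | None = None):
    """Open-chromatin overlap flags per credible set (and per gene roll-up).

    ``intervals`` columns (chrom, start, end) are half-open [start, end) on
    the variant coordinate line.  A set is flagged when any member position
    falls inside any interval.  ``gene_map`` (cs_id -> gene) triggers a
    per-gene any-set roll-up.

    Returns
    -------
    per_set : DataFrame (cs_id, in_ocr) — or (per_set, per_gene) when
    gene_map is given.
    """
    by_chrom = {}
    if len(intervals):
        for chrom, grp in intervals.groupby("chrom"):
            by_chrom[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy())
    rows = []
    for cs in credible_sets:
        hit = False
        for vid in cs.member_ids:
            chrom, pos, *_ = parse_variant_id(vid)
            if chrom not in by_chrom:
                continue
            starts, ends = by_chrom[chrom]
            if np.any((starts <= pos) & (pos < ends)):
                hit = True
                break
        rows.append({"cs_id": cs.cs_id, "in_ocr": hit})
    per_set = pd.DataFrame(rows, columns=["cs_id", "in_ocr"])
    if gene_map is None:
        return per_set
    per_set["gene"] = per_set["cs_id"].map(gene_map)
    per_gene = (
        per_set.dropna(subset=["gene"])
        .groupby("gene", sort=True)["in_ocr"].any()
        .rename("any_set_in_ocr").reset_index()
    )
    return per_set.drop(columns="gene"), per_gene
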