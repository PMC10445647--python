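"""Readers and writers for the pipeline's plain-text formats.

Tabular outputs are TSV; LD matrices are square whitespace-delimited text;
the atlas is a genes x cell-types CSV; gene models come from 6+ column BED
or GTF; open-chromatin intervals from BED.  BED coordinates (0-based
half-open) are converted on read to the 1-based conventions used internally.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import CellTypeData, specificity
from .finemap import CredibleSet, LocusData

FLOAT_FORMAT = "%.10g"

SUMSTAT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt",
                   "beta", "se", "z", "n", "maf"]
CS_COLUMNS = ["cs_id", "variant_id", "pip", "lead", "coverage_achieved",
              "signal_pip_total"]


def write_sumstats(locus: LocusData, path) -> None:
    locus.to_frame()[SUMSTAT_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_sumstats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ld(ld: np.ndarray, path) -> None:
    np.savetxt(path, ld, fmt=FLOAT_FORMAT)


def read_ld(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))


def read_locus(sumstats_path, ld_path) -> LocusData:
    return LocusData.from_frame(read_sumstats(sumstats_path), read_ld(ld_path))


def write_truth(truth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True) + "\n")


def write_credible_sets(credible_sets, path) -> None:
    rows = []
    for cs in credible_sets:
        for vid, pip in zip(cs.member_ids, cs.pip):
            rows.append(
                {
                    "cs_id": cs.cs_id,
                    "variant_id": vid,
                    "pip": pip,
                    "lead": vid == cs.lead_id,
                    "coverage_achieved": cs.coverage_achieved,
                    "signal_pip_total": cs.signal_pip_total,
                }
            )
    pd.DataFrame(rows, columns=CS_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_credible_sets(path) -> list:
    df = pd.read_csv(path, sep="\t")
    sets = []
    for cs_id, grp in df.groupby("cs_id", sort=True):
        grp = grp.sort_values(["pip", "variant_id"], ascending=[False, True],
                              kind="stable")
        sets.append(
            CredibleSet(
                cs_id=str(cs_id),
                member_ids=grp["variant_id"].to_numpy(dtype=object),
                pip=grp["pip"].to_numpy(dtype=float),
                signal_pip_total=float(grp["signal_pip_total"].iloc[0]),
                coverage_achieved=float(grp["coverage_achieved"].iloc[0]),
                lead_id=str(grp.loc[grp["lead"], "variant_id"].iloc[0]),
            )
        )
    return sets


def write_atlas(ctd: CellTypeData, path) -> None:
    ctd.mean_expr.to_csv(path, index_label="gene", float_format=FLOAT_FORMAT)


def read_atlas(path, floor: float = 0.1) -> CellTypeData:
    mean_expr = pd.read_csv(path, index_col="gene")
    return specificity(mean_expr, floor=floor)


def read_gene_set(path) -> list:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gene_set(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_bed(path) -> pd.DataFrame:
    """Gene models from BED6(+2): chrom start end gene_id score strand
    [gene_name] [biotype].  Coordinates converted to 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError("gene BED needs at least 6 columns")
    out = pd.DataFrame(
        {
            "gene_id": df[3].astype(str),
            "gene_name": df[6].astype(str) if df.shape[1] > 6 else df[3].astype(str),
            "chrom": df[0].astype(str),
            "start": df[1].astype(int) + 1,
            "end": df[2].astype(int),
            "strand": df[5].astype(str),
            "biotype": df[7].astype(str) if df.shape[1] > 7 else "protein_coding",
        }
    )
    if out["gene_id"].duplicated().any():
        raise ValueError("gene_id values must be unique")
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gene_gtf(path) -> pd.DataFrame:
    """Gene models from GTF 'gene' records (already 1-based inclusive)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "feature", "start", "end", "score",
               "strand", "frame", "attributes"],
    )
    df = df[df["feature"] == "gene"]
    attrs = df["attributes"].map(lambda s: dict(_GTF_ATTR.findall(s)))
    out = pd.DataFrame(
        {
            "gene_id": attrs.map(lambda a: a.get("gene_id", "")),
            "gene_name": attrs.map(lambda a: a.get("gene_name", "")),
            "chrom": df["chrom"].astype(str),
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "strand": df["strand"].astype(str),
            "biotype": attrs.map(
                lambda a: a.get("gene_type", a.get("gene_biotype", ""))
            ),
        }
    )
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def read_bed_intervals(path) -> pd.DataFrame:
    """BED intervals to the internal half-open 1-based convention.

    A BED record [s, e) (0-based) covers 1-based positions s+1 .. e, i.e.
    half-open [s+1, e+1) on the variant coordinate line.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(int) + 1,
            "end": df[2].astype(int) + 1,
        }
    )


def read_introns(path) -> pd.DataFrame:
    """Intron table: TSV with columns chrom, start, end [, strand, event] or a
    single 'event' column of chrom:start-end strings."""
    df = pd.read_csv(path, sep="\t")
    if "chrom" not in df.columns and "event" in df.columns:
        parts = df["event"].str.extract(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")
        df = pd.concat([df, parts], axis=1)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    return df


def read_qtl_metadata(path) -> pd.DataFrame:
    """QTL signal metadata TSV: cs_id, gene, intron, tissue, fdr, effect_sign."""
    return pd.read_csv(path, sep="\t")
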