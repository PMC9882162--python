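"""Per-gene genomic and epigenomic features: gene-body CG methylation from
per-cytosine bisulfite calls, TPM expression from read counts, distance to
the nearest transposable element, and the joined analysis table.

Conventions: all genomic coordinates are 1-based inclusive; the "gene body"
is the full annotated gene span (UTRs and introns included) for both
methylation and TE overlap; percentages are on the 0–100 scale.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 5

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "count_methylated",
                    "count_unmethylated", "context"]
INTERVAL_COLUMNS = ["chrom", "start", "end", "feature_id"]


class FeatureError(ValueError):
    pass


def filter_and_pair_cg(
    records: pd.DataFrame,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    context: str = "CG",
) -> pd.DataFrame:
    """Coverage-filter CG cytosines and average symmetric dyads.

    ``records`` needs columns chrom, pos (1-based), strand (+/-), context,
    count_methylated, count_unmethylated. Sites with total coverage below
    ``min_coverage`` are dropped. A CG dyad is the + strand cytosine at
    position p paired with the - strand cytosine at p+1; when both pass
    coverage the site value is the mean of the two percentages, otherwise
    the surviving strand's percentage; the site is anchored at the + strand
    position. Minus-strand cytosines with no plus-strand partner anywhere
    in the input are kept as orphans (with a logged warning).

    ``context`` selects the cytosine context; CHG/CHH records can be
    summarised descriptively with the same machinery (dyad averaging only
    applies meaningfully to the symmetric CG context).

    Returns a frame with columns chrom, pos (anchor), meth_pct,
    n_cytosines (1 or 2).
    """
    req = set(CYTOSINE_COLUMNS)
    if not req.issubset(records.columns):
        raise FeatureError(f"cytosine records need columns {sorted(req)}")
    cg = records[records["context"] == context].copy()
    plus_positions = set(
        map(tuple, cg.loc[cg["strand"] == "+", ["chrom", "pos"]].itertuples(
            index=False, name=None))
    )
    cov = cg["count_methylated"] + cg["count_unmethylated"]
    cg = cg[cov >= min_coverage].copy()
    if cg.empty:
        return pd.DataFrame(columns=["chrom", "pos", "meth_pct", "n_cytosines"])
    total = cg["count_methylated"] + cg["count_unmethylated"]
    cg["pct"] = 100.0 * cg["count_methylated"] / total
    # anchor: + strand at its own position, - strand at pos-1
    cg["anchor"] = np.where(cg["strand"] == "+", cg["pos"], cg["pos"] - 1)
    no_partner = np.array([(c, p - 1) not in plus_positions
                           for c, p in zip(cg["chrom"], cg["pos"])])
    orphans = cg[(cg["strand"] == "-").to_numpy() & no_partner]
    if len(orphans):
        logger.warning(
            "%d minus-strand CG cytosines have no plus-strand partner; "
            "used alone", len(orphans),
        )
    out = (cg.groupby(["chrom", "anchor"], sort=True)["pct"]
             .agg(["mean", "size"]).reset_index())
    out.columns = ["chrom", "pos", "meth_pct", "n_cytosines"]
    return out


def gene_body_methylation(
    site_values_by_replicate: Sequence[pd.DataFrame],
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene percent CG methylation, averaged per replicate then across
    replicates.

    ``site_values_by_replicate`` are `filter_and_pair_cg` outputs, one per
    biological replicate. Per replicate a gene's value is the unweighted
    mean of per-site percentages over sites inside its span; the gene-level
    value averages the replicates that have >= 1 covered site. Genes with
    no qualifying site in any replicate get NaN and the
    ``no-covered-cytosines`` flag.

    Returns gene_id, cg_methylation_pct, n_cg_sites (distinct covered
    anchor sites across replicates), excluded_flag.
    """
    req = set(INTERVAL_COLUMNS)
    if not req.issubset(genes.columns):
        raise FeatureError(f"gene intervals need columns {sorted(req)}")
    per_rep: list[pd.Series] = []
    site_keys: dict[str, set] = {g: set() for g in genes["feature_id"]}
    for rep in site_values_by_replicate:
        values = {}
        for chrom, sub in rep.groupby("chrom"):
            sub = sub.sort_values("pos")
            pos = sub["pos"].to_numpy()
            pct = sub["meth_pct"].to_numpy()
            csum = np.concatenate([[0.0], np.cumsum(pct)])
            g = genes[genes["chrom"] == chrom]
            lo = np.searchsorted(pos, g["start"].to_numpy(), side="left")
            hi = np.searchsorted(pos, g["end"].to_numpy(), side="right")
            for gid, l, h in zip(g["feature_id"], lo, hi):
                if h > l:
                    values[gid] = (csum[h] - csum[l]) / (h - l)
                    site_keys[gid].update(zip([chrom] * (h - l), pos[l:h]))
        per_rep.append(pd.Series(values, dtype=float))
    mat = pd.DataFrame(per_rep).T.reindex(genes["feature_id"])
    mean = mat.mean(axis=1)  # skips replicates with no covered site
    out = pd.DataFrame({
        "gene_id": genes["feature_id"].to_numpy(),
        "cg_methylation_pct": mean.to_numpy(),
        "n_cg_sites": [len(site_keys[g]) for g in genes["feature_id"]],
    })
    out["excluded_flag"] = np.where(
        out["cg_methylation_pct"].isna(), "no-covered-cytosines", ""
    )
    return out


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from a genes x replicates count matrix.

    rate_g = counts_g / (length_g / 1000); TPM_g = rate_g / sum(rates) x 1e6,
    so each replicate column sums to 1e6. ``lengths`` (bp, > 0) is aligned
    on the count index.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise FeatureError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise FeatureError("gene lengths must be positive")
    rates = counts.div(lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    if (totals <= 0).any():
        raise FeatureError("a replicate has zero total counts")
    return rates.div(totals, axis=1) * 1.0e6


def mean_log2_tpm(tpm_table: pd.DataFrame) -> pd.Series:
    """Replicate-mean TPM, then log2(TPM + 1) for display/testing."""
    return np.log2(tpm_table.mean(axis=1) + 1.0)


def te_distance(genes: pd.DataFrame, tes: pd.DataFrame) -> pd.DataFrame:
    """Distance (bp) from each gene span to its nearest TE on the same
    chromosome.

    0 on any overlap (a TE inside UTR/intron sequence counts as distance
    0); otherwise the gap length max(start_g, start_t) - min(end_g, end_t)
    - 1 under 1-based inclusive coordinates, so directly adjacent features
    are at distance 0. Genes on chromosomes with no TE get NaN with a
    warning. Strand is ignored.
    """
    for df, what in ((genes, "genes"), (tes, "TEs")):
        if not set(INTERVAL_COLUMNS).issubset(df.columns):
            raise FeatureError(f"{what} need columns {INTERVAL_COLUMNS}")
    rows = []
    te_by_chrom = dict(tuple(tes.groupby("chrom")))
    for chrom, g in genes.groupby("chrom"):
        t = te_by_chrom.get(chrom)
        if t is None or t.empty:
            logger.warning("no TEs on chromosome %s; distances are missing",
                           chrom)
            for gid in g["feature_id"]:
                rows.append((gid, np.nan, False))
            continue
        ts = t["start"].to_numpy()
        te_ = t["end"].to_numpy()
        for gid, gs, ge in zip(g["feature_id"], g["start"], g["end"]):
            gaps = np.maximum(gs, ts) - np.minimum(ge, te_) - 1
            overlap = (ts <= ge) & (te_ >= gs)
            if overlap.any():
                rows.append((gid, 0, True))
            else:
                rows.append((gid, int(np.maximum(gaps, 0).min()), False))
    out = pd.DataFrame(rows, columns=["gene_id", "te_distance_bp",
                                      "te_within_gene"])
    return out


def assemble_feature_table(
    hv_calls: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
    te: pd.DataFrame | None = None,
    mutation_scores: pd.DataFrame | None = None,
    cluster: pd.DataFrame | None = None,
    nlr_class: pd.DataFrame | None = None,
    exclusions: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Outer-join all per-gene tables into the master analysis table.

    Every input needs a ``gene_id`` column; a duplicated gene_id anywhere
    is an error. ``exclusions`` maps a flag name (e.g. ``unmappable``) to
    gene ids: flagged genes stay in the table, the affected measurement is
    blanked (expression for ``unmappable``), and the flag is recorded in
    ``excluded_flags``.
    """
    pieces = [p for p in (hv_calls, expression, methylation, te,
                          mutation_scores, cluster, nlr_class)
              if p is not None]
    if not pieces:
        raise FeatureError("nothing to join")
    table: pd.DataFrame | None = None
    for piece in pieces:
        if "gene_id" not in piece.columns:
            raise FeatureError("every input table needs a gene_id column")
        if piece["gene_id"].duplicated().any():
            dup = piece.loc[piece["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FeatureError(f"duplicate gene_id {dup!r}")
        table = piece if table is None else table.merge(
            piece, on="gene_id", how="outer")
    assert table is not None
    flags = {g: [] for g in table["gene_id"]}
    if "excluded_flag" in table.columns:
        for g, f in zip(table["gene_id"], table.pop("excluded_flag")):
            if isinstance(f, str) and f:
                flags[g].append(f)
    for flag, ids in (exclusions or {}).items():
        for g in ids:
            if g in flags:
                flags[g].append(flag)
        if flag == "unmappable":
            blank = table["gene_id"].isin(set(ids))
            for col in table.columns:
                if col.startswith("tpm") or col == "mean_log2_tpm":
                    table.loc[blank, col] = np.nan
    table["excluded_flags"] = [";".join(sorted(set(flags[g])))
                               for g in table["gene_id"]]
    return table
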