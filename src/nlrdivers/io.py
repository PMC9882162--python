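"""Readers and writers for the external formats the pipeline consumes.

Coordinates are 1-based inclusive everywhere inside the package (matching
GFF3 and the TAIR TE table); the only conversion happens at the BED
boundary (0-based half-open), provided here as an explicit round-trippable
pair of functions.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .alignment import Alignment, AlignmentError, CodonAlignment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_fasta_alignment(
    path: str | Path,
    alphabet: str = "protein",
    gene_id: str | None = None,
    codon: bool = False,
) -> Alignment:
    """Read a multi-FASTA alignment; gene_id defaults to the file stem.

    Residues are uppercased; ragged records raise an error naming the
    offending record id.
    """
    path = Path(path)
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    length = len(records[0][1])
    for sid, seq in records:
        if len(seq) != length:
            raise AlignmentError(
                f"{path}: record {sid!r} has length {len(seq)}, "
                f"expected {length}"
            )
    cls = CodonAlignment if codon else Alignment
    kwargs = {} if codon else {"alphabet": alphabet}
    aln = cls(records=tuple(records), **kwargs)
    object.__setattr__(aln, "gene_id", gene_id or path.stem)
    return aln


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_alignment_dir(
    directory: str | Path, alphabet: str = "protein", codon: bool = False
) -> dict[str, Alignment]:
    """All ``.fa``/``.fasta`` alignments in a directory, keyed by file stem."""
    directory = Path(directory)
    out: dict[str, Alignment] = {}
    for path in sorted(directory.glob("*")):
        if path.suffix.lower() not in (".fa", ".fasta", ".fna", ".faa"):
            continue
        out[path.stem] = read_fasta_alignment(path, alphabet=alphabet,
                                              codon=codon)
    return out


# ---------------------------------------------------------------------------
# gene and TE annotations
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Gene spans and exon-union lengths from a GFF3 gene annotation.

    Returns (genes, exon_union_length): genes has columns chrom, start,
    end, strand, feature_id (1-based inclusive); exon_union_length maps
    gene id -> merged exon bp (the effective length used for TPM). Genes
    without an ID attribute are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    exon_len: dict[str, int] = {}
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("ID", [None])[0]
        if gid is None:
            logger.warning("gene at %s:%d-%d has no ID; skipped",
                           gene.seqid, gene.start, gene.end)
            continue
        rows.append((gene.seqid, gene.start, gene.end, gene.strand, gid))
        exons = [(f.start, f.end)
                 for f in db.children(gene, featuretype="exon")]
        if not exons:
            exons = [(gene.start, gene.end)]
        exon_len[gid] = merged_interval_length(exons)
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                        "feature_id"])
    return genes, pd.Series(exon_len, name="exon_union_bp")


def merged_interval_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by a union of 1-based inclusive intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_start = cur_end = None
    for s, e in ivs:
        if cur_end is None or s > cur_end + 1:
            if cur_end is not None:
                total += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


_TE_NAME_RE = re.compile(r"^AT([0-9MC])TE", re.IGNORECASE)


def read_te_table(path: str | Path) -> pd.DataFrame:
    """TAIR-style transposable-element table.

    Expects a tab-separated file whose first columns are TE name,
    orientation, start, end (header tolerated); the chromosome is inferred
    from the TE name prefix (AT3TE... -> Chr3). Rows with start > end are
    swapped (orientation normalisation); unparseable rows are skipped with
    a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 4:
        raise ValueError("TE table needs >= 4 columns "
                         "(name, orientation, start, end)")
    name_c, orient_c, start_c, end_c = cols[:4]
    rows = []
    n_skipped = 0
    for name, orient, start, end in zip(df[name_c], df[orient_c],
                                        df[start_c], df[end_c]):
        m = _TE_NAME_RE.match(str(name))
        try:
            s, e = int(start), int(end)
        except (TypeError, ValueError):
            m = None
        if m is None:
            n_skipped += 1
            continue
        chrom = f"Chr{m.group(1).upper()}"
        strand = "+" if str(orient).lower().startswith(("t", "+")) else "-"
        if s > e:
            s, e = e, s
            strand = "-" if strand == "+" else "+"
        rows.append((chrom, s, e, strand, str(name)))
    if n_skipped:
        logger.warning("skipped %d malformed TE rows", n_skipped)
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                      "feature_id"])
    out.attrs["n_skipped"] = n_skipped
    return out


# ---------------------------------------------------------------------------
# cytosine reports, counts, scores
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Bismark-style per-cytosine report.

    Canonical layout (no header): chrom, pos, strand, count_methylated,
    count_unmethylated, context[, trinucleotide]. Returns the standardised
    cytosine-record frame used by `features.filter_and_pair_cg`.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 6:
        raise ValueError("cytosine report needs >= 6 columns")
    out = pd.DataFrame({
        "chrom": df[0],
        "pos": df[1].astype(int),
        "strand": df[2],
        "count_methylated": df[3].astype(int),
        "count_unmethylated": df[4].astype(int),
        "context": df[5],
    })
    bad = ~out["context"].isin(["CG", "CHG", "CHH"])
    if bad.any():
        logger.warning("dropping %d rows with unknown context", int(bad.sum()))
        out = out[~bad]
    return out.reset_index(drop=True)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x replicate read-count TSV (first column gene_id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_scores(path: str | Path, value_column: str | None = None) -> pd.Series:
    """Per-gene score TSV (gene_id, score)."""
    df = pd.read_csv(path, sep="\t")
    col = value_column or df.columns[1]
    return pd.Series(df[col].to_numpy(), index=df[df.columns[0]], name=col)


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_domain_annotations(path: str | Path):
    """Domain annotation TSV: sequence_id, domain, start, end (header row)."""
    from .popgen import DomainAnnotation

    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    return [
        DomainAnnotation(str(r[cols[0]]), str(r[cols[1]]),
                         int(r[cols[2]]), int(r[cols[3]]))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_vcf_genotypes(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Haplotype allele matrix from a (minimal, GT-only) VCF.

    Phased and unphased genotypes are treated identically as allele
    multisets; each diploid sample contributes two haplotype columns and
    missing alleles are coded -1. ``region`` is (chrom, start, end),
    1-based inclusive, filtered in Python (no index required). Returns
    (genotypes with shape (n_sites, n_haplotypes), positions, sample ids).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    positions = []
    for variant in vcf:
        if region is not None:
            chrom, start, end = region
            if variant.CHROM != chrom or not (start <= variant.POS <= end):
                continue
        alleles = []
        for gt in variant.genotypes:  # [a0, a1, phased] per sample
            for a in gt[:-1]:
                alleles.append(-1 if a is None or a < 0 else int(a))
        rows.append(alleles)
        positions.append(variant.POS)
    if not rows:
        return (np.empty((0, 0), dtype=int), np.array([], dtype=int), samples)
    return np.array(rows, dtype=int), np.array(positions, dtype=int), samples


# ---------------------------------------------------------------------------
# BED round trip
# ---------------------------------------------------------------------------

def intervals_to_bed(df: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive intervals -> BED (0-based half-open)."""
    out = df.copy()
    out["start"] = out["start"] - 1
    return out


def bed_to_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """BED (0-based half-open) -> 1-based inclusive intervals."""
    out = df.copy()
    out["start"] = out["start"] + 1
    return out
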