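"""Population-genetic summary statistics from alignments and genotype
matrices: segregating sites, nucleotide diversity (pi), Watterson's theta,
Tajima's D, Nei–Gojobori piN/piS, domain subsets and sliding windows.

Missing-data policy for alignment statistics is *complete deletion*: any
column containing a gap or ambiguous base in any sequence is dropped before
counting, so S, the mean pairwise difference count Pi, and the Tajima
constants all refer to one shared site set. Genotype-matrix statistics
(`stats_from_genotypes`) instead use pairwise-complete allele counts per
site, because per-site sample sizes vary in population VCFs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alignment import Alignment, CodonAlignment
from .codon import NG_SITES, STOP_CODONS, codon_pair_diffs

logger = logging.getLogger(__name__)

_ACGT = frozenset(b"ACGT")


class PopGenError(ValueError):
    pass


class NoAnalyzableSitesError(PopGenError):
    """All columns were removed by complete deletion."""


def tajima_constants(n: int) -> dict[str, float]:
    """The Tajima (1989) normalising constants for sample size n >= 2."""
    if n < 2:
        raise PopGenError("Tajima constants require n >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


@dataclass(frozen=True)
class PopGenResult:
    n_sequences: int
    n_sites_analyzed: int
    S: int
    pi: float               # per analyzed site
    theta_w: float          # per analyzed site, S / (a1 * sites)
    pi_total: float         # mean pairwise difference count (Tajima's Pi)
    tajima_d: float         # NaN when undefined
    tajima_d_reason: str | None = None
    constants: dict = field(default_factory=dict)


def _analyzed_column_mask(aln: Alignment) -> np.ndarray:
    mat = aln.to_matrix()
    ok = np.isin(mat, [b"A", b"C", b"G", b"T"])
    return ok.all(axis=0)


def _alignment_site_stats(aln: Alignment) -> tuple[int, int, float]:
    """(n_sites_analyzed, S, total mean pairwise differences Pi).

    Per retained column, the pairwise-difference count is computed from
    allele counts: C(n,2) - sum_a C(n_a,2).
    """
    if aln.n_sequences < 2:
        raise PopGenError("need >= 2 sequences")
    mask = _analyzed_column_mask(aln)
    n_sites = int(mask.sum())
    if n_sites == 0:
        raise NoAnalyzableSitesError(
            "no columns free of gaps/ambiguity under complete deletion"
        )
    mat = aln.to_matrix()[:, mask]
    n = aln.n_sequences
    counts = np.stack([(mat == b).sum(axis=0)
                       for b in (b"A", b"C", b"G", b"T")])
    poly = (counts > 0).sum(axis=0) > 1
    S = int(poly.sum())
    total_pairs = n * (n - 1) / 2.0
    same_pairs = (counts * (counts - 1) // 2).sum(axis=0)
    diff_sum = float((total_pairs - same_pairs)[poly].sum())
    return n_sites, S, diff_sum / total_pairs


def segregating_sites(aln: Alignment) -> int:
    """Count of analyzed columns carrying >= 2 distinct unambiguous bases."""
    _, S, _ = _alignment_site_stats(aln)
    return S


def nucleotide_diversity(aln: Alignment) -> float:
    """Per-site pi: mean pairwise differences / analyzed sites."""
    n_sites, _, pi_total = _alignment_site_stats(aln)
    return pi_total / n_sites


def tajimas_d(aln: Alignment) -> PopGenResult:
    """Full summary: S, pi, theta_W, and Tajima's D with its constants.

    D is computed on the total scale, D = (Pi - S/a1) / sqrt(e1 S + e2 S (S-1)),
    and is flagged undefined (NaN, with a reason) when S == 0 or n < 3.
    """
    n_sites, S, pi_total = _alignment_site_stats(aln)
    n = aln.n_sequences
    consts = tajima_constants(n)
    theta_w = S / (consts["a1"] * n_sites)
    pi = pi_total / n_sites
    d = math.nan
    reason: str | None = None
    if n < 3:
        reason = "n_sequences < 3"
    elif S == 0:
        reason = "no segregating sites"
    else:
        var = consts["e1"] * S + consts["e2"] * S * (S - 1)
        if var <= 0:
            # e1 vanishes at n=3, so S=1 gives a zero variance estimate
            reason = "zero variance estimate"
        else:
            d = (pi_total - S / consts["a1"]) / math.sqrt(var)
    return PopGenResult(
        n_sequences=n, n_sites_analyzed=n_sites, S=S, pi=pi,
        theta_w=theta_w, pi_total=pi_total, tajima_d=d,
        tajima_d_reason=reason, constants=consts,
    )


# ---------------------------------------------------------------------------
# piN / piS
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PiNPiSResult:
    pi_n: float
    pi_s: float
    ratio: float            # NaN when piS == 0
    n_pairs: int
    mean_syn_sites: float
    mean_nonsyn_sites: float
    n_stop_fallbacks: int = 0


def pi_n_pi_s(aln: CodonAlignment, jc_correction: bool = False) -> PiNPiSResult:
    """Nei–Gojobori piN and piS, averaged over all sequence pairs.

    For each pair, codons where either sequence carries a gap, ambiguity or
    stop are skipped; synonymous/nonsynonymous site counts are averaged over
    the pair and differences are pathway-averaged. piS is the mean over
    pairs of syn_diffs/syn_sites (piN analogous); the ratio is NaN when
    piS == 0. ``jc_correction`` applies the Jukes–Cantor transform
    -3/4 ln(1 - 4p/3) to each pair's proportions before averaging.
    """
    if aln.n_sequences < 2:
        raise PopGenError("need >= 2 sequences")
    seqs = aln.sequences
    n = aln.n_sequences
    pn_vals: list[float] = []
    ps_vals: list[float] = []
    syn_sites_all: list[float] = []
    nonsyn_sites_all: list[float] = []
    n_fallback = 0
    any_codons = False
    for i in range(n):
        for j in range(i + 1, n):
            syn_sites = nonsyn_sites = syn_d = nonsyn_d = 0.0
            n_codons = 0
            for k in range(aln.n_codons):
                c1 = seqs[i][3 * k : 3 * k + 3]
                c2 = seqs[j][3 * k : 3 * k + 3]
                if (set(c1) | set(c2)) - set("ACGT"):
                    continue
                if c1 in STOP_CODONS or c2 in STOP_CODONS:
                    continue
                s1 = NG_SITES[c1]
                s2 = NG_SITES[c2]
                syn_sites += (s1[0] + s2[0]) / 2.0
                nonsyn_sites += (s1[1] + s2[1]) / 2.0
                if c1 != c2:
                    d = codon_pair_diffs(c1, c2)
                    syn_d += d.syn_diffs
                    nonsyn_d += d.nonsyn_diffs
                    if d.stop_fallback:
                        n_fallback += 1
                n_codons += 1
            if n_codons == 0:
                continue
            any_codons = True
            ps = syn_d / syn_sites if syn_sites > 0 else 0.0
            pn = nonsyn_d / nonsyn_sites if nonsyn_sites > 0 else 0.0
            if jc_correction:
                ps = _jc(ps)
                pn = _jc(pn)
            ps_vals.append(ps)
            pn_vals.append(pn)
            syn_sites_all.append(syn_sites)
            nonsyn_sites_all.append(nonsyn_sites)
    if not any_codons:
        raise PopGenError("no analyzable codons in any sequence pair")
    pi_s = float(np.mean(ps_vals))
    pi_n = float(np.mean(pn_vals))
    ratio = pi_n / pi_s if pi_s > 0 else math.nan
    return PiNPiSResult(
        pi_n=pi_n, pi_s=pi_s, ratio=ratio, n_pairs=len(ps_vals),
        mean_syn_sites=float(np.mean(syn_sites_all)),
        mean_nonsyn_sites=float(np.mean(nonsyn_sites_all)),
        n_stop_fallbacks=n_fallback,
    )


def _jc(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# sliding windows and domain subsets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowStats:
    window_start: int   # 1-based inclusive alignment coordinate
    window_end: int
    midpoint: float
    stats: PopGenResult | None
    pin_pis: PiNPiSResult | None = None


def sliding_window_stats(
    aln: Alignment,
    window_bp: int = 300,
    step_bp: int = 75,
    include_pin_pis: bool = False,
) -> list[WindowStats]:
    """Summary statistics in complete sliding windows over the alignment.

    Windows are 1-based inclusive alignment coordinates starting at 1 and
    advancing by ``step_bp``; a trailing incomplete window is dropped. An
    alignment shorter than one window yields an empty list with a warning.
    Windows whose columns are all removed by complete deletion carry
    ``stats=None``.
    """
    if aln.length < window_bp:
        warnings.warn(
            f"alignment length {aln.length} shorter than window {window_bp}; "
            "no windows emitted"
        )
        return []
    out: list[WindowStats] = []
    start = 1
    while start + window_bp - 1 <= aln.length:
        end = start + window_bp - 1
        sub = aln.slice_columns(start - 1, end)
        try:
            stats = tajimas_d(sub)
        except NoAnalyzableSitesError:
            stats = None
        pnps = None
        if include_pin_pis and isinstance(sub, CodonAlignment):
            try:
                pnps = pi_n_pi_s(sub)
            except PopGenError:
                pnps = None
        out.append(WindowStats(start, end, (start + end) / 2.0, stats, pnps))
        start += step_bp
    return out


@dataclass(frozen=True)
class DomainAnnotation:
    """1-based inclusive residue range of one domain on one unaligned
    protein sequence."""

    sequence_id: str
    domain_label: str  # CC | TIR | NBARC | LRR | other
    residue_start: int
    residue_end: int

    def __post_init__(self) -> None:
        if self.residue_start < 1 or self.residue_end < self.residue_start:
            raise PopGenError(
                f"bad residue range {self.residue_start}..{self.residue_end} "
                f"for {self.sequence_id}"
            )


def assign_codon_column_domains(
    aln: CodonAlignment, annotations: Sequence[DomainAnnotation]
) -> list[str | None]:
    """Majority-vote domain label per codon column.

    Each sequence's unaligned residue ranges are mapped through its gaps; a
    codon column is assigned the label claimed by a strict majority (> 50%)
    of the sequences with a residue at that column. Ties and columns where
    annotations cover no strict majority are unassigned (None).
    """
    by_seq: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_seq.setdefault(ann.sequence_id, []).append(ann)

    labels: list[str | None] = []
    n_codons = aln.n_codons
    # per-sequence cumulative residue index at each codon column
    residue_idx = np.zeros((aln.n_sequences, n_codons), dtype=int)
    has_residue = np.zeros((aln.n_sequences, n_codons), dtype=bool)
    for s, seq in enumerate(aln.sequences):
        r = 0
        for k in range(n_codons):
            codon = seq[3 * k : 3 * k + 3]
            if codon == "---":
                continue
            r += 1
            residue_idx[s, k] = r
            has_residue[s, k] = True

    seq_ids = aln.sequence_ids
    for k in range(n_codons):
        votes: dict[str, int] = {}
        n_present = 0
        for s in range(aln.n_sequences):
            if not has_residue[s, k]:
                continue
            n_present += 1
            r = residue_idx[s, k]
            for ann in by_seq.get(seq_ids[s], ()):
                if ann.residue_start <= r <= ann.residue_end:
                    votes[ann.domain_label] = votes.get(ann.domain_label, 0) + 1
                    break
        winner = None
        if n_present:
            for label, count in votes.items():
                if count * 2 > n_present:
                    winner = label
                    break
        labels.append(winner)
    return labels


def domain_subset(
    aln: CodonAlignment,
    annotations: Sequence[DomainAnnotation],
    domain_label: str,
) -> CodonAlignment:
    """Concatenated codon columns assigned to ``domain_label`` by majority
    vote; empty (zero-length) alignment with a warning when none are."""
    labels = assign_codon_column_domains(aln, annotations)
    cols: list[int] = []
    for k, lab in enumerate(labels):
        if lab == domain_label:
            cols.extend(range(3 * k, 3 * k + 3))
    if not cols:
        warnings.warn(f"no columns assigned to domain {domain_label!r}")
    return aln.take_columns(cols)


# ---------------------------------------------------------------------------
# genotype matrices (VCF-derived)
# ---------------------------------------------------------------------------

def stats_from_genotypes(genotypes: np.ndarray) -> PopGenResult:
    """Summary statistics from a haplotype allele matrix.

    ``genotypes`` has shape (n_sites, n_haplotypes) with integer allele
    codes and -1 for missing. Per site, with m called haplotypes and allele
    counts n_a, pi_site = sum_{a<b} 2 n_a n_b / (m (m-1)); sites with fewer
    than 2 called haplotypes are dropped. S counts sites with >= 2 distinct
    called alleles; Tajima's D uses the median called sample size; per-site
    normalisation is over the retained sites.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2:
        raise PopGenError("genotype matrix must be 2-D (sites x haplotypes)")
    pi_sites: list[float] = []
    S = 0
    m_values: list[int] = []
    for row in genotypes:
        called = row[row >= 0]
        m = called.size
        if m < 2:
            continue
        m_values.append(m)
        _, counts = np.unique(called, return_counts=True)
        if counts.size > 1:
            S += 1
        same = np.sum(counts * (counts - 1))  # ordered same-pairs
        pi_sites.append(1.0 - same / (m * (m - 1)))
    if not pi_sites:
        raise NoAnalyzableSitesError("no sites with >= 2 called haplotypes")
    n_sites = len(pi_sites)
    pi_total = float(np.sum(pi_sites))
    n_med = int(np.median(m_values))
    consts = tajima_constants(n_med) if n_med >= 2 else {}
    theta_w = S / (consts["a1"] * n_sites) if consts else math.nan
    d = math.nan
    reason: str | None = None
    if n_med < 3:
        reason = "median called sample size < 3"
    elif S == 0:
        reason = "no segregating sites"
    else:
        var = consts["e1"] * S + consts["e2"] * S * (S - 1)
        if var <= 0:
            reason = "zero variance estimate"
        else:
            d = (pi_total - S / consts["a1"]) / math.sqrt(var)
    return PopGenResult(
        n_sequences=n_med, n_sites_analyzed=n_sites, S=S,
        pi=pi_total / n_sites, theta_w=theta_w, pi_total=pi_total,
        tajima_d=d, tajima_d_reason=reason, constants=consts,
    )
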