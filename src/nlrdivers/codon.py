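"""Nei–Gojobori synonymous/nonsynonymous site and difference counting.

Implements the NG86 scheme used for intraspecies piN/piS: each codon
position contributes a fractional synonymous site count (the share of its
possible single-base changes that preserve the amino acid, with changes to
stop codons excluded from the denominator), and differences between a codon
pair are classified by averaging over all minimal mutational pathways that
avoid stop codons. Raw proportions are used by default — no Jukes–Cantor
correction — which suits the low-divergence, within-species regime; the
correction is available behind a flag on the diversity estimator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]  # standard genetic code

GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    GENETIC_CODE[_stop] = "*"

STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(set(GENETIC_CODE) - STOP_CODONS))
_BASES = "ACGT"


class CodonError(ValueError):
    pass


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise CodonError(f"not a fully resolved codon: {codon!r}")
    if codon in STOP_CODONS:
        raise CodonError(f"stop codon {codon!r} has no site decomposition")
    return codon


def nei_gojobori_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Per position, synonymous fraction = synonymous single-base changes /
    non-stop single-base changes; the three fractions sum to the synonymous
    site count and the nonsynonymous count is its complement to 3.
    """
    codon = _check_codon(codon)
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        n_legal = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            n_legal += 1
            if GENETIC_CODE[mutant] == aa:
                n_syn += 1
        syn += n_syn / n_legal
    return syn, 3.0 - syn


#: site counts for all 61 sense codons, precomputed once
NG_SITES: dict[str, tuple[float, float]] = {
    c: nei_gojobori_sites(c) for c in SENSE_CODONS
}


@dataclass(frozen=True)
class PairDiffs:
    syn_diffs: float
    nonsyn_diffs: float
    #: True when every minimal pathway passed through a stop codon and the
    #: unrestricted pathway set was used instead
    stop_fallback: bool = False


def codon_pair_diffs(c1: str, c2: str) -> PairDiffs:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    codons.

    All orderings of the differing positions are enumerated; pathways whose
    intermediate codons are stops are excluded. When no stop-free pathway
    exists the average over the unrestricted set is returned with
    ``stop_fallback=True``. syn + nonsyn always equals the Hamming distance.
    """
    c1 = _check_codon(c1)
    c2 = _check_codon(c2)
    diff_positions = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_positions:
        return PairDiffs(0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        syn = nonsyn = 0
        current = c1
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        return syn, nonsyn

    legal: list[tuple[float, float]] = []
    unrestricted: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_positions):
        res = walk(order)
        if res is not None:
            legal.append(res)
        # unrestricted bookkeeping counts stop-crossing steps too
        syn = nonsyn = 0
        current = c1
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        unrestricted.append((syn, nonsyn))

    pool = legal if legal else unrestricted
    syn = sum(s for s, _ in pool) / len(pool)
    nonsyn = sum(n for _, n in pool) / len(pool)
    return PairDiffs(syn, nonsyn, stop_fallback=not legal)


@dataclass(frozen=True)
class SynNonsynCounts:
    """Accumulated fractional sites and differences for one sequence pair."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int
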