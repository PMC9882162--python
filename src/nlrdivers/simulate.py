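"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* `simulate_coalescent` — samples of aligned neutral coding sequences from
  the standard (no-recombination) coalescent with infinite-sites mutation
  at population-scaled rate theta per locus, so E[pi x L] = theta and
  E[S] = theta x a1(n). Backed by msprime; mutations are mapped to distinct
  integer positions on [1, length_bp].
* `simulate_codon_population` — a star genealogy of codon sequences where
  synonymous proposals are always retained and nonsynonymous ones with
  probability ``omega_accept``; mutations that would create stops are
  rejected. With omega_accept = 1 the Nei–Gojobori piN/piS of the output
  centres on 1; with 0, piN is identically 0.
* `simulate_feature_table` — per-gene feature tables (expression,
  methylation, TE distance, mutation-probability score) for an
  hv / non-hv / non-NLR gene universe with group effects injected in SD
  units, a CG-site covariate correlated with methylation (to exercise the
  matched permutation control), and injected missingness.

All generators are deterministic under their seed and also return a
ground-truth record of what was injected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import msprime
import numpy as np
import pandas as pd

from .alignment import Alignment, CodonAlignment
from .codon import GENETIC_CODE, SENSE_CODONS, STOP_CODONS

_BASES = "ACGT"

#: default hv-group effect sizes, in pooled-SD units of the background
#: distribution: higher expression, less gene-body methylation, TEs pulled
#: toward/into the gene, and a higher mutation-probability score
DEFAULT_EFFECT_SIZES = {
    "expression": 1.0,
    "methylation": -1.0,
    # strong pull toward (and into) the gene: reproduces the observed
    # hv-group contrast of median TE distance 0 kbp against ~2 kbp, with
    # most hv genes carrying a TE within the gene span
    "te_distance": -1.5,
    "mutation": 1.0,
}

#: study-like group sizes: a small hv class against a ~10x larger non-hv
#: class, inside a genome-scale pool of non-NLR genes
DEFAULT_GROUP_SIZES = {"hv": 15, "non-hv": 150}


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 10
    theta: float = 5.0
    length_bp: int = 1500
    seed: int = 0
    omega_accept: float = 1.0
    n_genes: int = 2000
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if sum(self.group_sizes.values()) > self.n_genes:
            raise ValueError("group sizes exceed n_genes")

    def to_dict(self) -> dict:
        return asdict(self)


def _child_seed(rng: np.random.Generator) -> int:
    # msprime wants 1 <= seed < 2^32; stay below 2^31 throughout
    return int(rng.integers(1, 2**31 - 1))


# ---------------------------------------------------------------------------
# neutral coalescent alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoalescentSim:
    alignment: Alignment
    site_positions: tuple[int, ...]  # 1-based, one per variant column
    tree_sequence: object            # tskit.TreeSequence, for cross-checks


def simulate_coalescent(
    n_samples: int, theta: float, length_bp: int, seed: int
) -> CoalescentSim:
    """A neutral-coalescent sample of aligned sequences.

    Haploid samples, constant population; per-site mutation rate
    theta / (2 L) on the coalescent time scale, infinite-sites placement
    mapped to distinct integer positions (collisions resampled uniformly
    from unused positions, with a warning). Monomorphic positions are
    filled with i.i.d. random bases.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    ts = msprime.sim_ancestry(
        samples=n_samples, ploidy=1, population_size=1.0,
        sequence_length=length_bp, random_seed=_child_seed(rng),
    )
    mts = msprime.sim_mutations(
        ts, rate=theta / (2.0 * length_bp), model=msprime.JC69(),
        discrete_genome=False, random_seed=_child_seed(rng),
    )
    base_idx = rng.integers(0, 4, size=length_bp)
    mat = np.frombuffer(_BASES.encode(), dtype="S1")[base_idx]
    mat = np.tile(mat, (n_samples, 1)).copy()

    used: set[int] = set()
    positions: list[int] = []
    collisions = 0
    for var in mts.variants():
        pos = int(math.floor(var.site.position))  # 0-based column
        if pos in used or pos >= length_bp:
            collisions += 1
            free = np.setdiff1d(np.arange(length_bp), np.fromiter(used, int))
            pos = int(rng.choice(free))
        used.add(pos)
        positions.append(pos + 1)
        alleles = np.array([a.encode() for a in var.alleles], dtype="S1")
        mat[:, pos] = alleles[var.genotypes]
    if collisions:
        warnings.warn(f"{collisions} mutation position collisions resampled")
    records = tuple(
        (f"s{i}", mat[i].tobytes().decode()) for i in range(n_samples)
    )
    aln = Alignment(records=records, alphabet="nucleotide")
    return CoalescentSim(aln, tuple(sorted(positions)), mts)


def simulate_coalescent_codon(
    n_samples: int, theta: float, n_codons: int, seed: int
) -> CodonAlignment:
    """Coalescent alignment re-wrapped as an in-frame codon alignment
    (frame is synthetic; used where the pipeline expects codon input)."""
    sim = simulate_coalescent(n_samples, theta, 3 * n_codons, seed)
    return CodonAlignment(records=sim.alignment.records)


# ---------------------------------------------------------------------------
# codon populations with tunable nonsynonymous acceptance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonMutationEvent:
    lineage: int
    codon_index: int
    position_in_codon: int
    from_base: str
    to_base: str
    synonymous: bool


@dataclass(frozen=True)
class CodonPopulationSim:
    alignment: CodonAlignment
    ancestral: str
    events: tuple[CodonMutationEvent, ...]

    @property
    def n_syn_retained(self) -> int:
        return sum(e.synonymous for e in self.events)

    @property
    def n_nonsyn_retained(self) -> int:
        return sum(not e.synonymous for e in self.events)


def random_sense_codon_sequence(
    n_codons: int,
    rng: np.random.Generator,
    exclude_amino_acids: str = "",
) -> str:
    """Random in-frame stop-free sequence.

    ``exclude_amino_acids`` drops all codons of the named residues. Leucine
    and arginine are the two amino acids whose synonymous codon networks
    span more than one codon position, so excluding "LR" yields a sequence
    on which purely synonymous evolution can never be scored as partially
    nonsynonymous by pathway-averaged counting (see the piN/piS notes).
    """
    pool = [c for c in SENSE_CODONS
            if GENETIC_CODE[c] not in set(exclude_amino_acids)]
    return "".join(rng.choice(pool) for _ in range(n_codons))


def simulate_codon_population(
    ancestral_codons: str | int,
    n_samples: int,
    mutations_per_lineage: float,
    omega_accept: float,
    seed: int,
) -> CodonPopulationSim:
    """Star-genealogy codon population with a nonsynonymous acceptance knob.

    ``ancestral_codons`` is an in-frame stop-free sequence, or an integer
    length to draw a random one. Each of ``n_samples`` lineages receives a
    Poisson(``mutations_per_lineage``) number of proposed single-base
    changes applied sequentially; proposals creating a stop codon are
    rejected outright, synonymous proposals always retained, nonsynonymous
    ones retained with probability ``omega_accept``. Retained events are
    logged so the output can be reconciled against a replay.
    """
    rng = np.random.default_rng(seed)
    if isinstance(ancestral_codons, int):
        ancestral = random_sense_codon_sequence(ancestral_codons, rng)
    else:
        ancestral = ancestral_codons.upper()
    if len(ancestral) % 3 != 0:
        raise ValueError("ancestral sequence length must be divisible by 3")
    for k in range(0, len(ancestral), 3):
        if ancestral[k : k + 3] in STOP_CODONS:
            raise ValueError("ancestral sequence contains an in-frame stop")
    if not 0.0 <= omega_accept <= 1.0:
        raise ValueError("omega_accept must lie in [0, 1]")

    length = len(ancestral)
    events: list[CodonMutationEvent] = []
    records = []
    for lineage in range(n_samples):
        seq = list(ancestral)
        n_prop = rng.poisson(mutations_per_lineage)
        for _ in range(n_prop):
            pos = int(rng.integers(0, length))
            current = seq[pos]
            # uniform over the 3 alternative bases
            alts = [b for b in _BASES if b != current]
            to = alts[int(rng.integers(0, 3))]
            k = pos // 3
            codon = "".join(seq[3 * k : 3 * k + 3])
            mutant = codon[: pos % 3] + to + codon[pos % 3 + 1 :]
            if mutant in STOP_CODONS:
                continue
            syn = GENETIC_CODE[mutant] == GENETIC_CODE[codon]
            if not syn and rng.random() > omega_accept:
                continue
            seq[pos] = to
            events.append(CodonMutationEvent(
                lineage=lineage, codon_index=k, position_in_codon=pos % 3,
                from_base=current, to_base=to, synonymous=syn,
            ))
        records.append((f"s{lineage}", "".join(seq)))
    aln = CodonAlignment(records=tuple(records))
    return CodonPopulationSim(aln, ancestral, tuple(events))


def replay_events(sim: CodonPopulationSim) -> CodonAlignment:
    """Re-apply the event log to the ancestral sequence; must reproduce the
    simulated alignment exactly (reconciliation oracle)."""
    seqs = {i: list(sim.ancestral) for i in range(sim.alignment.n_sequences)}
    for e in sim.events:
        pos = 3 * e.codon_index + e.position_in_codon
        assert seqs[e.lineage][pos] == e.from_base
        seqs[e.lineage][pos] = e.to_base
    records = tuple(
        (f"s{i}", "".join(seqs[i])) for i in range(sim.alignment.n_sequences)
    )
    return CodonAlignment(records=records)


_AA8 = "ACDEFGHI"  # 8-residue palette: uniform draws give up to 3 bits


def simulate_protein_alignment(
    n_sequences: int,
    length: int,
    n_variable_columns: int,
    seed: int,
    n_residues: int = 8,
) -> Alignment:
    """Protein population alignment with exactly ``n_variable_columns``
    high-entropy columns (residues drawn uniformly over ``n_residues``
    amino acids, ~3 bits realised for n_residues=8 at moderate sample
    sizes) and all remaining columns invariant. Ground truth for the
    hv / non-hv classification boundary."""
    if n_variable_columns > length:
        raise ValueError("more variable columns than columns")
    rng = np.random.default_rng(seed)
    palette = _AA8[:n_residues]
    var_cols = rng.choice(length, size=n_variable_columns, replace=False)
    const = rng.choice(list("LMNPQRSTVWY"), size=length)
    mat = np.tile(const, (n_sequences, 1))
    for c in var_cols:
        mat[:, c] = rng.choice(list(palette), size=n_sequences)
    records = tuple(
        (f"s{i}", "".join(mat[i])) for i in range(n_sequences)
    )
    return Alignment(records=records, alphabet="protein")


# ---------------------------------------------------------------------------
# per-gene feature tables with injected group effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureTableSim:
    table: pd.DataFrame
    ground_truth: dict


def simulate_feature_table(config: SimConfig) -> FeatureTableSim:
    """Per-gene features for an hv / non-hv / non-NLR universe.

    Background (non-NLR and non-hv) draws: expression lognormal (normal on
    the log2(TPM+1) display scale), methylation beta-like on [0, 100], TE
    distance exponential (mean 3 kbp) with a point mass at 0, mutation
    score normal. The hv group receives ``effect_sizes`` shifts in
    background-SD units (TE-distance shifts are applied as a subtraction
    clipped at 0, which grows the within-gene point mass). ``n_cg_sites``
    is drawn Poisson with a rate increasing in methylation so that
    gene-set methylation tests inherit a CG-site bias the matched test
    must correct. Missingness is injected per feature at
    ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_hv = config.group_sizes.get("hv", 0)
    n_nonhv = config.group_sizes.get("non-hv", 0)
    labels = np.array(
        ["hv"] * n_hv + ["non-hv"] * n_nonhv
        + ["non-NLR"] * (n - n_hv - n_nonhv)
    )
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    is_hv = labels == "hv"
    eff = {**DEFAULT_EFFECT_SIZES, **config.effect_sizes}

    # expression on the log2(TPM+1) scale
    expr_sd = 2.0
    expression = rng.normal(3.0, expr_sd, size=n)
    expression[is_hv] += eff["expression"] * expr_sd
    expression = np.clip(expression, 0.0, None)

    # methylation: beta-like percent; hv shift in SD units of the background
    base_mean, conc = 0.30, 8.0
    meth = 100.0 * rng.beta(base_mean * conc, (1 - base_mean) * conc, size=n)
    meth_sd = float(np.std(meth))
    meth[is_hv] = np.clip(meth[is_hv] + eff["methylation"] * meth_sd, 0, 100)

    # TE distance: exponential with a point mass at zero
    te_scale = 3000.0
    te = rng.exponential(te_scale, size=n)
    te[rng.random(n) < 0.10] = 0.0
    te_sd = float(np.std(te))
    te[is_hv] = np.clip(te[is_hv] + eff["te_distance"] * te_sd, 0.0, None)

    # mutation-probability score (unitless, consumed not computed)
    mut_sd = 0.2
    mutation = rng.normal(1.0, mut_sd, size=n)
    mutation[is_hv] += eff["mutation"] * mut_sd

    # CG-site covariate correlated with methylation
    n_cg = rng.poisson(10.0 + 60.0 * meth / 100.0, size=n) + 1

    cluster_member = rng.random(n) < np.where(labels == "non-NLR", 0.05, 0.5)
    nlr_class = np.where(
        labels == "non-NLR", "other",
        rng.choice(["CNL", "TNL", "RNL"], size=n, p=[0.5, 0.4, 0.1]),
    )

    table = pd.DataFrame({
        "gene_id": gene_ids,
        "hv_label": labels,
        "mean_log2_tpm": expression,
        "cg_methylation_pct": meth,
        "n_cg_sites": n_cg,
        "te_distance_bp": te,
        "te_within_gene": pd.array(te == 0.0, dtype="boolean"),
        "mutation_probability": mutation,
        "cluster_member": cluster_member,
        "nlr_class": nlr_class,
    })
    for col in ("mean_log2_tpm", "cg_methylation_pct", "te_distance_bp",
                "mutation_probability"):
        mask = rng.random(n) < config.missing_rate
        table.loc[mask, col] = np.nan
    table.loc[table["te_distance_bp"].isna(), "te_within_gene"] = pd.NA

    truth = {
        "seed": config.seed,
        "n_genes": n,
        "group_sizes": {"hv": int(n_hv), "non-hv": int(n_nonhv),
                        "non-NLR": int(n - n_hv - n_nonhv)},
        "effect_sizes": eff,
        "background_sd": {"expression": expr_sd, "methylation": meth_sd,
                          "te_distance": te_sd, "mutation": mut_sd},
        "missing_rate": config.missing_rate,
    }
    return FeatureTableSim(table, truth)
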