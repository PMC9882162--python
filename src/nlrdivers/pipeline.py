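"""End-to-end pipeline: entropy -> hv classification -> population
genetics -> feature assembly -> enrichment tests, on real inputs or fully
synthetic ones, with a JSON run manifest that makes every stochastic
output traceable to a seed.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alignment import Alignment, CodonAlignment
from .entropy import (DEFAULT_MIN_OCCUPANCY, HV_ENTROPY_THRESHOLD_BITS,
                      HV_MIN_POSITIONS, classify_hv, entropy_profile)
from .popgen import (DomainAnnotation, NoAnalyzableSitesError, PopGenError,
                     pi_n_pi_s, sliding_window_stats, domain_subset,
                     tajimas_d)
from .simulate import (SimConfig, simulate_coalescent_codon,
                       simulate_feature_table, simulate_protein_alignment)
from .stats import (bh_adjust, fisher_2x2, matched_perm_test, perm_diff_test,
                    rank_sum_test)

DOMAIN_LABELS = ("CC", "TIR", "NBARC", "LRR")


class PipelineError(RuntimeError):
    pass


def _stage_error(stage: str, exc: Exception) -> PipelineError:
    return PipelineError(f"[{stage}] {exc}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_entropy(
    alignments: Mapping[str, Alignment],
    threshold_bits: float = HV_ENTROPY_THRESHOLD_BITS,
    min_positions: int = HV_MIN_POSITIONS,
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-column entropy table and per-gene hv calls for a set of protein
    alignments."""
    col_rows = []
    call_rows = []
    for gene_id, aln in alignments.items():
        profile = entropy_profile(aln, min_occupancy=min_occupancy,
                                  gene_id=gene_id)
        call = classify_hv(profile, threshold_bits=threshold_bits,
                           min_positions=min_positions)
        for i, (h, occ) in enumerate(zip(profile.entropies,
                                         profile.occupancy)):
            col_rows.append((gene_id, i, h, occ))
        call_rows.append((gene_id, call.n_high_entropy_positions, call.label))
    columns = pd.DataFrame(
        col_rows, columns=["gene_id", "column_index", "entropy_bits",
                           "occupancy"])
    calls = pd.DataFrame(
        call_rows, columns=["gene_id", "n_high_entropy", "label"])
    return columns, calls


def stage_popgen(
    codon_alignments: Mapping[str, CodonAlignment],
    annotations: Mapping[str, Sequence[DomainAnnotation]] | None = None,
    windows: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-gene/region popgen table: CDS, optional domains, optional
    sliding windows. Regions with no analyzable sites are emitted with
    missing statistics."""
    rows = []

    def add(gene_id: str, region: str, aln: CodonAlignment) -> None:
        if aln.length == 0:
            return
        try:
            res = tajimas_d(aln)
        except (NoAnalyzableSitesError, PopGenError):
            return
        try:
            pnps = pi_n_pi_s(aln)
            pin, pis, ratio = pnps.pi_n, pnps.pi_s, pnps.ratio
        except PopGenError:
            pin = pis = ratio = math.nan
        rows.append((gene_id, region, res.n_sequences, res.n_sites_analyzed,
                     res.S, res.pi, res.theta_w, res.tajima_d, pin, pis,
                     ratio))

    for gene_id, aln in codon_alignments.items():
        add(gene_id, "CDS", aln)
        anns = (annotations or {}).get(gene_id)
        if anns:
            for label in DOMAIN_LABELS:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sub = domain_subset(aln, anns, label)
                if sub.length:
                    add(gene_id, label, sub)
        if windows is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wstats = sliding_window_stats(aln, windows[0], windows[1])
            for w in wstats:
                if w.stats is None:
                    continue
                rows.append((gene_id, f"window:{w.window_start}-{w.window_end}",
                             w.stats.n_sequences, w.stats.n_sites_analyzed,
                             w.stats.S, w.stats.pi, w.stats.theta_w,
                             w.stats.tajima_d, math.nan, math.nan, math.nan))
    return pd.DataFrame(rows, columns=[
        "gene_id", "region", "n", "sites", "S", "pi", "theta_w", "tajima_d",
        "piN", "piS", "piN_piS"])


def stage_enrichment(
    table: pd.DataFrame,
    n_replicates: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """The hv vs non-hv comparison battery on a feature table.

    Permutation tests (mean for expression/methylation/mutation, median
    for TE distance), rank-sum tests on the same features, Fisher's exact
    on TE-within-gene, and a covariate-matched permutation test of
    methylation against the non-NLR pool matched on measured CG sites.
    BH adjustment is applied within the permutation-test family and the
    rank-sum family separately.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    nlr = table[table["hv_label"].isin(["hv", "non-hv"])]
    results = []

    perm_specs = [
        ("expression", "mean_log2_tpm", "mean"),
        ("methylation", "cg_methylation_pct", "mean"),
        ("te_distance", "te_distance_bp", "median"),
        ("mutation", "mutation_probability", "mean"),
    ]
    # gene-set style permutation tests: the hv set against the rest of the
    # gene universe (random same-size sets form the null)
    for i, (feature, col, stat) in enumerate(perm_specs[:3]):
        sub = table[[col, "hv_label"]].dropna()
        labels = np.where(sub["hv_label"] == "hv", "hv", "genome")
        res = perm_diff_test(
            sub[col].to_numpy(), labels, stat=stat,
            n_replicates=n_replicates, seed=seeds[i], tail="two-sided",
            group_order=("hv", "genome"),
        )
        results.append({
            "test": f"perm-{stat}", "feature": feature,
            "groups": "hv:genome", "statistic": res.statistic_name,
            "observed": res.observed, "p": res.p_value,
            "n_replicates": res.n_replicates, "seed": seeds[i],
            "family": "perm",
        })
    # paired-group comparisons: hv vs non-hv rank-sum battery
    for feature, col, _ in perm_specs:
        sub = nlr[[col, "hv_label"]].dropna()
        stat, p = rank_sum_test(
            sub.loc[sub["hv_label"] == "hv", col],
            sub.loc[sub["hv_label"] == "non-hv", col],
        )
        results.append({
            "test": "rank-sum", "feature": feature, "groups": "hv:non-hv",
            "statistic": "U", "observed": stat, "p": p,
            "n_replicates": 0, "seed": -1, "family": "ranksum",
        })

    tw = nlr[["hv_label", "te_within_gene"]].dropna()
    counts = [[int(((tw["hv_label"] == g) & (tw["te_within_gene"] == v)).sum())
               for v in (True, False)] for g in ("hv", "non-hv")]
    if min(sum(r) for r in counts) > 0 and min(map(sum, zip(*counts))) > 0:
        odds, p = fisher_2x2(counts)
        results.append({
            "test": "fisher", "feature": "te_within_gene",
            "groups": "hv:non-hv", "statistic": "odds_ratio",
            "observed": odds, "p": p, "n_replicates": 0, "seed": -1,
            "family": "fisher",
        })

    hv_ids = table.loc[table["hv_label"] == "hv", "gene_id"]
    pool = table[table["hv_label"] != "non-hv"]  # hv targets vs non-NLR pool
    try:
        res = matched_perm_test(
            pool, hv_ids, response="cg_methylation_pct",
            matching_covariate="n_cg_sites", n_replicates=n_replicates,
            seed=seeds[5], tail="less",
        )
        results.append({
            "test": "matched-perm", "feature": "methylation",
            "groups": "hv:genome", "statistic": res.statistic_name,
            "observed": res.observed, "p": res.p_value,
            "n_replicates": res.n_replicates, "seed": seeds[5],
            "family": "matched",
        })
    except Exception:
        pass

    out = pd.DataFrame(results)
    out["p_adjusted"] = np.nan
    for fam, idx in out.groupby("family").groups.items():
        out.loc[idx, "p_adjusted"] = bh_adjust(out.loc[idx, "p"])
    return out.drop(columns=["family"])


# ---------------------------------------------------------------------------
# synthetic end-to-end run
# ---------------------------------------------------------------------------

def run_pipeline_synthetic(
    out_dir: str | Path,
    seed: int = 0,
    n_replicates: int = 10_000,
    sim_config: SimConfig | None = None,
    n_popgen_genes: int = 3,
) -> Path:
    """Full synthetic run: generate protein alignments consistent with an
    hv / non-hv gene universe, classify them, simulate codon alignments
    for a few genes, simulate the feature table with injected hv effects,
    run the enrichment battery, and write all stage TSVs plus the run
    manifest. Deterministic under ``seed``."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_feat, s_aln, s_pg, s_enrich = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4))

    config = sim_config or SimConfig(seed=s_feat)
    if config.seed != s_feat:
        config = SimConfig(**{**config.to_dict(), "seed": s_feat})
    sim = simulate_feature_table(config)
    table = sim.table

    # protein alignments for every NLR gene, hv genes carry >= 12
    # high-entropy columns, non-hv at most 4
    rng = np.random.default_rng(s_aln)
    alignments: dict[str, Alignment] = {}
    truth_k: dict[str, int] = {}
    nlr_rows = table[table["hv_label"].isin(["hv", "non-hv"])]
    for gene_id, label in zip(nlr_rows["gene_id"], nlr_rows["hv_label"]):
        k = int(rng.integers(12, 26)) if label == "hv" else int(
            rng.integers(0, 5))
        truth_k[gene_id] = k
        alignments[gene_id] = simulate_protein_alignment(
            n_sequences=32, length=150, n_variable_columns=k,
            seed=int(rng.integers(0, 2**31)),
        )
    entropy_cols, hv_calls = stage_entropy(alignments)
    # classification feeds the analysis table: replace simulated labels by
    # the classifier's calls (identical by construction for clean inputs)
    label_map = dict(zip(hv_calls["gene_id"], hv_calls["label"]))
    table = table.copy()
    table["hv_label"] = [label_map.get(g, lab) for g, lab in
                         zip(table["gene_id"], table["hv_label"])]

    # a few coalescent codon alignments exercise the popgen stage
    pg_rng = np.random.default_rng(s_pg)
    codon_alns = {
        f"sim{g}": simulate_coalescent_codon(
            n_samples=10, theta=5.0, n_codons=200,
            seed=int(pg_rng.integers(0, 2**31)))
        for g in range(n_popgen_genes)
    }
    popgen_table = stage_popgen(codon_alns, windows=(300, 75))

    results = stage_enrichment(table, n_replicates=n_replicates,
                               seed=s_enrich)

    entropy_cols.to_csv(out / "entropy_columns.tsv", sep="\t", index=False)
    hv_calls.to_csv(out / "hv_calls.tsv", sep="\t", index=False)
    popgen_table.to_csv(out / "popgen.tsv", sep="\t", index=False)
    table.to_csv(out / "feature_table.tsv", sep="\t", index=False)
    results.to_csv(out / "enrichment_results.tsv", sep="\t", index=False)

    manifest = {
        "tool_version": __version__,
        "mode": "synthetic",
        "seed": seed,
        "stage_seeds": {"features": s_feat, "alignments": s_aln,
                        "popgen": s_pg, "enrichment": s_enrich},
        "sim_config": config.to_dict(),
        "ground_truth": sim.ground_truth,
        "n_replicates": n_replicates,
        "elapsed_s": round(time.time() - t0, 3),
        "inputs": {},
        "warnings": [],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: Mapping,
    out_dir: str | Path,
    seed: int = 0,
) -> Path:
    """Run the analysis graph on real inputs described by ``config``.

    Recognised keys: ``entropy_aln_dir`` (protein FASTAs),
    ``codon_aln_dir`` (in-frame FASTAs), ``domains_file``,
    ``meth_reports`` (list of cytosine reports, one per replicate),
    ``counts_file``, ``genes_gff``, ``te_file``, ``scores_file``,
    ``exclude_file``, ``windows`` ([size, step]), ``n_replicates``.
    Synthetic mode (``synthetic: true``) delegates to
    `run_pipeline_synthetic`. Any missing input path aborts with an error
    naming the config key.
    """
    if config.get("synthetic"):
        return run_pipeline_synthetic(
            out_dir, seed=seed,
            n_replicates=int(config.get("n_replicates", 10_000)),
        )
    from . import features as feat
    from . import io as nio

    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums = {}

    def need(key: str) -> Path:
        if key not in config:
            raise PipelineError(f"[config] missing required key {key!r}")
        p = Path(config[key])
        if not p.exists():
            raise PipelineError(f"[config] {key}: no such path {p}")
        if p.is_file():
            checksums[key] = file_checksum(p)
        return p

    alignments = nio.read_alignment_dir(need("entropy_aln_dir"))
    entropy_cols, hv_calls = stage_entropy(alignments)
    entropy_cols.to_csv(out / "entropy_columns.tsv", sep="\t", index=False)
    hv_calls.to_csv(out / "hv_calls.tsv", sep="\t", index=False)

    popgen_table = None
    if "codon_aln_dir" in config:
        codon_alns = nio.read_alignment_dir(Path(config["codon_aln_dir"]),
                                            codon=True)
        annotations = None
        if "domains_file" in config:
            anns = nio.read_domain_annotations(need("domains_file"))
            annotations = {}
            for gid, aln in codon_alns.items():
                ids = set(aln.sequence_ids)
                annotations[gid] = [a for a in anns if a.sequence_id in ids]
        windows = tuple(config["windows"]) if "windows" in config else None
        popgen_table = stage_popgen(codon_alns, annotations, windows)
        popgen_table.to_csv(out / "popgen.tsv", sep="\t", index=False)

    pieces: dict = {"hv_calls": hv_calls.rename(
        columns={"label": "hv_label"})[["gene_id", "hv_label"]]}
    if "counts_file" in config and "genes_gff" in config:
        counts = nio.read_counts(need("counts_file"))
        genes, exon_len = nio.read_gff3_genes(need("genes_gff"))
        tpm_table = feat.tpm(counts, exon_len)
        expr = feat.mean_log2_tpm(tpm_table).rename("mean_log2_tpm")
        pieces["expression"] = expr.rename_axis("gene_id").reset_index()
        if "meth_reports" in config:
            reps = [feat.filter_and_pair_cg(nio.read_cytosine_report(p))
                    for p in config["meth_reports"]]
            pieces["methylation"] = feat.gene_body_methylation(reps, genes)
        if "te_file" in config:
            tes = nio.read_te_table(need("te_file"))
            pieces["te"] = feat.te_distance(genes, tes)
    if "scores_file" in config:
        scores = nio.read_scores(need("scores_file"))
        pieces["mutation_scores"] = (
            scores.rename("mutation_probability")
            .rename_axis("gene_id").reset_index())
    exclusions = {}
    if "exclude_file" in config:
        exclusions["unmappable"] = nio.read_gene_list(need("exclude_file"))

    table = feat.assemble_feature_table(exclusions=exclusions, **pieces)
    table.to_csv(out / "feature_table.tsv", sep="\t", index=False)

    results = stage_enrichment(
        table, n_replicates=int(config.get("n_replicates", 10_000)),
        seed=seed)
    results.to_csv(out / "enrichment_results.tsv", sep="\t", index=False)

    manifest = {
        "tool_version": __version__,
        "mode": "real",
        "seed": seed,
        "config": {k: str(v) for k, v in config.items()},
        "input_checksums": checksums,
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
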