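"""End-to-end orchestration: simulate -> pairs -> Ks -> families -> mixture
-> GO -> expression -> report.

Every stage writes plain TSV/JSON into the run directory, so a stage can be
re-run from the previous stage's files or replaced by an external tool's
output (user-supplied Ks tables are accepted by the mixture stage
directly).  The resolved configuration and its hash are embedded in every
output for provenance, and a fixed master seed makes reruns byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as expr
from . import families as fam
from . import io as pio
from . import ks as ks_mod
from . import mixture as mix
from . import ontology as onto
from .pairs import (align_all_vs_all, apply_length_filter, call_paralogs,
                    dedupe_zero_ks, load_hits)
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("paralogy")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "summarize"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Threshold defaults are the reference study's rules; the resolved config
    is serialized into the run report and hashed into every output header.
    """

    outdir: str = "paralogy_run"
    seed: int = 0
    # inputs: either simulate or provide files
    simulate: bool = True
    n_families: int = 120
    cds_fasta: str | None = None
    hits_tsv: str | None = None
    counts_tsv: str | None = None
    tissue_map_tsv: str | None = None
    obo: str | None = None
    annotations: str | None = None
    # filters (reference defaults)
    min_cds_nt: int = 300
    min_aln_aa: int = 100
    min_pct_id: float = 30.0
    ks_pct_id: float = 60.0
    ks_max: float = 2.0
    young_cutoff: float = 0.4
    family_annot_frac: float = 0.30
    enrich_alpha: float = 0.01
    coexpr_alpha: float = 0.05
    min_ests: int = 3
    n_null_pairs: int = 10_000
    n_restarts: int = 5
    max_normals: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunReport:
    """Per-stage record counts and headline results of one run."""

    config: dict
    config_hash: str
    counts: dict = field(default_factory=dict)
    mixture: dict = field(default_factory=dict)
    powerlaw: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config, "config_hash": self.config_hash,
            "counts": self.counts, "mixture": self.mixture,
            "powerlaw": self.powerlaw, "expression": self.expression,
            "enrichment": self.enrichment,
        }


def _pair_seed(config: RunConfig, a: str, b: str) -> int:
    return (config.stage_seed("ks") ^ zlib.crc32(f"{a}|{b}".encode())) % (2**31)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis per a RunConfig; returns the RunReport.

    Raises a configuration error before any compute when a requested stage
    lacks its input.
    """
    if not config.simulate and not config.cds_fasta:
        raise ValueError("either enable simulation or provide cds_fasta")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"config {config.config_hash} seed {config.seed}"
    report = RunReport(config=config.to_dict(), config_hash=config.config_hash)

    # ---- inputs -----------------------------------------------------------
    truth = None
    if config.simulate:
        sim_cfg = SimulationConfig(seed=config.stage_seed("simulate"),
                                   n_families=config.n_families)
        dataset = simulate_dataset(sim_cfg)
        genes = dataset.genes
        counts = dataset.counts
        tissue_map = dataset.tissue_map
        truth = dataset
        pio.write_gene_fastas(genes, outdir / "cds.fasta",
                              outdir / "protein.fasta")
        pio.write_counts(outdir / "est_counts.tsv", counts, tag)
        logger.info("simulate: %d genes (%d families planned)",
                    len(genes), sim_cfg.n_families)
    else:
        counts = (pio.read_counts(config.counts_tsv)
                  if config.counts_tsv else None)
        genes = pio.read_cds_fasta(config.cds_fasta, counts)
        tissue_map = (pio.read_tissue_map(config.tissue_map_tsv)
                      if config.tissue_map_tsv else None)

    genes = apply_length_filter(genes, config.min_cds_nt)
    by_id = {g.id: g for g in genes}
    report.counts["genes_in"] = len(genes)

    # ---- pairs ------------------------------------------------------------
    hits = (load_hits(config.hits_tsv) if config.hits_tsv
            else align_all_vs_all(genes))
    pairs, singlets = call_paralogs(
        hits, all_gene_ids=by_id, min_aln_aa=config.min_aln_aa,
        min_pct_id=config.min_pct_id, ks_pct_id=config.ks_pct_id,
    )
    report.counts["pairs_called"] = len(pairs)
    report.counts["singlets"] = len(singlets)
    logger.info("pairs: %d called, %d singlets", len(pairs), len(singlets))
    pio.write_tsv(outdir / "pairs.tsv", pd.DataFrame(
        [{"gene_a": p.gene_a, "gene_b": p.gene_b,
          "aligned_length": p.aligned_length,
          "pct_id": p.percent_identity, "ks_eligible": p.ks_eligible}
         for p in pairs]), tag)

    # ---- Ks ---------------------------------------------------------------
    estimates: dict = {}
    for p in pairs:
        if not p.ks_eligible:
            continue
        ga, gb = by_id[p.gene_a], by_id[p.gene_b]
        columns = ks_mod.codon_align(ga.cds, gb.cds, ga.protein, gb.protein)
        if len(columns) < 10:
            continue
        estimates[p.key] = ks_mod.fit_pair_ml(
            columns, n_restarts=config.n_restarts,
            seed=_pair_seed(config, *p.key),
        )
    retained, zero_pairs = ks_mod.filter_ks(estimates, ks_max=config.ks_max)
    dropped_genes = dedupe_zero_ks(zero_pairs)
    ks_values = {
        pair: est.ks for pair, est in retained.items()
        if est.ks > 0 and not (set(pair) & dropped_genes)
    }
    pairs = [p for p in pairs if not (set(p.key) & dropped_genes)]
    report.counts["ks_eligible"] = len(estimates)
    report.counts["ks_retained"] = len(ks_values)
    report.counts["zero_ks_genes_removed"] = len(dropped_genes)
    logger.info("ks: %d fits, %d retained, %d redundant genes removed",
                len(estimates), len(ks_values), len(dropped_genes))
    pio.write_tsv(outdir / "ks.tsv", pd.DataFrame(
        [{"gene_a": a, "gene_b": b, "t": e.t, "kappa": e.kappa,
          "omega": e.omega, "ks": e.ks, "ka": e.ka, "loglik": e.loglik,
          "n_codons_used": e.n_codons_used,
          "flags": ",".join(e.flags)}
         for (a, b), e in sorted(estimates.items())]), tag)

    # ---- families ---------------------------------------------------------
    families = fam.cluster_families(pairs)
    node_rows, ages = [], []
    for family in families:
        nodes = fam.date_duplications(family, ks_values)
        family.nodes = nodes
        for node in nodes:
            ages.append(node.age_ks)
            node_rows.append({"family_id": family.family_id,
                              "age_ks": node.age_ks})
    young_families = fam.young_subset(ks_values, config.young_cutoff)
    amp_rows = []
    for family in families:
        d_young = fam.count_young_nodes(family.nodes, config.young_cutoff)
        if d_young < family.size:
            rec = fam.amplification_ratio(family.size, d_young,
                                          family.family_id)
            amp_rows.append({"family_id": rec.family_id,
                             "n_total": rec.n_total, "d_young": rec.d_young,
                             "n_ancestral": rec.n_ancestral,
                             "ratio": rec.ratio})
    report.counts["families"] = len(families)
    report.counts["genes_in_families"] = sum(f.size for f in families)
    report.counts["duplication_nodes"] = len(ages)
    report.counts["young_families"] = len(young_families)
    report.counts["young_duplications"] = sum(
        r["d_young"] for r in amp_rows)
    logger.info("families: %d (%d genes), %d nodes", len(families),
                report.counts["genes_in_families"], len(ages))
    sizes = [f.size for f in families]
    try:
        pl = fam.fit_powerlaw(sizes)
        report.powerlaw = {"a": pl.a, "b": pl.b, "r_squared": pl.r_squared}
    except ValueError:
        report.powerlaw = {}
    pio.write_tsv(outdir / "families.tsv", pd.DataFrame(
        [{"family_id": f.family_id, "n": f.size,
          "members": ",".join(sorted(f.members))} for f in families]), tag)
    pio.write_tsv(outdir / "nodes.tsv", pd.DataFrame(node_rows), tag)
    pio.write_tsv(outdir / "amplification.tsv", pd.DataFrame(amp_rows), tag)

    # ---- mixture ----------------------------------------------------------
    ages_in = [a for a in ages if 0 < a <= config.ks_max]
    if len(ages_in) >= 50:
        best, table = mix.select_model(
            ages_in, max_normals=config.max_normals,
            seed=config.stage_seed("mixture"), upper=config.ks_max,
        )
        report.mixture = {
            "n_normals": best.n_normals, "death_rate": best.death_rate,
            "w_exp": best.w_exp,
            "components": [
                {"mean": c.mean, "variance": c.variance, "weight": c.weight}
                for c in best.components
            ],
            "ks_stat": best.ks_stat, "ks_pvalue": best.ks_pvalue,
            "selection": table,
        }
        grid = np.linspace(0.01, config.ks_max, 200)
        pio.write_tsv(outdir / "mixture_density.tsv", pd.DataFrame(
            {"ks": grid, "density": best.pdf(grid)}), tag)
        logger.info("mixture: %d normals, death rate %.3f",
                    best.n_normals, best.death_rate)
    else:
        report.mixture = {"skipped": f"only {len(ages_in)} node ages"}

    # ---- GO enrichment ----------------------------------------------------
    if config.obo and config.annotations:
        graph = onto.load_ontology(config.obo)
        annotations = onto.load_annotations(config.annotations, graph)
        family_terms = {
            f.family_id: onto.annotate_family(f.members, annotations,
                                              config.family_annot_frac)
            for f in families
        }
        singlet_terms = {g: annotations.terms_of(g) for g in singlets}
        _, frame = onto.fisher_enrichment(family_terms, singlet_terms,
                                          alpha=config.enrich_alpha)
        pio.write_tsv(outdir / "enrichment.tsv", frame, tag)
        report.enrichment = {
            "terms_tested": int(len(frame)),
            "significant": int(frame["significant"].sum()) if len(frame) else 0,
            "annotated_families": sum(1 for t in family_terms.values() if t),
            "annotated_singlets": sum(1 for t in singlet_terms.values() if t),
        }

    # ---- expression -------------------------------------------------------
    if counts is not None:
        kept = expr.filter_min_ests(counts, config.min_ests)
        freqs = expr.expression_frequencies(counts).loc[kept.index]
        pair_keys = [p.key for p in pairs
                     if p.key[0] in freqs.index and p.key[1] in freqs.index]
        pair_r = {k: expr.pearson_divergence(k, freqs) for k in pair_keys}
        r_star = expr.null_threshold(
            freqs, exclude_pairs=pair_keys,
            n_random_pairs=config.n_null_pairs,
            alpha=config.coexpr_alpha, seed=config.stage_seed("expression"),
        )
        fractions = expr.divergent_fractions(pair_r, ks_values, r_star,
                                             config.young_cutoff)
        shifted = 0
        tested = 0
        if tissue_map:
            for key in pair_keys:
                res = expr.tissue_specificity(key, counts, tissue_map,
                                              alpha=config.coexpr_alpha)
                if res is None:
                    continue
                tested += 1
                if any(t.significant for t in res):
                    shifted += 1
        report.expression = {
            "r_star": r_star, "fractions": fractions,
            "pairs_profiled": len(pair_r),
            "tissue_tested": tested, "tissue_shifted": shifted,
        }
        pio.write_tsv(outdir / "divergence.tsv", pd.DataFrame(
            [{"gene_a": a, "gene_b": b, "r": r,
              "coregulated": (not np.isnan(r)) and r >= r_star}
             for (a, b), r in sorted(pair_r.items())]), tag)
        logger.info("expression: r*=%.3f, %d pairs", r_star, len(pair_r))

    # ---- report -----------------------------------------------------------
    if truth is not None:
        report.counts["true_families"] = len(set(
            truth.true_family_ids.values()))
        report.counts["true_pairs"] = len(truth.true_pair_ks)
    pio.write_json(outdir / "report.json", report.to_dict())
    return report


def summarize(report: RunReport) -> tuple[str, dict]:
    """Human-readable statistics block plus its machine form.

    Mirrors the classic unigene-analysis table: total genes, genes in
    families, mean family size, singlets — then mixture parameters,
    amplification and divergence headlines.
    """
    c = report.counts
    lines = []
    machine: dict = {}
    if not c.get("genes_in"):
        return "no data\n", {"status": "no data"}
    genes_in_families = c.get("genes_in_families", 0)
    n_fam = c.get("families", 0)
    mean_size = genes_in_families / n_fam if n_fam else float("nan")
    singlets = c.get("singlets", 0)
    total = c.get("genes_in", 0)
    pct_fam = 100 * genes_in_families / total
    pct_single = 100 * singlets / total
    lines.append(f"Protein-coding genes: {total}")
    lines.append(f"Genes in families: {genes_in_families} (~{pct_fam:.1f}%)")
    lines.append(f"Gene families: {n_fam}")
    lines.append(f"Mean number of genes per family: {mean_size:.1f}")
    lines.append(f"Single-copy genes (singlets): {singlets} "
                 f"(~{pct_single:.1f}%)")
    machine.update({
        "genes": total, "genes_in_families": genes_in_families,
        "families": n_fam, "mean_family_size": round(mean_size, 1),
        "singlets": singlets,
        "pct_in_families": round(pct_fam, 1),
        "pct_singlets": round(pct_single, 1),
    })
    if report.enrichment:
        ann = report.enrichment
        if singlets:
            rate = round(100 * ann.get("annotated_singlets", 0) / singlets)
            lines.append(f"GO-annotated singlets: {rate}%")
            machine["singlet_annotation_pct"] = rate
    if report.mixture and "death_rate" in report.mixture:
        m = report.mixture
        comp = ", ".join(
            f"N(mean {x['mean']:.3f}, var {x['variance']:.3f}, w {x['weight']:.2f})"
            for x in m["components"])
        lines.append(f"Age mixture: {m['n_normals']} normals; death rate "
                     f"{m['death_rate']:.3f}; {comp}")
        machine["mixture"] = m
    if report.powerlaw:
        p = report.powerlaw
        lines.append(f"Family-size power law: f(x) = {p['a']:.0f} x^-{p['b']:.2f} "
                     f"(R^2 = {p['r_squared']:.2f})")
        machine["powerlaw"] = p
    if report.expression:
        e = report.expression
        f = e["fractions"]
        lines.append(
            f"Expression divergence: r* = {e['r_star']:.2f}; divergent "
            f"{_pct(f['overall'])} overall, {_pct(f['young'])} young, "
            f"{_pct(f['old'])} old")
        machine["expression"] = e
    return "\n".join(lines) + "\n", machine


def _pct(x) -> str:
    return "n/a" if x is None or (isinstance(x, float) and np.isnan(x)) \
        else f"{round(100 * x)}%"
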