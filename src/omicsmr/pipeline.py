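"""End-to-end orchestration of the causal-protein discovery workflow.

The synthetic default run mirrors the full study flow: three independent
pQTL "databases" are scanned protein by protein with two-sample MR
against one disease outcome; proteins significant in every database with
a consistent effect direction form the candidate set; the candidate is
validated with SMR/HEIDI on an eQTL region and screened for side effects
with MR-PheWAS; a case/control expression study yields DEGs and a
trait-associated co-expression module whose intersection defines the key
genes; a correlation screen and PPI hub scoring nominate the downstream
partner.  Every stage is a pure function of (inputs, config, seed), so a
repeated run reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpr, hubnet, synthdata
from .instruments import InstrumentConfig, select_instruments
from .mr import MRAnalysis, MRConfig, run_mr
from .phewas import run_phewas
from .smr import HeidiConfig, SMRResult, run_smr


@dataclass
class PipelineConfig:
    seed: int = 1
    # proteome-wide MR scan
    n_databases: int = 3
    n_proteins: int = 30
    planted_protein: str = "P001"
    planted_theta: float = 0.5
    n_snps_per_protein: int = 18
    ld_block_size: int = 3
    ld_rho: float = 0.8
    exposure_n: tuple = (35_000, 35_000, 10_000)
    outcome_n_effective: float = 2661.0
    mr_alpha: float = 0.05
    require_consistent_direction: bool = True
    # instrument selection
    iv_p_threshold: float = 5e-8
    cis_window: int = 1_000_000
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    # harmonization / estimators
    palindromic_af_tolerance: float = 0.08
    ivw_random_effects: bool = True
    n_boot: int = 1000
    # SMR / HEIDI
    smr_alpha: float = 0.05
    heidi_alpha: float = 0.05
    smr_region_snps: int = 30
    # PheWAS
    phewas_enabled: bool = True
    phewas_n_outcomes: int = 50
    phewas_threshold: float = 5e-5
    # expression stage
    expr_n_genes: int = 300
    expr_samples_per_group: tuple = (7, 6)
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    # candidate powers capped at 12: with ~13 samples, higher powers
    # amplify correlation noise faster than structure (small-sample
    # guidance for unsigned networks)
    wgcna_powers: tuple = tuple(range(1, 13))
    wgcna_r2_target: float = 0.80
    wgcna_min_module_size: int = 10
    wgcna_cut_height: float = 0.25
    screen_alpha: float = 0.05
    # hub scoring
    hub_top_k: int = 30
    hub_degree_boost: int = 30
    n_hubs: int = 5

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    def as_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in data.items():
            if isinstance(v, list):
                data[k] = tuple(v)
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _subseed(seed: int, *tags) -> int:
    """Deterministic stream seed below 2**31 derived from (seed, tags)."""
    coded = [seed] + [
        int.from_bytes(hashlib.sha256(str(t).encode()).digest()[:4], "big") for t in tags
    ]
    return int(np.random.SeedSequence(coded).generate_state(1)[0] % (2**31))


def intersect_causal_proteins(
    mr_tables: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    require_consistent_direction: bool = True,
) -> list[str]:
    """Proteins significant in every database, optionally with one sign.

    Each table needs columns ``protein``, ``beta``, ``pval`` (the primary
    method's row per protein).
    """
    if len(mr_tables) < 2:
        raise ValueError("need MR tables from at least 2 databases")
    sig_sets = []
    for table in mr_tables.values():
        sig_sets.append(set(table.loc[table["pval"] < alpha, "protein"]))
    inter = set.intersection(*sig_sets)
    if require_consistent_direction:
        consistent = set()
        for protein in inter:
            signs = {
                np.sign(t.loc[t["protein"] == protein, "beta"].iloc[0])
                for t in mr_tables.values()
            }
            if len(signs) == 1 and 0 not in signs:
                consistent.add(protein)
        inter = consistent
    return sorted(inter)


@dataclass
class RunReport:
    config_hash: str
    mr_results: pd.DataFrame
    primary_tables: dict
    candidate_proteins: list
    smr: SMRResult | None
    phewas: pd.DataFrame | None
    deg_table: pd.DataFrame
    wgcna: coexpr.WGCNAResult
    trait_module: str
    key_genes: list
    screen: pd.DataFrame
    screen_hits: list
    hub_table: pd.DataFrame
    hub_genes: list
    truth_metrics: dict = field(default_factory=dict)


def _protein_scan(config: PipelineConfig):
    """MR of every protein in every database against the outcome."""
    iv_config = InstrumentConfig(
        p_threshold=config.iv_p_threshold,
        cis_window=config.cis_window,
        r2_threshold=config.clump_r2,
        clump_window_kb=config.clump_window_kb,
        f_min=config.f_min,
    )
    mr_config = MRConfig(
        palindromic_af_tolerance=config.palindromic_af_tolerance,
        random_effects=config.ivw_random_effects,
        n_boot=config.n_boot,
    )
    n_snps = config.n_snps_per_protein
    blocks = [config.ld_block_size] * (n_snps // config.ld_block_size)
    if sum(blocks) < n_snps:
        blocks.append(n_snps - sum(blocks))
    rows, primary_tables, analyses = [], {}, {}
    planted_exposure = planted_ld = None
    for d in range(config.n_databases):
        db = f"DB{d + 1}"
        primary_rows = []
        for p in range(config.n_proteins):
            protein = f"P{p + 1:03d}"
            theta = config.planted_theta if protein == config.planted_protein else 0.0
            ld = synthdata.simulate_ld_matrix(n_snps, blocks, config.ld_rho)
            exposure, outcome, _ = synthdata.simulate_two_sample_study(
                n_snps,
                ld,
                theta=theta,
                n_exposure=config.exposure_n[d % len(config.exposure_n)],
                n_outcome=config.outcome_n_effective,
                seed=_subseed(config.seed, "scan", db, protein),
            )
            if db == "DB1" and protein == config.planted_protein:
                planted_exposure, planted_ld = exposure, ld
            tss = int(np.median(ld.positions))
            ivs = select_instruments(exposure, ld, gene_chr="1", gene_tss=tss, config=iv_config)
            if len(ivs) == 0:
                analysis = MRAnalysis(pd.DataFrame(), None, None, "no instruments")
            else:
                out_sub = outcome[outcome["snp"].isin(ivs.snps)]
                analysis = run_mr(ivs.records, out_sub, mr_config)
            analyses[(db, protein)] = analysis
            if analysis.primary is None:
                continue
            for _, row in analysis.results.iterrows():
                rows.append({"database": db, "protein": protein, **row.to_dict()})
            pr = analysis.primary
            primary_rows.append(
                {"protein": protein, "method": pr["method"], "beta": pr["beta"],
                 "se": pr["se"], "pval": pr["pval"], "or": pr["or"], "n_snp": pr["n_snp"]}
            )
        primary_tables[db] = pd.DataFrame(primary_rows)
    return pd.DataFrame(rows), primary_tables, analyses, planted_exposure, planted_ld


def run_all(config: PipelineConfig | None = None, outdir: str | Path | None = None) -> RunReport:
    """Execute the full synthetic workflow and assemble the report."""
    config = config or PipelineConfig()

    # --- stage 1: proteome-wide MR scan across databases + intersection
    mr_results, primary_tables, _, planted_exposure, planted_ld = _protein_scan(config)
    candidates = intersect_causal_proteins(
        primary_tables, config.mr_alpha, config.require_consistent_direction
    )

    # --- stage 2: SMR/HEIDI validation on the candidate's cis region
    eqtl, gwas, region_ld, _ = synthdata.simulate_smr_region(
        "pleiotropy",
        n_snps=config.smr_region_snps,
        seed=_subseed(config.seed, "smr"),
    )
    smr_result = run_smr(
        eqtl, gwas, region_ld, config.smr_alpha, config.heidi_alpha, HeidiConfig()
    )

    # --- stage 3: MR-PheWAS for side effects
    phewas_table = None
    if config.phewas_enabled:
        catalog = synthdata.simulate_outcome_catalog(
            planted_exposure,
            planted_ld,
            config.phewas_n_outcomes,
            n_outcome=config.outcome_n_effective,
            seed=_subseed(config.seed, "phewas"),
        )
        phewas_table = run_phewas(
            planted_exposure, catalog, config.phewas_threshold,
            MRConfig(palindromic_af_tolerance=config.palindromic_af_tolerance,
                     random_effects=config.ivw_random_effects),
        )

    # --- stage 4: expression study -> DEGs + WGCNA -> key genes
    matrix, samples, expr_truth = synthdata.simulate_expression_study(
        n_genes=config.expr_n_genes,
        n_samples_per_group=tuple(config.expr_samples_per_group),
        seed=_subseed(config.seed, "expression"),
    )
    adjusted = coexpr.adjust_batch(matrix, samples)
    deg = coexpr.differential_expression(
        adjusted, samples, config.lfc_threshold, config.fdr_threshold
    )
    wg = coexpr.run_wgcna(
        adjusted,
        samples,
        candidate_powers=tuple(config.wgcna_powers),
        r2_target=config.wgcna_r2_target,
        min_module_size=config.wgcna_min_module_size,
        cut_height=config.wgcna_cut_height,
    )
    trait_module = wg.module_trait["cor"].abs().idxmax()
    module_genes = set(wg.module_labels.index[wg.module_labels == trait_module])
    deg_genes = set(deg.index[deg["status"] != "ns"])
    key = coexpr.intersect_gene_sets(trait_module=module_genes, degs=deg_genes)
    key_genes = key.intersection

    # --- stage 5: correlation screen against a planted partner panel
    rng = np.random.default_rng(_subseed(config.seed, "lipid-panel"))
    trait_truth_genes = [
        g for g, m in expr_truth.module_assignment.items()
        if m in expr_truth.trait_assoc_modules
    ]
    target_gene = trait_truth_genes[0]  # the candidate protein's encoded gene
    partner_gene = trait_truth_genes[1]  # co-module gene: the planted partner
    # decoys come from outside the trait module: an unrelated pathway panel
    # in which only the planted partner is genuinely co-expressed
    decoy_pool = [
        g for g in adjusted.index
        if expr_truth.module_assignment.get(g) not in expr_truth.trait_assoc_modules
    ]
    panel = sorted(
        {partner_gene, *(str(g) for g in rng.choice(decoy_pool, size=26, replace=False))}
    )
    screen = coexpr.spearman_screen(adjusted, target_gene, panel, config.screen_alpha)
    screen_hits = sorted(
        screen.index[(screen["significant"]) & (screen["direction"] == "positive")]
    )

    # --- stage 6: PPI hub scoring over the key genes
    hub_nodes = key_genes if len(key_genes) >= 10 else sorted(module_genes | deg_genes)
    module_truth = {g: expr_truth.module_assignment.get(g, "none") for g in hub_nodes}
    edges, ppi_truth = synthdata.simulate_ppi_graph(
        module_truth,
        hub_degree_boost=config.hub_degree_boost,
        n_hubs=config.n_hubs,
        seed=_subseed(config.seed, "ppi"),
    )
    scores = hubnet.hub_scores(edges)
    k = min(config.hub_top_k, len(scores))
    hub_genes, _ = hubnet.hub_intersection(scores, k)

    # --- truth-comparison metrics
    planted_key = sorted(
        set(trait_truth_genes) & set(expr_truth.de_gene_ids)
    )
    observed_key = set(key_genes)
    union = observed_key | set(planted_key)
    truth_metrics = {
        "planted_protein_recovered": config.planted_protein in candidates,
        "n_candidate_proteins": len(candidates),
        "key_gene_jaccard": (
            len(observed_key & set(planted_key)) / len(union) if union else 1.0
        ),
        "planted_hubs_recovered": set(ppi_truth.hub_node_ids) <= set(hub_genes),
        "phewas_false_flags": (
            int(phewas_table["significant"].sum()) if phewas_table is not None else None
        ),
    }

    report = RunReport(
        config_hash=config.hash(),
        mr_results=mr_results,
        primary_tables=primary_tables,
        candidate_proteins=candidates,
        smr=smr_result,
        phewas=phewas_table,
        deg_table=deg,
        wgcna=wg,
        trait_module=trait_module,
        key_genes=key_genes,
        screen=screen,
        screen_hits=screen_hits,
        hub_table=scores,
        hub_genes=hub_genes,
        truth_metrics=truth_metrics,
    )
    if outdir is not None:
        write_report(report, config, outdir)
    return report


def write_report(report: RunReport, config: PipelineConfig, outdir: str | Path) -> None:
    """Persist every report table as TSV plus a structured summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report.mr_results.to_csv(out / "mr_results.tsv", sep="\t", index=False, na_rep="NA")
    for db, table in report.primary_tables.items():
        table.to_csv(out / f"mr_primary_{db}.tsv", sep="\t", index=False, na_rep="NA")
    if report.phewas is not None:
        report.phewas.to_csv(out / "phewas.tsv", sep="\t", index=False, na_rep="NA")
    report.deg_table.to_csv(out / "deg.tsv", sep="\t", index_label="gene", na_rep="NA")
    report.wgcna.module_labels.to_frame().to_csv(
        out / "modules.tsv", sep="\t", index_label="gene", na_rep="NA"
    )
    report.wgcna.module_trait.to_csv(out / "module_trait.tsv", sep="\t", na_rep="NA")
    report.screen.to_csv(out / "screen.tsv", sep="\t", na_rep="NA")
    report.hub_table.to_csv(out / "hub_scores.tsv", sep="\t", index_label="node", na_rep="NA")
    summary = {
        "config_hash": report.config_hash,
        "candidate_proteins": [str(p) for p in report.candidate_proteins],
        "smr": None
        if report.smr is None
        else {
            "b_smr": float(report.smr.b_smr),
            "p_smr": float(report.smr.p_smr),
            "p_heidi": None if report.smr.p_heidi is None else float(report.smr.p_heidi),
            "verdict": report.smr.verdict,
        },
        "trait_module": str(report.trait_module),
        "n_key_genes": len(report.key_genes),
        "key_genes": [str(g) for g in report.key_genes],
        "screen_hits": [str(g) for g in report.screen_hits],
        "hub_genes": [str(g) for g in report.hub_genes],
        "truth_metrics": {
            k: (bool(v) if isinstance(v, (bool, np.bool_)) else
                float(v) if isinstance(v, (float, np.floating)) else
                int(v) if isinstance(v, (int, np.integer)) else v)
            for k, v in report.truth_metrics.items()
        },
    }
    (out / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
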