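"""Synthetic EPIC-array-like data with planted ground truth.

Emulates the statistical structure of an ARID1A-centred OCCC methylation
study: a bimodal genome-wide beta distribution, four sample sets (primary
tumors, a cell-line panel and two isogenic knockout pairs run in duplicate),
group-specific differentially methylated (DM) CpGs, expression sign-coupled
to promoter/gene-body methylation with a batch effect, one planted
EZH2-target-like gene set among uniform decoys, and a DepMap-style
dependency table in which engineered candidate genes are selectively
essential in ARID1A-deficient lines.

Every non-null effect placed in any simulated file is recorded in the
:class:`SimTruth` ledger, so downstream parameter-recovery tests can score
sensitivity and direction accuracy exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffmeth import SampleSetDefinition
from .gsea import GeneSetCollection
from .preprocess import MethylationMatrix, beta_to_m
from .select import DependencyTable

__all__ = ["SimConfig", "SimTruth", "simulate_beta_matrix", "simulate_expression",
           "simulate_genesets", "simulate_dependency"]

#: region-class vocabulary shared with annotation and counting
PROMOTER = "promoter"
ALT_PROMOTER = "alt_promoter"
GENE_BODY = "gene_body"
OTHER = "other"

#: beta clipped into this open interval so M-values stay finite at offset 0
BETA_EPS = 1e-6

_REQUIRED_GROUPS = ("tumor_mt", "tumor_wt", "cell_mt", "cell_wt", "ko_pairs")


def _default_groups() -> dict[str, int]:
    # study cohort shape: 11 mt / 24 wt tumors, 10 mt / 3 wt cell lines,
    # two isogenic knockout pairs run in duplicate
    return {"tumor_mt": 11, "tumor_wt": 24, "cell_mt": 10, "cell_wt": 3, "ko_pairs": 2}


@dataclass
class SimConfig:
    """All knobs of the simulation; a single seed drives every stream.

    delta_beta is the planted DM effect on the beta scale; frac_dm fixes both
    the DM probe count (frac_dm * n_probes) and the DM gene count
    (frac_dm * n_genes).  coupling_strength is the expression change in log2
    units per unit of mean promoter/gene-body M; only planted genes and a
    coupled_fraction share of the other DM genes are expression-coupled at
    all (methylation change does not universally translate into expression
    change).  dm_region_split divides DM genes over promoter / gene-body /
    alternative-promoter CGIs.  n_candidates planted-set genes are
    additionally DM in the tumor group (the engineered end-to-end
    candidates); the remaining planted genes are DM only in the cell-derived
    groups.
    """

    n_probes: int = 10_000
    n_genes: int = 2_000
    samples_per_group: Mapping[str, int] = field(default_factory=_default_groups)
    frac_dm: float = 0.05
    delta_beta: float = 0.3
    frac_promoter: float = 0.3
    frac_genebody: float = 0.3
    frac_altpromoter: float = 0.1
    coupling_strength: float = 0.5
    coupled_fraction: float = 0.5
    noise_sd_beta: float = 0.01
    noise_sd_expr: float = 0.5
    planted_set_name: str = "PLANTED_EZH2_TARGETS_UP"
    planted_set_size: int = 30
    n_candidates: int = 5
    candidate_signal_boost: float = 1.5
    dm_region_split: tuple[float, float, float] = (0.7, 0.2, 0.1)
    n_batches: int = 2
    batch_shift: float = 3.0
    expr_baseline_mean: float = 7.0
    expr_baseline_sd: float = 1.0
    dep_essential_shift: float = -0.5
    dep_noise_sd: float = 0.1
    mix_weight_low: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dm", "frac_promoter", "frac_genebody", "frac_altpromoter",
                     "mix_weight_low", "coupled_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.delta_beta <= 1.0:
            raise ValueError("delta_beta must lie in [0, 1]")
        if self.frac_promoter + self.frac_genebody + self.frac_altpromoter > 1.0 + 1e-12:
            raise ValueError("region fractions must sum to <= 1")
        for name in ("n_probes", "n_genes", "planted_set_size", "n_batches"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_candidates < 0 or self.n_candidates > self.planted_set_size:
            raise ValueError("n_candidates must lie in [0, planted_set_size]")
        for g in _REQUIRED_GROUPS:
            if self.samples_per_group.get(g, 0) <= 0:
                raise ValueError(f"group {g!r} must have at least one sample")
        if self.frac_dm * self.n_probes < self.planted_set_size:
            raise ValueError("frac_dm * n_probes must be >= planted_set_size")
        if self.n_probes < self.n_genes:
            raise ValueError("need at least one probe per gene")
        if abs(sum(self.dm_region_split) - 1.0) > 1e-9:
            raise ValueError("dm_region_split must sum to 1")

    # ---- derived bookkeeping ------------------------------------------------
    @property
    def n_dm_probes(self) -> int:
        return round(self.frac_dm * self.n_probes)

    @property
    def n_dm_genes(self) -> int:
        return max(1, round(self.frac_dm * self.n_genes)) if self.n_dm_probes else 0

    def sample_layout(self) -> dict[str, list[str]]:
        """Sample ids per simulation arm, in fixed order."""
        n = self.samples_per_group
        layout = {
            "tumor_mt": [f"tumor_mt_{i + 1:02d}" for i in range(n["tumor_mt"])],
            "tumor_wt": [f"tumor_wt_{i + 1:02d}" for i in range(n["tumor_wt"])],
            "cell_mt": [f"cell_mt_{i + 1:02d}" for i in range(n["cell_mt"])],
            "cell_wt": [f"cell_wt_{i + 1:02d}" for i in range(n["cell_wt"])],
        }
        k = n["ko_pairs"]
        for line in ("es2", "ovca429"):
            layout[f"{line}_parent"] = [f"{line}_parent_{i + 1}" for i in range(k)]
            layout[f"{line}_ko"] = [f"{line}_ko_{i + 1}" for i in range(k)]
        return layout


@dataclass
class SimTruth:
    """Exhaustive ground-truth ledger for one simulation."""

    probe_annotation: pd.DataFrame  # probe_id(index), chrom, pos, region_class, gene
    dm_probes: pd.DataFrame  # probe_id(index), gene, region_class, direction, true_delta_beta, tumor_dm
    dm_genes: pd.DataFrame  # gene(index), region_class, direction, coupled, tumor_dm, planted, candidate
    gene_coupling: pd.Series  # every gene -> expression-coupled flag
    dm_gene_ids: list[str]
    planted_genes: list[str]
    planted_set_name: str
    candidate_genes: list[str]
    sample_groups: pd.Series  # sample_id -> group label
    sample_sets: list[SampleSetDefinition]
    batch_assignment: pd.Series | None = None  # filled by simulate_expression
    expr_shift: pd.Series | None = None  # noise-free per-gene mt-wt shift, ditto

    @property
    def dm_probe_ids(self) -> list[str]:
        return list(self.dm_probes.index)

    def dm_directions(self) -> pd.Series:
        return self.dm_probes["direction"]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, order-insensitive streams all derived from the one seed
    return np.random.default_rng([config.seed, stream])


def _build_annotation(config: SimConfig, rng: np.random.Generator):
    """Assign probes to genes/regions and choose the DM structure.

    Probes are laid out gene-major (gene g owns a contiguous block); each DM
    gene has all of its DM probes in a single region class so that promoter
    and gene-body effects cannot cancel inside the expression coupling.
    """
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    ppg = config.n_probes // config.n_genes
    probe_ids = [f"cg{i:08d}" for i in range(config.n_probes)]

    gene_of = np.full(config.n_probes, "", dtype=object)
    for i in range(ppg * config.n_genes):
        gene_of[i] = genes[i // ppg]
    # leftover probes beyond the gene blocks stay unassigned ("other")

    classes = np.full(config.n_probes, OTHER, dtype=object)
    p_bg = [config.frac_promoter, config.frac_genebody, config.frac_altpromoter]
    p_bg.append(max(0.0, 1.0 - sum(p_bg)))
    draw = rng.choice([PROMOTER, GENE_BODY, ALT_PROMOTER, OTHER],
                      size=config.n_probes, p=p_bg)
    assigned = gene_of != ""
    classes[assigned] = draw[assigned]
    classes[~assigned] = OTHER

    # --- DM genes: region-coherent, half hyper / half hypo within region ---
    n_dm_p, n_dm_g = config.n_dm_probes, config.n_dm_genes
    per_gene = n_dm_p // n_dm_g
    if per_gene == 0 or per_gene > ppg:
        raise ValueError(
            f"cannot place {n_dm_p} DM probes on {n_dm_g} genes with {ppg} probes/gene")
    extra = n_dm_p - per_gene * n_dm_g

    dm_gene_idx = rng.permutation(config.n_genes)[:n_dm_g]
    dm_genes = [genes[i] for i in dm_gene_idx]

    fp, fb, fa = config.dm_region_split
    n_prom = round(fp * n_dm_g)
    n_body = round(fb * n_dm_g)
    n_alt = n_dm_g - n_prom - n_body
    region_of_gene = ([PROMOTER] * n_prom + [GENE_BODY] * n_body + [ALT_PROMOTER] * n_alt)
    # alternate directions inside each region block -> exact 50/50 split
    direction_of_gene = []
    for region in (PROMOTER, GENE_BODY, ALT_PROMOTER):
        cnt = region_of_gene.count(region)
        direction_of_gene.extend([+1 if j % 2 == 0 else -1 for j in range(cnt)])

    records = []
    for j, (gi, gene) in enumerate(zip(dm_gene_idx, dm_genes)):
        k = per_gene + (1 if j < extra else 0)
        region = region_of_gene[j]
        direction = direction_of_gene[j]
        block = range(gi * ppg, gi * ppg + k)
        for pi in block:
            classes[pi] = region
            records.append((probe_ids[pi], gene, region, direction))

    annot = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(config.n_probes, dtype=int) * 1000,
            "region_class": classes,
            "gene": [g if g else pd.NA for g in gene_of],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    annot.loc[annot["region_class"] == OTHER, "gene"] = pd.NA

    dm = pd.DataFrame(records, columns=["probe_id", "gene", "region_class", "direction"])
    dm = dm.set_index("probe_id")

    # planted set = hypomethylated promoter-DM genes -> consensus GSEA sign
    # pattern (-, +, -) under repressive promoter coupling
    hypo_prom = [g for j, g in enumerate(dm_genes)
                 if region_of_gene[j] == PROMOTER and direction_of_gene[j] == -1]
    if len(hypo_prom) < config.planted_set_size:
        raise ValueError(
            f"only {len(hypo_prom)} hypomethylated promoter-DM genes available for a "
            f"planted set of size {config.planted_set_size}; increase n_genes or frac_dm")
    planted = hypo_prom[: config.planted_set_size]
    candidates = planted[: config.n_candidates]

    # tumor consistency: all DM genes except the non-candidate planted ones
    non_cand = set(planted) - set(candidates)
    dm["tumor_dm"] = [g not in non_cand for g in dm["gene"]]

    # expression coupling: planted genes always; every other gene (DM or not)
    # with prob coupled_fraction
    planted_set = set(planted)
    draw_coupled = rng.random(config.n_genes) < config.coupled_fraction
    coupled = {g: (g in planted_set) or bool(draw_coupled[i])
               for i, g in enumerate(genes)}
    gene_truth = pd.DataFrame(
        {
            "region_class": region_of_gene,
            "direction": direction_of_gene,
            "coupled": [coupled[g] for g in dm_genes],
            "tumor_dm": [g not in non_cand for g in dm_genes],
            "planted": [g in set(planted) for g in dm_genes],
            "candidate": [g in set(candidates) for g in dm_genes],
        },
        index=pd.Index(dm_genes, name="gene"),
    )
    coupling = pd.Series({g: coupled[g] for g in genes}, name="coupled")
    coupling.index.name = "gene"
    return annot, dm, gene_truth, coupling, planted, candidates


def simulate_beta_matrix(config: SimConfig) -> tuple[MethylationMatrix, SimTruth]:
    """Draw the beta matrix and its ground-truth ledger.

    Background probe baselines come from an equal-weight Beta(1,9)/Beta(9,1)
    mixture (bimodal, concentrated near 0 and 1).  DM probes start in the
    mode opposite to their direction (hyper from Beta(2,8), hypo from
    Beta(8,2)) and are shifted by +-delta_beta in the mutant/knockout arms;
    everything is clipped to (BETA_EPS, 1 - BETA_EPS).  Identical seeds give
    bit-identical output.
    """
    rng = _rng(config, 0)
    annot, dm, gene_truth, coupling, planted, candidates = _build_annotation(config, rng)

    layout = config.sample_layout()
    samples: list[str] = [s for group in layout.values() for s in group]
    groups = pd.Series(
        {s: g for g, members in layout.items() for s in members}, name="group")

    n_p, n_s = config.n_probes, len(samples)
    baseline = np.where(
        rng.random(n_p) < config.mix_weight_low,
        rng.beta(1.0, 9.0, size=n_p),
        rng.beta(9.0, 1.0, size=n_p),
    )
    # DM probes start clearly inside the mode opposite to their direction;
    # the draws are rescaled into [0.02, 0.98] because a baseline saturating
    # at the boundary makes the M-value scale degenerate under beta noise
    dm_pos = annot.index.get_indexer(dm.index)
    directions = dm["direction"].to_numpy()
    baseline[dm_pos] = 0.02 + 0.96 * np.where(
        directions > 0, rng.beta(2.0, 8.0, size=len(dm_pos)),
        rng.beta(8.0, 2.0, size=len(dm_pos)))
    # engineered candidates start deeper in the opposite methylation mode,
    # giving them the largest |delta M| (the flagship-signature margin)
    cand_probe = dm["gene"].isin(candidates).to_numpy()
    if cand_probe.any():
        k = int(cand_probe.sum())
        baseline[dm_pos[cand_probe]] = 0.02 + 0.96 * np.where(
            directions[cand_probe] > 0, rng.beta(2.0, 16.0, size=k),
            rng.beta(16.0, 2.0, size=k))

    shifted = np.clip(baseline[dm_pos] + directions * config.delta_beta,
                      BETA_EPS, 1.0 - BETA_EPS)
    true_delta = shifted - baseline[dm_pos]

    cell_case = set(layout["cell_mt"] + layout["es2_ko"] + layout["ovca429_ko"])
    tumor_case = set(layout["tumor_mt"])
    tumor_dm = dm["tumor_dm"].to_numpy()

    shift = np.zeros((n_p, n_s))
    for j, s in enumerate(samples):
        if s in cell_case:
            shift[dm_pos, j] = true_delta
        elif s in tumor_case:
            shift[dm_pos[tumor_dm], j] = true_delta[tumor_dm]

    beta = baseline[:, None] + shift + rng.normal(0.0, config.noise_sd_beta, (n_p, n_s))
    beta = np.clip(beta, BETA_EPS, 1.0 - BETA_EPS)

    meth = MethylationMatrix(
        pd.DataFrame(beta, index=annot.index, columns=pd.Index(samples, name="sample_id")))

    dm_out = dm.copy()
    dm_out["true_delta_beta"] = true_delta

    sample_sets = [
        SampleSetDefinition("primary_tumor", layout["tumor_mt"], layout["tumor_wt"]),
        SampleSetDefinition("cell_lines", layout["cell_mt"], layout["cell_wt"]),
        SampleSetDefinition("ES2_pair", layout["es2_ko"], layout["es2_parent"]),
        SampleSetDefinition("OVCA429_pair", layout["ovca429_ko"], layout["ovca429_parent"]),
    ]
    truth = SimTruth(
        probe_annotation=annot,
        dm_probes=dm_out,
        dm_genes=gene_truth,
        gene_coupling=coupling,
        dm_gene_ids=list(gene_truth.index),
        planted_genes=planted,
        planted_set_name=config.planted_set_name,
        candidate_genes=candidates,
        sample_groups=groups,
        sample_sets=sample_sets,
    )
    return meth, truth


def simulate_expression(truth: SimTruth, meth: MethylationMatrix, config: SimConfig):
    """log2 expression for the cell-line panel, coupled to methylation.

    Per coupled gene: expression = baseline - c * mean(promoter M)
    + c * mean(gene-body M) + batch_shift * batch + noise, where
    c = coupling_strength and the means run over the gene's promoter /
    gene-body probes (alternative-promoter and unassigned probes contribute
    to neither term).  Uncoupled DM genes, non-DM genes and genes with no
    probes get baseline + batch + noise only.  Batch labels alternate over
    samples so both batches contain mutant and wildtype lines.

    Returns an :class:`occmeth.integrate.ExpressionMatrix`; also fills
    ``truth.batch_assignment`` and ``truth.expr_shift`` (the noise-free
    mt-minus-wt shift actually implanted).
    """
    from .integrate import ExpressionMatrix

    rng = _rng(config, 1)
    layout = config.sample_layout()
    samples = layout["cell_mt"] + layout["cell_wt"]
    if not set(samples) <= set(meth.sample_ids):
        raise ValueError("truth/meth do not come from the same simulation")

    m = beta_to_m(meth.beta[samples]).to_numpy()
    annot = truth.probe_annotation
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    pos_of = {p: i for i, p in enumerate(annot.index)}

    prom_term = np.zeros((config.n_genes, len(samples)))
    body_term = np.zeros((config.n_genes, len(samples)))
    by_gene = annot.dropna(subset=["gene"]).groupby("gene", sort=False)
    gene_index = {g: i for i, g in enumerate(genes)}
    for gene, sub in by_gene:
        gi = gene_index[gene]
        prom = [pos_of[p] for p in sub.index[sub["region_class"] == PROMOTER]]
        body = [pos_of[p] for p in sub.index[sub["region_class"] == GENE_BODY]]
        if prom:
            prom_term[gi] = m[prom].mean(axis=0)
        if body:
            body_term[gi] = m[body].mean(axis=0)

    baseline = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd,
                          config.n_genes)
    batches = pd.Series([i % config.n_batches for i in range(len(samples))],
                        index=pd.Index(samples, name="sample_id"), name="batch")
    coupled = truth.gene_coupling.reindex(genes).to_numpy(dtype=bool)
    boost = np.where(pd.Index(genes).isin(truth.candidate_genes),
                     config.candidate_signal_boost, 1.0)
    c = config.coupling_strength * coupled[:, None] * boost[:, None]
    signal = baseline[:, None] - c * prom_term + c * body_term
    values = (signal + config.batch_shift * batches.to_numpy()[None, :]
              + rng.normal(0.0, config.noise_sd_expr, signal.shape))

    is_mt = np.array([s in set(layout["cell_mt"]) for s in samples])
    shift = signal[:, is_mt].mean(axis=1) - signal[:, ~is_mt].mean(axis=1)

    truth.batch_assignment = batches
    truth.expr_shift = pd.Series(shift, index=pd.Index(genes, name="gene"),
                                 name="expr_shift")
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        batches,
    )
    return expr


def simulate_genesets(
    truth: SimTruth,
    config: SimConfig,
    n_decoy_sets: int = 50,
    decoy_size: int = 25,
    universe: Sequence[str] | None = None,
) -> GeneSetCollection:
    """One planted direction-concordant set plus uniform decoy sets.

    The planted set is the EZH2-target-like collection of hypomethylated
    promoter-DM genes fixed at simulation time.  Decoys are drawn uniformly
    without replacement from ``universe`` (default: the full gene universe),
    so a decoy of size s overlaps the DM genes by ~ s * frac_dm in
    expectation.
    """
    rng = _rng(config, 2)
    pool = list(universe) if universe is not None else [
        f"G{i:04d}" for i in range(config.n_genes)]
    if decoy_size > len(pool):
        raise ValueError("decoy_size exceeds the universe size")
    sets: dict[str, list[str]] = {config.planted_set_name: list(truth.planted_genes)}
    width = max(3, len(str(max(n_decoy_sets, 1))))
    for i in range(n_decoy_sets):
        members = sorted(rng.choice(pool, size=decoy_size, replace=False).tolist())
        sets[f"DECOY_{i + 1:0{width}d}"] = members
    return GeneSetCollection(sets)


def simulate_dependency(truth: SimTruth, config: SimConfig) -> DependencyTable:
    """DepMap-style dependency scores over the simulated cell-line panel.

    Engineered candidate genes are selectively essential in ARID1A-deficient
    lines (their mutant-line scores are shifted by dep_essential_shift,
    negative = essential); every other gene scores ~N(0, dep_noise_sd)
    everywhere.  Seeded reruns are bit-identical.
    """
    rng = _rng(config, 3)
    layout = config.sample_layout()
    lines = layout["cell_mt"] + layout["cell_wt"]
    status = pd.Series(
        ["mt"] * len(layout["cell_mt"]) + ["wt"] * len(layout["cell_wt"]),
        index=pd.Index(lines, name="cell_line"), name="arid1a_status")
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    scores = rng.normal(0.0, config.dep_noise_sd, (config.n_genes, len(lines)))
    mt_cols = np.array([s == "mt" for s in status])
    for g in truth.candidate_genes:
        scores[genes.index(g), mt_cols] += config.dep_essential_shift
    table = pd.DataFrame(scores, index=pd.Index(genes, name="gene"), columns=lines)
    return DependencyTable(table, status, source="CRISPR")
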