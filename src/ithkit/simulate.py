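"""Synthetic multiregion cohort generator.

Generates patients with clone trees, genotypes (arm losses/gains,
chromatin-modifier driver mutations), purity-admixed expression with
gene-dosage effects and heritable Brownian drift along tree edges,
Dirichlet TME fractions with driver-linked immunosuppressive shifts,
and lineage-coupled TCR repertoires. Every generative quantity is
recorded in a truth record so downstream estimators can be tested for
parameter recovery, calibration and directionality.

The simulator is test scaffolding: its choices emulate the statistical
structure the analysis assumes, not tumor biology.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import AnalysisConfig
from .datamodel import (
    CloneGenotype,
    CloneTree,
    EPIGENETIC_DRIVERS,
    ExpressionMatrix,
    Repertoire,
    SampleMeta,
)
from .errors import ConfigError
from . import io as ioh

# ordered so the arms that acquire events (9p/14q losses, 1q/7q gains)
# exist even in small simulated gene universes
ARM_CYCLE = [
    "9p", "14q", "1q", "7q", "3p", "5q", "1p", "2q",
    "4q", "6q", "8p", "8q", "12p", "20q",
]

DEFAULT_POPULATIONS = (
    "T_effector", "CD8_T", "NK", "B_cells",
    "myeloid", "macrophages", "neutrophils", "endothelial",
)
TEFF_POPULATIONS = ("T_effector", "CD8_T", "NK")
MYELOID_POPULATIONS = ("myeloid", "macrophages", "neutrophils")


@dataclass
class SimulationConfig:
    """Knobs of the generative model; see module docstring."""

    n_patients: int = 10
    regions_per_patient: Tuple[int, int] = (2, 4)
    clones_per_patient: Tuple[int, int] = (3, 6)
    polyclonal_fraction: float = 0.2
    n_genes: int = 200
    arm_block_size: int = 20
    dosage_slope: float = 1.0
    drift_sd: float = 0.3
    driver_trans_effect: float = 1.0
    trans_target_fraction: float = 0.10
    purity_range: Tuple[float, float] = (0.5, 0.9)
    noise_sd: float = 0.1
    arm_loss_prob: float = 0.25
    arm_gain_prob: float = 0.10
    driver_mut_prob: float = 0.20
    candidate_loss_arms: Tuple[str, ...] = ("9p", "14q")
    candidate_gain_arms: Tuple[str, ...] = ("1q", "7q")
    trans_driver: str = "9p_loss"
    tme_populations: Tuple[str, ...] = DEFAULT_POPULATIONS
    tme_concentration: Tuple[float, ...] = (8.0, 6.0, 4.0, 4.0, 6.0, 5.0, 3.0, 4.0)
    immunosuppressive_shift: float = 2.0
    sig_block_size: int = 15
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    stroma_jitter_sd: float = 0.1
    min_log2_dosage: float = -3.0
    wgd_prob: float = 0.1
    metastasis_fraction: float = 0.5
    repertoire_pool_size: int = 30
    repertoire_private_rate: float = 4.0
    repertoire_geometric_p: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_genes < 1:
            raise ConfigError("n_patients and n_genes must be >= 1")
        for lo, hi, name in (
            (*self.regions_per_patient, "regions_per_patient"),
            (*self.clones_per_patient, "clones_per_patient"),
        ):
            if lo < 1 or hi < lo:
                raise ConfigError(f"invalid range for {name}: ({lo}, {hi})")
        lo, hi = self.purity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("purity_range must be ordered and within [0, 1]")
        for name in ("drift_sd", "noise_sd", "stroma_jitter_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("polyclonal_fraction", "arm_loss_prob", "arm_gain_prob",
                     "driver_mut_prob", "trans_target_fraction",
                     "metastasis_fraction", "wgd_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.arm_loss_prob + self.arm_gain_prob + self.driver_mut_prob > 1.0:
            raise ConfigError("per-edge event probabilities must sum to <= 1")
        if len(self.tme_populations) != len(self.tme_concentration):
            raise ConfigError("tme_concentration must match tme_populations")
        if not (0.0 < self.repertoire_geometric_p <= 1.0):
            raise ConfigError("repertoire_geometric_p must lie in (0, 1]")


@dataclass
class SyntheticCohort:
    """Simulated cohort plus the ground truth of its generative model."""

    expression: ExpressionMatrix
    tpm_like: ExpressionMatrix
    cn: ExpressionMatrix
    metadata: List[SampleMeta]
    trees: Dict[str, CloneTree]
    tme_fractions: ExpressionMatrix  # populations x samples, columns on simplex
    repertoires: List[Repertoire]
    gene_arms: Dict[str, str]
    truth: Dict = field(default_factory=dict)


def simulate_tree(
    n_clones: int, seed: int | np.random.Generator = 0, patient_id: str = "P0"
) -> CloneTree:
    """Random rooted tree grown by uniform attachment; root is 'MRCA'."""
    if n_clones < 1:
        raise ConfigError("n_clones must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = ["MRCA"] + [f"C{i}" for i in range(1, n_clones)]
    edges = []
    for i in range(1, n_clones):
        parent = names[int(rng.integers(0, i))]
        edges.append((parent, names[i]))
    return CloneTree(patient_id, edges, nodes=names)


def simulate_genotypes(
    tree: CloneTree, config: SimulationConfig, rng: np.random.Generator
) -> CloneTree:
    """Fill clone genotypes by cumulative inheritance along edges.

    The root carries a truncal VHL-like driver and diploid arms. Each
    non-root edge independently acquires at most one event: arm loss,
    arm gain, or an epigenetic driver mutation, with the configured
    probabilities.
    """
    root_gt = CloneGenotype(
        clone_id=tree.root,
        driver_mutations={"VHL_altered"},
        cn={},
        arm_events={arm: "neutral" for arm in ARM_CYCLE},
    )
    genotypes = {tree.root: root_gt}
    # deterministic preorder so the random stream is reproducible
    stack = [tree.root]
    order = []
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(tree.children[node]))
    for node in order:
        if node == tree.root:
            continue
        gt = genotypes[tree.parent[node]].copy()
        gt.clone_id = node
        u = rng.random()
        if u < config.arm_loss_prob:
            candidates = [
                a for a in config.candidate_loss_arms if gt.arm_events.get(a) != "loss"
            ]
            if candidates:
                arm = candidates[int(rng.integers(0, len(candidates)))]
                gt.arm_events[arm] = "loss"
        elif u < config.arm_loss_prob + config.arm_gain_prob:
            candidates = [
                a for a in config.candidate_gain_arms if gt.arm_events.get(a) != "gain"
            ]
            if candidates:
                arm = candidates[int(rng.integers(0, len(candidates)))]
                gt.arm_events[arm] = "gain"
        elif u < config.arm_loss_prob + config.arm_gain_prob + config.driver_mut_prob:
            candidates = [d for d in EPIGENETIC_DRIVERS if d not in gt.driver_mutations]
            if candidates:
                gt.driver_mutations.add(candidates[int(rng.integers(0, len(candidates)))])
        genotypes[node] = gt
    tree.genotypes = genotypes
    return tree


def _gene_arms(config: SimulationConfig) -> Tuple[List[str], Dict[str, str]]:
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    arms = {}
    for i, gene in enumerate(genes):
        arms[gene] = ARM_CYCLE[(i // config.arm_block_size) % len(ARM_CYCLE)]
    return genes, arms


def _clone_has_driver(gt: CloneGenotype, driver: str) -> bool:
    if driver.endswith("_loss"):
        return gt.arm_events.get(driver[:-5]) == "loss"
    if driver.endswith("_gain"):
        return gt.arm_events.get(driver[:-5]) == "gain"
    return driver in gt.driver_mutations


def _clone_cn_vector(
    gt: CloneGenotype, genes: List[str], arms: Dict[str, str]
) -> np.ndarray:
    cn = np.full(len(genes), 2, dtype=int)
    for i, gene in enumerate(genes):
        event = gt.arm_events.get(arms[gene], "neutral")
        if event == "loss":
            cn[i] = 1
        elif event == "gain":
            cn[i] = 3
    for gene, value in gt.cn.items():
        if gene in arms:
            cn[genes.index(gene)] = value
    return cn


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full cohort; see module docstring for the generative model.

    The random stream is split per patient from the global seed so that
    increasing ``n_patients`` leaves earlier patients' draws unchanged.
    """
    seed_seq = np.random.SeedSequence(config.seed)
    cohort_ss, *patient_ss = seed_seq.spawn(config.n_patients + 1)
    cohort_rng = np.random.default_rng(cohort_ss)

    genes, arms = _gene_arms(config)
    gene_idx = {g: i for i, g in enumerate(genes)}
    non9p = [g for g in genes if arms[g] != "9p"]
    baseline = cohort_rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    stroma_base = cohort_rng.normal(
        config.baseline_mean, config.baseline_sd, config.n_genes
    )
    pool = [g for g in non9p]
    cohort_rng.shuffle(pool)
    k = config.sig_block_size
    teff_genes = sorted(pool[:k])
    myeloid_genes = sorted(pool[k : 2 * k])
    n_targets = max(1, int(round(config.trans_target_fraction * config.n_genes)))
    trans_targets = sorted(pool[2 * k : 2 * k + n_targets])

    pops = list(config.tme_populations)
    alpha0 = np.asarray(config.tme_concentration, dtype=float)
    teff_mask = np.array([p in TEFF_POPULATIONS for p in pops])
    myeloid_mask = np.array([p in MYELOID_POPULATIONS for p in pops])

    sample_ids: List[str] = []
    expr_cols: List[np.ndarray] = []
    tpm_cols: List[np.ndarray] = []
    cn_cols: List[np.ndarray] = []
    tme_cols: List[np.ndarray] = []
    metadata: List[SampleMeta] = []
    repertoires: List[Repertoire] = []
    trees: Dict[str, CloneTree] = {}
    truth_samples: Dict[str, Dict] = {}
    truth_patients: Dict[str, Dict] = {}

    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        rng = np.random.default_rng(patient_ss[p])
        n_clones = int(
            rng.integers(config.clones_per_patient[0], config.clones_per_patient[1] + 1)
        )
        tree = simulate_tree(n_clones, rng, patient_id=pid)
        simulate_genotypes(tree, config, rng)
        trees[pid] = tree

        # per-clone expression means: baseline + dosage + drift + trans/immune shifts
        edge_drift = {
            (par, ch): rng.normal(0.0, config.drift_sd, config.n_genes)
            for par, ch in tree.edges
        }
        clone_means: Dict[str, np.ndarray] = {}
        clone_cn: Dict[str, np.ndarray] = {}
        for clone in tree.nodes:
            gt = tree.genotypes[clone]
            cn = _clone_cn_vector(gt, genes, arms)
            clone_cn[clone] = cn
            with np.errstate(divide="ignore"):
                dosage = np.log2(cn / 2.0)
            dosage = np.maximum(dosage, config.min_log2_dosage)
            mean = baseline + config.dosage_slope * dosage
            path = tree.root_path(clone)
            for child, parent in zip(path[:-1], path[1:]):
                mean = mean + edge_drift[(parent, child)]
            if _clone_has_driver(gt, config.trans_driver):
                for g in trans_targets:
                    mean[gene_idx[g]] += config.driver_trans_effect
                for g in teff_genes:
                    mean[gene_idx[g]] -= config.immunosuppressive_shift
                for g in myeloid_genes:
                    mean[gene_idx[g]] += config.immunosuppressive_shift
            clone_means[clone] = mean

        stroma = stroma_base + rng.normal(0.0, config.stroma_jitter_sd, config.n_genes)

        # repertoire scaffold: shared pool plus private clonotypes per edge
        shared_pool = [f"{pid}:shared:{i}" for i in range(config.repertoire_pool_size)]
        edge_private: Dict[Tuple[str, str], List[str]] = {}
        for par, ch in tree.edges:
            n_new = int(rng.poisson(config.repertoire_private_rate))
            edge_private[(par, ch)] = [f"{pid}:{ch}:{i}" for i in range(n_new)]
        clone_clonotypes: Dict[str, List[str]] = {}
        for clone in tree.nodes:
            keys = list(shared_pool)
            path = tree.root_path(clone)
            for child, parent in zip(path[:-1], path[1:]):
                keys.extend(edge_private[(parent, child)])
            clone_clonotypes[clone] = keys

        n_regions = int(
            rng.integers(config.regions_per_patient[0], config.regions_per_patient[1] + 1)
        )
        wgd = bool(rng.random() < config.wgd_prob)
        seeding_clone: Optional[str] = None
        has_met = rng.random() < config.metastasis_fraction
        if has_met:
            non_root = [c for c in tree.nodes if c != tree.root]
            seeding_clone = (
                non_root[int(rng.integers(0, len(non_root)))] if non_root else tree.root
            )

        region_specs: List[Tuple[str, str, List[str]]] = []
        for r in range(n_regions):
            sid = f"{pid}_R{r:02d}"
            clone = tree.nodes[int(rng.integers(0, len(tree.nodes)))]
            clones = [clone]
            if len(tree.nodes) > 1 and rng.random() < config.polyclonal_fraction:
                neighbours = list(tree.children[clone])
                if clone in tree.parent:
                    neighbours.append(tree.parent[clone])
                second = neighbours[int(rng.integers(0, len(neighbours)))]
                clones.append(second)
            region_specs.append((sid, "primary", sorted(set(clones))))
        if has_met and seeding_clone is not None:
            region_specs.append((f"{pid}_M00", "metastasis", [seeding_clone]))

        for sid, stype, clones in region_specs:
            purity = float(rng.uniform(*config.purity_range))
            tumor_mean = np.mean([clone_means[c] for c in clones], axis=0)
            obs = (
                purity * tumor_mean
                + (1.0 - purity) * stroma
                + rng.normal(0.0, config.noise_sd, config.n_genes)
            )
            cn_vec = np.round(
                np.mean([clone_cn[c] for c in clones], axis=0)
            ).astype(int)
            drivers: Dict[str, bool] = {"VHL_altered": True}
            gts = [tree.genotypes[c] for c in clones]
            drivers["9p_loss"] = any(g.arm_events.get("9p") == "loss" for g in gts)
            drivers["14q_loss"] = any(g.arm_events.get("14q") == "loss" for g in gts)
            for d in EPIGENETIC_DRIVERS:
                drivers[d] = any(d in g.driver_mutations for g in gts)
            immunosuppressive = any(
                _clone_has_driver(g, config.trans_driver) for g in gts
            )
            alpha = alpha0.copy()
            if immunosuppressive:
                alpha = np.where(
                    myeloid_mask, alpha * np.exp(config.immunosuppressive_shift), alpha
                )
                alpha = np.where(
                    teff_mask, alpha * np.exp(-config.immunosuppressive_shift), alpha
                )
            fractions = rng.dirichlet(alpha)
            wgii = float(np.mean(cn_vec != 2))

            keys = sorted({k for c in clones for k in clone_clonotypes[c]})
            counts = {
                key: int(rng.geometric(config.repertoire_geometric_p)) for key in keys
            }

            sample_ids.append(sid)
            expr_cols.append(obs)
            tpm_cols.append(np.power(2.0, obs))
            cn_cols.append(cn_vec.astype(float))
            tme_cols.append(fractions)
            metadata.append(
                SampleMeta(
                    sample_id=sid,
                    patient_id=pid,
                    sample_type=stype,
                    purity=purity,
                    wgii=wgii,
                    wgd=wgd,
                    driver_status=drivers,
                    clones=set(clones),
                )
            )
            repertoires.append(Repertoire(sample_id=sid, chain="TCR", counts=counts))
            truth_samples[sid] = {
                "patient_id": pid,
                "clones": sorted(clones),
                "purity": purity,
                "immunosuppressive": bool(immunosuppressive),
                "tumor_mean": [float(v) for v in tumor_mean],
            }

        truth_patients[pid] = {
            "n_clones": n_clones,
            "seeding_clone": seeding_clone,
            "clone_means": {
                c: [float(v) for v in m] for c, m in sorted(clone_means.items())
            },
            "stroma": [float(v) for v in stroma],
        }

    values = np.column_stack(expr_cols)
    expression = ExpressionMatrix(values, genes, sample_ids)
    tpm_like = ExpressionMatrix(np.column_stack(tpm_cols), genes, sample_ids)
    cn_matrix = ExpressionMatrix(np.column_stack(cn_cols), genes, sample_ids)
    tme = ExpressionMatrix(np.column_stack(tme_cols), pops, sample_ids)

    truth = {
        "config": asdict(config),
        "baseline": [float(v) for v in baseline],
        "stroma_base": [float(v) for v in stroma_base],
        "teff_genes": teff_genes,
        "myeloid_genes": myeloid_genes,
        "trans_target_genes": trans_targets,
        "samples": truth_samples,
        "patients": truth_patients,
    }
    return SyntheticCohort(
        expression=expression,
        tpm_like=tpm_like,
        cn=cn_matrix,
        metadata=metadata,
        trees=trees,
        tme_fractions=tme,
        repertoires=repertoires,
        gene_arms=arms,
        truth=truth,
    )


def signature_gene_sets(cohort: SyntheticCohort):
    """T-effector / myeloid GMT-style gene sets matching the simulator truth."""
    from .datamodel import GeneSet

    return [
        GeneSet("teff_signature", set(cohort.truth["teff_genes"])),
        GeneSet("myeloid_signature", set(cohort.truth["myeloid_genes"])),
    ]


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Serialize the cohort in the pipeline's text formats plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ioh.write_expression(cohort.expression, out / "expression.tsv")
    ioh.write_expression(cohort.tpm_like, out / "tpm.tsv")
    ioh.write_expression(cohort.cn, out / "copy_number.tsv")
    ioh.write_expression(cohort.tme_fractions, out / "tme_fractions.tsv")
    ioh.write_metadata(cohort.metadata, out / "metadata.tsv")
    ioh.write_repertoires(cohort.repertoires, out / "repertoires.tsv")
    annotations = [
        # synthetic genes are laid out on abstract arms; coordinates are block indices
        _annotation_for(gene, arm, i)
        for i, (gene, arm) in enumerate(sorted(cohort.gene_arms.items()))
    ]
    ioh.write_gene_annotations(annotations, out / "gene_annotations.tsv")
    ioh.write_gmt(signature_gene_sets(cohort), out / "signatures.gmt")
    tree_dir = out / "trees"
    tree_dir.mkdir(exist_ok=True)
    for pid, tree in sorted(cohort.trees.items()):
        ioh.write_clone_tree(tree, tree_dir / f"{pid}.json")
    (out / "truth.json").write_text(
        json.dumps(cohort.truth, indent=1, sort_keys=True) + "\n"
    )


def read_cohort(out_dir: str | Path) -> SyntheticCohort:
    """Load a cohort previously serialized by :func:`write_cohort`."""
    out = Path(out_dir)
    expression = ioh.read_expression(out / "expression.tsv")
    tpm_like = ioh.read_expression(out / "tpm.tsv")
    cn = ioh.read_expression(out / "copy_number.tsv")
    tme = ioh.read_expression(out / "tme_fractions.tsv")
    metadata = ioh.read_metadata(out / "metadata.tsv")
    repertoires = ioh.read_repertoires(out / "repertoires.tsv")
    annotations = ioh.read_gene_annotations(out / "gene_annotations.tsv")
    trees = {}
    for tree_path in sorted((out / "trees").glob("*.json")):
        tree = ioh.read_clone_tree(tree_path, format="edge-json")
        trees[tree.patient_id] = tree
    truth = json.loads((out / "truth.json").read_text())
    return SyntheticCohort(
        expression=expression,
        tpm_like=tpm_like,
        cn=cn,
        metadata=metadata,
        trees=trees,
        tme_fractions=tme,
        repertoires=repertoires,
        gene_arms={a.gene_id: a.arm for a in annotations},
        truth=truth,
    )


def _annotation_for(gene: str, arm: str, index: int):
    from .datamodel import GeneAnnotation

    chromosome = arm.rstrip("pq")
    start = index * 1000 + 1
    return GeneAnnotation(
        gene_id=gene, chromosome=chromosome, arm=arm, start=start, end=start + 999
    )
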