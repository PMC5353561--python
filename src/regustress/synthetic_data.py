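"""Synthetic expression studies with planted, recoverable structure.

The generator emulates the shape of the real microarray designs: seven
acute-stress treatment-versus-control contrasts with replicate counts
(3+3 or 8+4) and ethanol concentrations {2.5, 5, 3, 15, 15, 15, 15}% v/v,
and an adaptive-evolution design of six strains profiled at
{384, 744, 1224, 1824, 2496} hours against a single parent.  Planted
structure — differentially expressed genes, dose-responsive gene sets,
aberrant transcription units decoupled from their regulator, and monotone
adaptation trajectories concordant (or not) with tolerance annotations —
is recorded in truth tables so every downstream stage can be scored.

Noise is i.i.d. Gaussian on the log2 scale (a Student-t option with 5
degrees of freedom is available for robustness checks).  Baseline log2
levels are uniform on [6, 12] against a detection threshold of 4, so all
genes are expressed unless ``not_expressed_fraction`` is set.  All
randomness flows from the seed passed to each operation; identical
config+seed yields byte-identical fixture files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    ContrastDesign,
    DIRECTION_KNOCKOUT,
    DIRECTION_OVEREXPRESSION,
    ExpressionStudy,
    GeneSet,
    GeneSetCollection,
    RegEdge,
    RegulatoryNetwork,
    SIGN_ACTIVATION,
    SIGN_REPRESSION,
    ValidationError,
    write_contrasts,
    write_expression_study,
    write_gene_sets,
    write_network,
)

# the seven-contrast acute-stress design: (treatment reps, control reps, % v/v)
NEA_DESIGN = (
    (3, 3, 2.5),
    (8, 4, 5.0),
    (8, 4, 3.0),
    (3, 3, 15.0),
    (3, 3, 15.0),
    (3, 3, 15.0),
    (3, 3, 15.0),
)

EA_TIMEPOINTS = (0, 384, 744, 1224, 1824, 2496)


@dataclass
class SynthConfig:
    """Generator settings; defaults emulate the study conditions."""

    n_genes: int = 1200
    # gene sets
    n_sets: int = 10
    set_size_min: int = 8
    set_size_max: int = 30
    n_dose_responsive_sets: int = 2
    dose_slope: float = 0.05  # log2 units per % v/v ethanol
    # regulatory network
    n_tfs: int = 8
    tus_per_tf: int = 6
    genes_per_tu: int = 3
    sole_regulator_fraction: float = 0.8
    activation_fraction: float = 0.7
    ebp_fraction: float = 0.5
    fraction_aberrant_tus: float = 0.3
    # acute-stress design
    deg_fraction: float = 0.10
    effect_size: float = 1.0  # log2 FC of planted DEGs
    # adaptive-evolution design
    n_strains: int = 6
    n_tolerance_genes: int = 100
    concordant_fraction: float = 0.91
    fraction_trend_genes: float = 0.30
    fraction_monotone: float = 0.80
    step_increment: float = 0.30  # log2 per evolution step
    # noise / baseline
    noise_sd: float = 0.25
    noise_model: str = "gaussian"  # gaussian | t5
    baseline_low: float = 6.0
    baseline_high: float = 12.0
    detection_threshold: float = 4.0
    not_expressed_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_sets", "n_tfs", "tus_per_tf", "genes_per_tu",
            "n_strains", "n_tolerance_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in (
            "sole_regulator_fraction", "activation_fraction", "ebp_fraction",
            "fraction_aberrant_tus", "deg_fraction", "concordant_fraction",
            "fraction_trend_genes", "fraction_monotone", "not_expressed_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.noise_model not in ("gaussian", "t5"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        n_network_genes = self.n_tfs * (1 + self.tus_per_tf * self.genes_per_tu)
        if n_network_genes > self.n_genes:
            raise ValidationError(
                f"infeasible configuration: network needs {n_network_genes} genes "
                f"but n_genes = {self.n_genes}"
            )


@dataclass
class TruthTables:
    """Planted structure, keyed by the identifiers of the generated study."""

    deg: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene", "contrast", "direction", "effect"]
        )
    )
    dose_sets: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["set", "slope"])
    )
    aberrant_tus: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["tu", "tf", "sign", "tf_state", "planted_verdict"]
        )
    )
    trend: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "trend_class", "direction"])
    )
    tolerance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "direction", "concordant"])
    )
    # per-contrast planted shifts (gene -> log2 shift), nonzero entries only
    shifts: dict[str, pd.Series] = field(default_factory=dict)

    def unaffected_genes(self, contrast: str, genes: list[str]) -> list[str]:
        """Genes with no planted effect of any kind in a contrast."""
        shifted = set(self.shifts.get(contrast, pd.Series(dtype=float)).index)
        return [g for g in genes if g not in shifted]


def _gene_names(config: SynthConfig) -> tuple[list[str], list[str]]:
    tf_genes = [f"tf{i:02d}" for i in range(1, config.n_tfs + 1)]
    others = [f"g{i:05d}" for i in range(1, config.n_genes - config.n_tfs + 1)]
    return tf_genes, others


def _noise(rng: np.random.Generator, config: SynthConfig, shape) -> np.ndarray:
    if config.noise_model == "gaussian":
        return rng.normal(0.0, config.noise_sd, shape)
    return rng.standard_t(5, shape) * config.noise_sd / np.sqrt(5 / 3)


def generate_network(config: SynthConfig, seed: int | None = None) -> RegulatoryNetwork:
    """Random signed TF -> TU -> gene network.

    Each TF regulates ``tus_per_tf`` TUs of ``genes_per_tu`` member genes
    (member assignments are disjoint).  A TU receives a second regulator
    with probability ``1 - sole_regulator_fraction``; edges are activating
    with probability ``activation_fraction``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tf_genes, others = _gene_names(config)
    edges: list[RegEdge] = []
    members: dict[str, list[str]] = {}
    gene_cursor = 0
    tu_idx = 0
    for tf in tf_genes:
        for _ in range(config.tus_per_tf):
            tu_idx += 1
            tu = f"tu{tu_idx:03d}"
            members[tu] = others[gene_cursor : gene_cursor + config.genes_per_tu]
            gene_cursor += config.genes_per_tu
            sign = (
                SIGN_ACTIVATION
                if rng.random() < config.activation_fraction
                else SIGN_REPRESSION
            )
            edges.append(RegEdge(tf=tf, tu=tu, sign=sign))
            if rng.random() > config.sole_regulator_fraction and config.n_tfs > 1:
                other = tf_genes[rng.integers(config.n_tfs)]
                while other == tf:
                    other = tf_genes[rng.integers(config.n_tfs)]
                sign2 = (
                    SIGN_ACTIVATION
                    if rng.random() < config.activation_fraction
                    else SIGN_REPRESSION
                )
                edges.append(RegEdge(tf=other, tu=tu, sign=sign2))
    n_ebp = max(1, round(config.ebp_fraction * config.n_tfs))
    ebp = list(rng.choice(tf_genes, size=n_ebp, replace=False))
    return RegulatoryNetwork(edges=edges, members=members, ebp_tfs=ebp)


def generate_gene_sets(
    config: SynthConfig, network: RegulatoryNetwork, seed: int | None = None
) -> GeneSetCollection:
    """Named gene sets drawn from genes outside the regulatory network.

    The first ``n_dose_responsive_sets`` sets (category ``stress_response``)
    are the ones that receive dose-proportional shifts in the acute-stress
    study; the rest are inert ``pathway`` sets.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    tf_genes, others = _gene_names(config)
    network_genes = {g for genes in network.members.values() for g in genes}
    pool = [g for g in others if g not in network_genes]
    sets = []
    for i in range(1, config.n_sets + 1):
        size = int(rng.integers(config.set_size_min, config.set_size_max + 1))
        genes = list(rng.choice(pool, size=min(size, len(pool)), replace=False))
        category = (
            "stress_response" if i <= config.n_dose_responsive_sets else "pathway"
        )
        sets.append(GeneSet(name=f"set{i:02d}", genes=tuple(sorted(genes)), category=category))
    return GeneSetCollection(sets)


def _aberrant_pattern(sign: str, tf_state: str, effect: float) -> float:
    """TU member shift that contradicts the regulator's state."""
    if sign == SIGN_ACTIVATION:
        # tf ns -> TU down ; tf up -> TU flat ("not up")
        return -effect if tf_state == "ns" else 0.0
    # repression: tf ns -> TU up ; tf up -> TU up
    return effect


def _consistent_pattern(sign: str, tf_state: str, effect: float) -> float:
    if tf_state == "ns":
        return 0.0
    return effect if sign == SIGN_ACTIVATION else -effect


def generate_nea_study(
    config: SynthConfig,
    network: RegulatoryNetwork,
    seed: int | None = None,
    sets: GeneSetCollection | None = None,
) -> tuple[ExpressionStudy, list[ContrastDesign], TruthTables]:
    """Seven-contrast acute-stress study with planted effects.

    Planted structure per contrast: a ``deg_fraction`` of eligible genes
    shifted by ``effect_size`` (random sign); dose-responsive sets shifted
    by ``dose_slope * ethanol_pct``; TU members of ethanol-binding TFs
    shifted consistently with — or, for planted-aberrant TUs, decoupled
    from — their regulator's planted state.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tf_genes, others = _gene_names(config)
    genes = tf_genes + others
    if sets is None:
        sets = generate_gene_sets(config, network, seed=seed)

    baseline = rng.uniform(config.baseline_low, config.baseline_high, len(genes))
    n_silent = round(config.not_expressed_fraction * len(genes))
    if n_silent:
        silent_idx = rng.choice(len(genes), size=n_silent, replace=False)
        baseline[silent_idx] = rng.uniform(0.0, config.detection_threshold - 1.0, n_silent)

    gene_pos = {g: i for i, g in enumerate(genes)}
    network_genes = {g for gs in network.members.values() for g in gs}
    dose_genes = {
        g
        for s in sets.by_category("stress_response")[: config.n_dose_responsive_sets]
        for g in s.genes
    }
    set_genes = {g for s in sets for g in s.genes}
    eligible = [
        g for g in others if g not in network_genes and g not in set_genes
    ]

    # global planted regulator states and TU verdicts (shared across contrasts)
    tf_state = {
        tf: ("up" if rng.random() < 0.5 else "ns") for tf in sorted(network.ebp_tfs)
    }
    aberrant_rows = []
    tu_shift: dict[str, float] = {}
    for tf in sorted(network.ebp_tfs):
        for edge in network.sole_regulator_tus(tf):
            aberrant = rng.random() < config.fraction_aberrant_tus
            shift = (
                _aberrant_pattern(edge.sign, tf_state[tf], config.effect_size)
                if aberrant
                else _consistent_pattern(edge.sign, tf_state[tf], config.effect_size)
            )
            tu_shift[edge.tu] = shift
            aberrant_rows.append(
                {
                    "tu": edge.tu,
                    "tf": tf,
                    "sign": edge.sign,
                    "tf_state": tf_state[tf],
                    "planted_verdict": "aberrant" if aberrant else "consistent",
                }
            )

    contrasts: list[ContrastDesign] = []
    truth = TruthTables(
        aberrant_tus=pd.DataFrame(
            aberrant_rows,
            columns=["tu", "tf", "sign", "tf_state", "planted_verdict"],
        )
    )
    deg_rows = []
    columns: dict[str, np.ndarray] = {}
    meta_rows = []

    for ci, (n_t, n_c, ethanol) in enumerate(NEA_DESIGN, start=1):
        name = f"nea{ci}"
        shift = np.zeros(len(genes))
        # random planted DEGs
        n_deg = round(config.deg_fraction * len(eligible))
        planted = rng.choice(eligible, size=n_deg, replace=False)
        directions = rng.choice([-1.0, 1.0], size=n_deg)
        for g, d in zip(planted, directions):
            shift[gene_pos[g]] = d * config.effect_size
            deg_rows.append(
                {
                    "gene": g,
                    "contrast": name,
                    "direction": "up" if d > 0 else "down",
                    "effect": config.effect_size,
                }
            )
        # dose-responsive sets
        for g in dose_genes:
            shift[gene_pos[g]] += config.dose_slope * ethanol
        # regulator-driven structure
        for tf, state in tf_state.items():
            if state == "up":
                shift[gene_pos[tf]] += config.effect_size
        for tu, s in tu_shift.items():
            for g in network.members[tu]:
                shift[gene_pos[g]] += s

        t_samples = [f"{name}_t{r}" for r in range(1, n_t + 1)]
        c_samples = [f"{name}_c{r}" for r in range(1, n_c + 1)]
        for r, s in enumerate(t_samples, start=1):
            columns[s] = baseline + shift + _noise(rng, config, len(genes))
            meta_rows.append((s, "treatment", r, "synthetic", pd.NA, ethanol))
        for r, s in enumerate(c_samples, start=1):
            columns[s] = baseline + _noise(rng, config, len(genes))
            meta_rows.append((s, "control", r, "synthetic", pd.NA, 0.0))
        contrasts.append(
            ContrastDesign(
                name=name,
                treatment=tuple(t_samples),
                control=tuple(c_samples),
                ethanol_pct=ethanol,
            )
        )
        nz = shift != 0
        truth.shifts[name] = pd.Series(
            shift[nz], index=[genes[i] for i in np.flatnonzero(nz)]
        )

    values = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample", "condition", "replicate", "strain", "time_h", "ethanol_pct"],
    ).set_index("sample")
    meta["time_h"] = meta["time_h"].astype("Int64")
    study = ExpressionStudy(values=values, metadata=meta)
    truth.deg = pd.DataFrame(
        deg_rows, columns=["gene", "contrast", "direction", "effect"]
    )
    truth.dose_sets = pd.DataFrame(
        [
            {"set": s.name, "slope": config.dose_slope}
            for s in sets.by_category("stress_response")[: config.n_dose_responsive_sets]
        ]
    )
    return study, contrasts, truth


def generate_ea_timecourse(
    config: SynthConfig, seed: int | None = None
) -> tuple[ExpressionStudy, GeneSetCollection, TruthTables]:
    """Adaptive-evolution time course: one parent, six evolved strains.

    A ``tolerance`` gene set is emitted with per-gene direction
    annotations; ``concordant_fraction`` of those genes receive monotone
    trajectories matching their annotation (overexpression-tolerant up,
    knockout-tolerant down) and the rest the opposite direction.  A
    further ``fraction_trend_genes`` of unannotated genes receive
    trajectories of which ``fraction_monotone`` are monotone and the rest
    zig-zag.  Monotone trajectories accumulate ``step_increment`` log2
    units per post-zero time point.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    tf_genes, others = _gene_names(config)
    genes = tf_genes + others
    gene_pos = {g: i for i, g in enumerate(genes)}
    baseline = rng.uniform(config.baseline_low, config.baseline_high, len(genes))

    n_tol = min(config.n_tolerance_genes, len(others))
    tol_genes = list(rng.choice(others, size=n_tol, replace=False))
    directions = {}
    trend_rows, tol_rows = [], []
    per_gene_traj: dict[str, np.ndarray] = {}
    steps = np.arange(1, len(EA_TIMEPOINTS))  # 1..5

    for i, g in enumerate(tol_genes):
        ann = DIRECTION_OVEREXPRESSION if i % 2 == 0 else DIRECTION_KNOCKOUT
        directions[g] = ann
        expected = 1.0 if ann == DIRECTION_OVEREXPRESSION else -1.0
        concordant = rng.random() < config.concordant_fraction
        d = expected if concordant else -expected
        per_gene_traj[g] = d * config.step_increment * steps
        trend_rows.append(
            {
                "gene": g,
                "trend_class": "monotone_up" if d > 0 else "monotone_down",
                "direction": "up" if d > 0 else "down",
            }
        )
        tol_rows.append({"gene": g, "direction": ann, "concordant": concordant})

    pool = [g for g in others if g not in per_gene_traj]
    n_trend = round(config.fraction_trend_genes * len(pool))
    extra = list(rng.choice(pool, size=n_trend, replace=False))
    for g in extra:
        if rng.random() < config.fraction_monotone:
            d = 1.0 if rng.random() < 0.5 else -1.0
            per_gene_traj[g] = d * config.step_increment * steps
            trend_rows.append(
                {
                    "gene": g,
                    "trend_class": "monotone_up" if d > 0 else "monotone_down",
                    "direction": "up" if d > 0 else "down",
                }
            )
        else:
            amp = 2.0 * config.step_increment
            per_gene_traj[g] = amp * np.array([1.0, 0.0, 1.0, 0.0, 1.0])[: len(steps)]
            trend_rows.append(
                {"gene": g, "trend_class": "non_monotone", "direction": "none"}
            )

    traj = np.zeros((len(genes), len(EA_TIMEPOINTS)))
    for g, t in per_gene_traj.items():
        traj[gene_pos[g], 1:] = t

    columns: dict[str, np.ndarray] = {}
    meta_rows = [("parent", "parent", 1, "parent", 0, 5.0)]
    columns["parent"] = baseline + _noise(rng, config, len(genes))
    strains = [f"strain{chr(ord('A') + i)}" for i in range(config.n_strains)]
    for strain in strains:
        for k, t in enumerate(EA_TIMEPOINTS):
            s = f"{strain}_h{t}"
            columns[s] = baseline + traj[:, k] + _noise(rng, config, len(genes))
            meta_rows.append((s, "evolved", 1, strain, t, 5.0))

    values = pd.DataFrame(columns, index=genes)
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample", "condition", "replicate", "strain", "time_h", "ethanol_pct"],
    ).set_index("sample")
    meta["time_h"] = meta["time_h"].astype("Int64")
    study = ExpressionStudy(values=values, metadata=meta)

    tol_set = GeneSet(
        name="tolerance",
        genes=tuple(sorted(tol_genes)),
        category="tolerance",
        directions=dict(sorted(directions.items())),
    )
    truth = TruthTables(
        trend=pd.DataFrame(trend_rows), tolerance=pd.DataFrame(tol_rows)
    )
    return study, GeneSetCollection([tol_set]), truth


def write_fixtures(
    directory: str | Path,
    config: SynthConfig,
    network: RegulatoryNetwork,
    sets: GeneSetCollection,
    nea: tuple[ExpressionStudy, list[ContrastDesign], TruthTables],
    ea: tuple[ExpressionStudy, GeneSetCollection, TruthTables],
    seed: int | None = None,
) -> dict:
    """Write every artifact in the pipeline's file formats plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nea_study, contrasts, nea_truth = nea
    ea_study, ea_sets, ea_truth = ea

    write_expression_study(
        nea_study, directory / "nea_matrix.tsv", directory / "nea_metadata.tsv"
    )
    write_contrasts(contrasts, directory / "contrasts.tsv")
    write_expression_study(
        ea_study, directory / "ea_matrix.tsv", directory / "ea_metadata.tsv"
    )
    all_sets = GeneSetCollection([*sets, *ea_sets])
    write_gene_sets(
        all_sets, directory / "gene_sets.gmt", directory / "gene_set_directions.tsv"
    )
    write_network(network, directory / "network.tsv")
    nea_truth.deg.to_csv(directory / "truth_deg.tsv", sep="\t", index=False)
    nea_truth.dose_sets.to_csv(directory / "truth_dose_sets.tsv", sep="\t", index=False)
    nea_truth.aberrant_tus.to_csv(
        directory / "truth_aberrant_tus.tsv", sep="\t", index=False
    )
    ea_truth.trend.to_csv(directory / "truth_trend.tsv", sep="\t", index=False)
    ea_truth.tolerance.to_csv(directory / "truth_tolerance.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed if seed is None else seed,
        "config": dataclasses.asdict(config),
        "files": sorted(p.name for p in directory.iterdir() if p.name != "manifest.json"),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def generate_all(config: SynthConfig, seed: int | None = None):
    """Convenience: network, sets, acute-stress study and evolution study
    from one seed (per-stage streams derived via SeedSequence.spawn)."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_net, s_nea, s_ea = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)]
    network = generate_network(config, seed=s_net)
    sets = generate_gene_sets(config, network, seed=s_net)
    nea = generate_nea_study(config, network, seed=s_nea, sets=sets)
    ea = generate_ea_timecourse(config, seed=s_ea)
    return network, sets, nea, ea
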