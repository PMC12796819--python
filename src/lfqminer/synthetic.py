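"""Synthetic MaxQuant-dialect data with known ground truth.

The generator emulates a label-free experiment the way the analysis models
it: per-protein baseline log2 abundances, condition-specific planted shifts
for a chosen subset of proteins, Gaussian replicate noise, logistic
intensity-dependent dropout (missing-not-at-random: the lower a value, the
likelier it vanishes) plus a uniform missing-at-random floor, and decoy /
contaminant rows carrying the MaxQuant ``+`` flags.  Output uses exactly
the ``proteinGroups.txt`` column dialect the parser consumes, alongside
truth tables (true per-contrast log2 fold changes, the dropout mask, the
true differential set) so every downstream module has closed-form expected
values.

Defaults mirror a typical 12-sample mouse liver study: 4 conditions x 3
replicates, ~2000 proteins, baseline log2 intensities centered at 25 (SD 2
across proteins), replicate SD 0.5, planted |log2FC| = 2 on a small subset,
and logistic dropout centered ~1.5 baseline SDs below the mean intensity,
so missingness concentrates in the low-abundance tail.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .maxquant_io import ExperimentDesign

DEFAULT_CONDITIONS = ("Chow_Veh", "Chow_LDT409", "HFD_Veh", "HFD_LDT409")


@dataclass
class PlantedEffect:
    """A protein subset shifted by a per-condition log2 offset."""

    proteins: tuple[int, ...]  # row indices into the simulated matrix
    shifts: dict[str, float]  # condition -> log2 shift


@dataclass
class SimulationSpec:
    n_proteins: int = 2000
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    planted: list[PlantedEffect] = field(default_factory=list)
    mnar_midpoint: float = 22.0  # log2 intensity of 50% dropout
    mnar_slope: float = 3.0  # logistic steepness per log2 unit
    mar_rate: float = 0.0  # uniform missingness floor
    n_decoys: int = 20
    n_contaminants: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_replicates < 2 or len(self.conditions) < 2:
            raise ValidationError("need >= 1 protein, >= 2 conditions, >= 2 replicates")
        if not (0 <= self.mar_rate <= 1):
            raise ValidationError("mar_rate must lie in [0, 1]")
        if self.mnar_slope < 0:
            raise ValidationError("mnar_slope must be nonnegative")
        seen: set[int] = set()
        for eff in self.planted:
            idx = set(eff.proteins)
            if idx & seen:
                raise ValidationError("planted protein subsets must be disjoint")
            if max(idx, default=-1) >= self.n_proteins or min(idx, default=0) < 0:
                raise ValidationError("planted protein index out of range")
            unknown = set(eff.shifts) - set(self.conditions)
            if unknown:
                raise ValidationError(f"planted shift for unknown conditions {unknown}")
            seen |= idx

    @property
    def labels(self) -> list[str]:
        n = len(self.conditions) * self.n_replicates
        return [f"MS{i + 1:02d}" for i in range(n)]

    def design(self) -> ExperimentDesign:
        rows = []
        i = 0
        for cond in self.conditions:
            for rep in range(1, self.n_replicates + 1):
                rows.append(
                    {"label": self.labels[i], "condition": cond,
                     "replicate": rep, "order": i + 1}
                )
                i += 1
        return ExperimentDesign(pd.DataFrame(rows))


def default_planted_spec(
    n_de: int = 100, effect: float = 2.0, seed: int = 0, **kwargs
) -> SimulationSpec:
    """Convenience spec: n_de proteins shifted in the two LDT409 conditions.

    Half the planted proteins go up, half down, mimicking a treatment effect
    shared across both diets.
    """
    spec = SimulationSpec(seed=seed, **kwargs)
    up = tuple(range(0, n_de // 2))
    down = tuple(range(n_de // 2, n_de))
    treated = [c for c in spec.conditions if c.endswith("LDT409")] or list(spec.conditions[:1])
    spec.planted = [
        PlantedEffect(up, {c: effect for c in treated}),
        PlantedEffect(down, {c: -effect for c in treated}),
    ]
    spec.__post_init__()
    return spec


@dataclass
class SimulatedData:
    """In-memory simulation output plus its ground truth."""

    protein_groups: pd.DataFrame  # the proteinGroups.txt content
    design: ExperimentDesign
    true_log2: pd.DataFrame  # noise-free planted log2 means (proteins x samples)
    observed_log2: pd.DataFrame  # noisy log2 values before dropout
    missing_mask: pd.DataFrame  # True where dropped to 0
    true_log2fc: pd.DataFrame  # proteins x contrast ids
    true_de: set[str]  # ids with a nonzero true log2FC in some contrast
    gene_names: list[str]

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(os.path.join(outdir, "truth"), exist_ok=True)
        paths = {
            "protein_groups": os.path.join(outdir, "proteinGroups.txt"),
            "design": os.path.join(outdir, "design.tsv"),
            "true_log2fc": os.path.join(outdir, "truth", "true_log2fc.tsv"),
            "missing_mask": os.path.join(outdir, "truth", "missing_mask.tsv"),
            "true_de": os.path.join(outdir, "truth", "true_de.txt"),
        }
        self.protein_groups.to_csv(paths["protein_groups"], sep="\t", index=False)
        self.design.table.to_csv(paths["design"], sep="\t", index=False)
        self.true_log2fc.to_csv(paths["true_log2fc"], sep="\t")
        self.missing_mask.astype(int).to_csv(paths["missing_mask"], sep="\t")
        with open(paths["true_de"], "w") as fh:
            fh.write("\n".join(sorted(self.true_de)) + "\n")
        return paths


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_protein_groups(spec: SimulationSpec) -> SimulatedData:
    """Run the generative model; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    design = spec.design()
    labels = spec.labels
    n, m = spec.n_proteins, len(labels)

    genes = [f"Gene{i + 1:04d}" for i in range(n)]
    accs = [f"P{i + 1:05d}" for i in range(n)]

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)
    true = np.tile(baseline[:, None], (1, m))
    cond_of = design.table["condition"].tolist()
    for eff in spec.planted:
        for j, cond in enumerate(cond_of):
            shift = eff.shifts.get(cond, 0.0)
            if shift:
                true[list(eff.proteins), j] += shift
    observed = true + rng.normal(0.0, spec.noise_sd, size=(n, m))

    if spec.mnar_slope > 0:
        p_mnar = _sigmoid((spec.mnar_midpoint - observed) * spec.mnar_slope)
    else:
        p_mnar = np.zeros_like(observed)  # slope 0 switches MNAR dropout off
    p_drop = np.clip(p_mnar + spec.mar_rate, 0.0, 1.0)
    mask = rng.random(size=(n, m)) < p_drop

    linear = np.power(2.0, observed)
    linear[mask] = 0.0

    # decoy / contaminant rows: plausible intensities, never part of truth
    n_extra = spec.n_decoys + spec.n_contaminants
    extra_lin = np.power(
        2.0, rng.normal(spec.baseline_mean, spec.baseline_sd, size=(n_extra, m))
    )
    extra_genes = [f"Rev{i + 1:03d}" for i in range(spec.n_decoys)] + [
        f"Con{i + 1:03d}" for i in range(spec.n_contaminants)
    ]
    extra_accs = [f"REV__Q{i + 1:05d}" for i in range(spec.n_decoys)] + [
        f"CON__Q{i + 1:05d}" for i in range(spec.n_contaminants)
    ]

    pg = pd.DataFrame(
        {
            "Protein IDs": accs + extra_accs,
            "Majority protein IDs": accs + extra_accs,
            "Gene names": genes + extra_genes,
        }
    )
    all_lin = np.vstack([linear, extra_lin])
    for j, lbl in enumerate(labels):
        pg[f"LFQ intensity {lbl}"] = all_lin[:, j]
    pg["Reverse"] = [""] * n + ["+"] * spec.n_decoys + [""] * spec.n_contaminants
    pg["Potential contaminant"] = [""] * n + [""] * spec.n_decoys + ["+"] * spec.n_contaminants
    pg["Only identified by site"] = ""

    conds = sorted(spec.conditions)
    contrast_ids = []
    fc_cols = {}
    shift_of = {c: np.zeros(n) for c in spec.conditions}
    for eff in spec.planted:
        for c, s in eff.shifts.items():
            shift_of[c][list(eff.proteins)] += s
    import itertools

    for a, b in itertools.combinations(conds, 2):
        cid = f"{a}_vs_{b}"
        contrast_ids.append(cid)
        fc_cols[cid] = shift_of[a] - shift_of[b]
    true_fc = pd.DataFrame(fc_cols, index=genes)
    true_de = set(true_fc.index[(true_fc != 0).any(axis=1)])

    idx = pd.Index(genes, name="id")
    return SimulatedData(
        protein_groups=pg,
        design=design,
        true_log2=pd.DataFrame(true, index=idx, columns=labels),
        observed_log2=pd.DataFrame(observed, index=idx, columns=labels),
        missing_mask=pd.DataFrame(mask, index=idx, columns=labels),
        true_log2fc=true_fc,
        true_de=true_de,
        gene_names=genes,
    )


@dataclass
class AnnotationPlan:
    """Overlap plan for gene-set / consensome fixtures with known answers."""

    pathway_id: str = "R-HSA-77111"
    pathway_name: str = "Synthesis of ketone bodies (synthetic fixture)"
    n_in_dataset: int = 6
    n_absent: int = 2
    receptor: str = "PPAR"
    n_targets_in_dataset: int = 50
    target_percentile_range: tuple[float, float] = (95.0, 100.0)
    n_targets_below_cutoff: int = 20
    below_percentile_range: tuple[float, float] = (50.0, 94.0)


def simulate_gene_annotations(
    sim: SimulatedData,
    plan: AnnotationPlan,
    seed: int = 0,
    detected: list[str] | None = None,
) -> tuple[dict[str, object], pd.DataFrame]:
    """Build a GMT-style gene-set dict and a long-form consensome DataFrame.

    Pathway: ``plan.n_in_dataset`` genes drawn from the dataset (from
    ``detected`` when given, so the overlap is exact even after filtering)
    plus ``plan.n_absent`` invented absent genes.  Consensome: the first
    ``n_targets_in_dataset`` dataset genes score in the target percentile
    range, the next ``n_targets_below_cutoff`` below it.
    """
    from .pathway_miner import GeneSet

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    genes = list(detected) if detected is not None else sim.gene_names
    need = plan.n_in_dataset + plan.n_targets_in_dataset + plan.n_targets_below_cutoff
    if need > len(genes):
        raise ValidationError("annotation plan needs more genes than simulated")
    present = list(rng.choice(genes, size=plan.n_in_dataset, replace=False))
    absent = [f"Absent{i + 1:03d}" for i in range(plan.n_absent)]
    gs = GeneSet(
        set_id=plan.pathway_id,
        name=plan.pathway_name,
        species="mouse",
        genes=frozenset(present + absent),
    )

    remaining = [g for g in genes if g not in set(present)]
    picked = list(rng.choice(remaining,
                             size=plan.n_targets_in_dataset + plan.n_targets_below_cutoff,
                             replace=False))
    hi = picked[: plan.n_targets_in_dataset]
    lo = picked[plan.n_targets_in_dataset:]
    lo_r, hi_r = plan.below_percentile_range, plan.target_percentile_range
    rows = [
        {"gene": g, "receptor": plan.receptor,
         "percentile": float(np.round(rng.uniform(*hi_r), 2))}
        for g in hi
    ] + [
        {"gene": g, "receptor": plan.receptor,
         "percentile": float(np.round(rng.uniform(*lo_r), 2))}
        for g in lo
    ]
    return {gs.set_id: gs}, pd.DataFrame(rows)


def write_annotation_fixtures(
    gene_sets: dict[str, object], consensome: pd.DataFrame, outdir: str
) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    gmt = os.path.join(outdir, "pathways.gmt")
    with open(gmt, "w") as fh:
        for gs in gene_sets.values():
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.genes)]) + "\n")
    cons = os.path.join(outdir, "consensome.tsv")
    consensome.to_csv(cons, sep="\t", index=False)
    return {"gmt": gmt, "consensome": cons}
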