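"""Synthetic paired two-group expression cohorts with planted effects.

The generator emulates a paired lesion/control RNA-seq design (default
seven patients, matching the study design the pipeline targets): per-gene
negative-binomial counts with a shared per-patient lognormal depth factor,
multiplicative fold changes planted on chosen enzyme genes in the lesion
group, and recorded gene lengths for TPM conversion.  A gold-standard
answer key derives the expected flux direction of every sentinel reaction
directly from the planted effects and the model's GPR rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import CONTROL, LESION, ExpressionMatrix
from .model_io import MetabolicModel

__all__ = [
    "SyntheticDesign",
    "GoldStandard",
    "generate_counts",
    "make_gold_standard",
    "make_demo_design",
    "DEMO_PLANTED_EFFECTS",
    "ANCHOR_GENE_MEANS",
    "make_cluster_profiles",
    "write_cohort",
]

#: Fold changes planted on sentinel gating genes in the demo cohort:
#: two enzyme knockdowns and one upregulation on the lesion group.
DEMO_PLANTED_EFFECTS: dict[str, float] = {
    "DEGS1_toy": 0.25,   # gates DHCRD2
    "ELOVL5_toy": 0.25,  # gates FAEL183
    "PISD_toy": 4.0,     # gates PSDm_hs
}

#: Housekeeping-level enzymes that anchor the per-sample percentile
#: normalization of reaction activities (highly expressed in skin).
ANCHOR_GENE_MEANS: dict[str, float] = {
    "GAPDH_toy": 5000.0,
    "NDUFA_toy": 5000.0,
}


@dataclass
class SyntheticDesign:
    """Parameters of a paired two-group negative-binomial cohort."""

    n_pairs: int = 7
    n_genes: int = 200
    nb_mean: float = 100.0
    nb_dispersion: float = 0.05
    planted_effects: dict[str, float] = field(default_factory=dict)
    patient_effect_sd: float = 0.2
    seed: int = 0
    gene_ids: tuple[str, ...] | None = None
    gene_means: dict[str, float] = field(default_factory=dict)
    length_range: tuple[float, float] = (500.0, 5000.0)

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.nb_mean <= 0 or self.nb_dispersion < 0:
            raise ValueError("nb_mean must be > 0 and nb_dispersion >= 0")
        if self.patient_effect_sd < 0:
            raise ValueError("patient_effect_sd must be >= 0")
        if self.gene_ids is not None:
            self.gene_ids = tuple(self.gene_ids)
            if len(self.gene_ids) != self.n_genes:
                raise ValueError("gene_ids length must equal n_genes")
        universe = set(self.universe)
        for gene, fold in self.planted_effects.items():
            if fold <= 0:
                raise ValueError(f"fold change for {gene!r} must be > 0")
            if gene not in universe:
                raise ValueError(f"planted gene {gene!r} not in the gene universe")
        for gene in self.gene_means:
            if gene not in universe:
                raise ValueError(f"gene_means key {gene!r} not in the gene universe")

    @property
    def universe(self) -> tuple[str, ...]:
        if self.gene_ids is not None:
            return self.gene_ids
        return tuple(f"G{i:04d}" for i in range(1, self.n_genes + 1))


@dataclass
class GoldStandard:
    """Planted truth: per-gene log2FC and expected sentinel flux directions."""

    gene_log2fc: pd.Series
    reaction_directions: dict[str, str]


def _sample_ids(design: SyntheticDesign) -> tuple[list[str], pd.Series, pd.Series]:
    samples, groups, patients = [], {}, {}
    for group in (LESION, CONTROL):
        for p in range(1, design.n_pairs + 1):
            sid = f"P{p:02d}_{group}"
            samples.append(sid)
            groups[sid] = group
            patients[sid] = f"P{p:02d}"
    return samples, pd.Series(groups), pd.Series(patients)


def gene_lengths(design: SyntheticDesign) -> pd.Series:
    """Log-uniform gene lengths (nt), deterministic for a fixed seed."""
    ss = np.random.SeedSequence(design.seed)
    rng = np.random.default_rng(ss.spawn(3)[0])
    lo, hi = design.length_range
    lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), design.n_genes))
    return pd.Series(np.round(lengths), index=list(design.universe), name="length")


def generate_counts(design: SyntheticDesign) -> ExpressionMatrix:
    """Draw the cohort's count matrix (genes x 2*n_pairs samples).

    Counts are NB(mean = mu, variance = mu + dispersion * mu^2) with
    mu = gene mean x patient depth factor x planted fold (lesion only).
    The Poisson limit is used when dispersion ~ 0.
    """
    ss = np.random.SeedSequence(design.seed)
    _, s_pat, s_counts = ss.spawn(3)[0:3]
    samples, groups, patients = _sample_ids(design)
    genes = list(design.universe)

    base = np.full(design.n_genes, design.nb_mean)
    gene_index = {g: i for i, g in enumerate(genes)}
    for gene, mean in design.gene_means.items():
        base[gene_index[gene]] = mean

    rng_pat = np.random.default_rng(s_pat)
    depth = (
        rng_pat.lognormal(0.0, design.patient_effect_sd, design.n_pairs)
        if design.patient_effect_sd > 0
        else np.ones(design.n_pairs)
    )
    depth_by_patient = {f"P{p:02d}": depth[p - 1] for p in range(1, design.n_pairs + 1)}

    mu = np.empty((design.n_genes, len(samples)))
    for s, sid in enumerate(samples):
        col = base * depth_by_patient[patients[sid]]
        if groups[sid] == LESION:
            col = col.copy()
            for gene, fold in design.planted_effects.items():
                col[gene_index[gene]] *= fold
        mu[:, s] = col

    rng = np.random.default_rng(s_counts)
    if design.nb_dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / design.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    values = pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples)
    return ExpressionMatrix(
        values, "counts", groups, patients, gene_lengths(design)
    )


def make_gold_standard(
    design: SyntheticDesign, model: MetabolicModel
) -> GoldStandard:
    """Expected outcomes implied by the planted effects and the GPR rules.

    A reaction whose sole gating gene carries a planted knockdown is
    expected "down"; an upregulation, "up"; everything else "none".
    """
    lfc = pd.Series(0.0, index=list(design.universe), name="true_log2fc")
    for gene, fold in design.planted_effects.items():
        lfc[gene] = math.log2(fold)
    directions: dict[str, str] = {}
    for rxn in model.reactions:
        rxn_genes = rxn.gpr.genes()
        direction = "none"
        if len(rxn_genes) == 1:
            (gene,) = rxn_genes
            fold = design.planted_effects.get(gene)
            if fold is not None and fold != 1.0:
                direction = "up" if fold > 1.0 else "down"
        directions[rxn.id] = direction
    return GoldStandard(gene_log2fc=lfc, reaction_directions=directions)


def make_demo_design(
    model: MetabolicModel,
    seed: int = 0,
    n_genes: int = 200,
    planted_effects: Mapping[str, float] | None = None,
    nb_mean: float = 100.0,
    nb_dispersion: float = 0.05,
    patient_effect_sd: float = 0.2,
    n_pairs: int = 7,
) -> SyntheticDesign:
    """The bundled study conditions: 7 paired samples, planted sentinel effects.

    The gene universe is the model's genes plus filler genes; the two anchor
    enzymes are given housekeeping-level means so the percentile normalizer
    of the flux bounds is stable across samples.
    """
    model_genes = sorted(model.genes)
    if n_genes < len(model_genes):
        raise ValueError("n_genes smaller than the model's gene count")
    fillers = [f"G{i:04d}" for i in range(1, n_genes - len(model_genes) + 1)]
    gene_ids = tuple(model_genes + fillers)
    planted = dict(
        DEMO_PLANTED_EFFECTS if planted_effects is None else planted_effects
    )
    gene_means = {g: m for g, m in ANCHOR_GENE_MEANS.items() if g in set(gene_ids)}
    return SyntheticDesign(
        n_pairs=n_pairs,
        n_genes=n_genes,
        nb_mean=nb_mean,
        nb_dispersion=nb_dispersion,
        planted_effects=planted,
        patient_effect_sd=patient_effect_sd,
        seed=seed,
        gene_ids=gene_ids,
        gene_means=gene_means,
    )


def make_cluster_profiles(
    n_genes: int = 60,
    n_clusters: int = 3,
    n_features: int = 7,
    separation: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted-cluster log2FC-like profiles (genes x features) plus labels.

    Each cluster's center is a distinct sign pattern across features (a
    shared per-patient response shape), scaled to ``separation`` noise-SD
    units per feature, with unit Gaussian noise on top.  Pattern-based
    centers (rather than constant offsets) are used because co-expression
    similarity lives in the response shape: a constant per-gene offset is
    removed by the median centering that consensus clustering applies.
    Gene counts are split as evenly as possible across clusters.
    """
    if n_clusters < 2 or n_genes <= n_clusters:
        raise ValueError("need n_genes > n_clusters >= 2")
    rng = np.random.default_rng(seed)
    sizes = [n_genes // n_clusters] * n_clusters
    for i in range(n_genes % n_clusters):
        sizes[i] += 1
    labels = np.repeat(np.arange(n_clusters), sizes)
    features = np.arange(n_features)
    # cluster c is "down" (-separation) on features j with j % k == c,
    # "up" (+separation) elsewhere; any two centers differ on ~2f/k features
    patterns = np.where(
        (features[None, :] % n_clusters) == np.arange(n_clusters)[:, None],
        -separation,
        separation,
    )
    profiles = rng.standard_normal((n_genes, n_features)) + patterns[labels]
    genes = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    cols = [f"pt{j}" for j in range(1, n_features + 1)]
    return (
        pd.DataFrame(profiles, index=genes, columns=cols),
        pd.Series(labels, index=genes, name="cluster"),
    )


def write_cohort(
    counts: ExpressionMatrix,
    outdir: str | Path,
    gold: GoldStandard | None = None,
) -> dict[str, Path]:
    """Write counts, sample sheet, lengths and (optionally) the answer key."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["counts"] = outdir / "counts.tsv"
    counts.values.rename_axis("gene").to_csv(paths["counts"], sep="\t")
    sheet = pd.DataFrame(
        {
            "sample": counts.samples,
            "patient": counts.patients.to_numpy()
            if counts.patients is not None
            else "",
            "group": counts.groups.to_numpy(),
        }
    )
    paths["samples"] = outdir / "samples.tsv"
    sheet.to_csv(paths["samples"], sep="\t", index=False)
    if counts.lengths is not None:
        paths["lengths"] = outdir / "lengths.tsv"
        counts.lengths.rename_axis("gene").to_frame().to_csv(
            paths["lengths"], sep="\t"
        )
    if gold is not None:
        paths["gold_genes"] = outdir / "gold_gene_log2fc.tsv"
        gold.gene_log2fc.rename_axis("gene").to_frame().to_csv(
            paths["gold_genes"], sep="\t"
        )
        paths["gold_reactions"] = outdir / "gold_reaction_directions.tsv"
        pd.Series(gold.reaction_directions, name="direction").rename_axis(
            "reaction"
        ).to_frame().to_csv(paths["gold_reactions"], sep="\t")
    return paths
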