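"""Synthetic multi-tissue, multi-population cohorts with full ground truth.

The generator emulates the structure of a donor-biobank transcriptome cohort:
individuals drawn from labelled populations carry a structural-variant allele
at a stated frequency under Hardy–Weinberg sampling, contribute one RNA-seq
sample per tissue, express a linked fusion transcript with a per-sample
penetrance when they carry the variant — plus a low, genotype-independent
background rate standing in for trans-splicing — and accumulate clinical
phenotype codes under a logistic model with optional planted genotype
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Population",
    "ChimeraSpec",
    "CohortTruth",
    "sample_cohort",
    "attach_samples",
    "simulate_chimera_table",
    "simulate_phenotypes",
    "DEFAULT_TISSUES",
]

DEFAULT_TISSUES = tuple(f"tissue_{i:02d}" for i in range(30))


@dataclass(frozen=True)
class Population:
    label: str
    allele_frequency: float
    n: int

    def validate(self) -> None:
        if not (0.0 <= self.allele_frequency <= 1.0):
            raise ValueError(f"{self.label}: allele frequency must be in [0,1]")
        if self.n < 0:
            raise ValueError(f"{self.label}: n must be non-negative")


@dataclass(frozen=True)
class ChimeraSpec:
    """Generative parameters for one chimeric RNA in the prediction table.

    ``carrier_expression_prob`` is the per-sample penetrance in variant
    carriers (genotype ≥ 1); ``background_prob`` the genotype-independent
    per-sample rate.  A ubiquitous (non-polymorphic) chimera is modelled by
    setting both probabilities equal.  ``score_range``/``identity_range``
    bound the uniform confidence-score and annotated-transcript-identity
    draws attached to each emitted row.
    """

    chimera_id: str
    gene5: str = "GENE5"
    gene3: str = "GENE3"
    chrom5: str = "chrT"
    pos5: int = 10_000
    strand5: str = "+"
    chrom3: str = "chrT"
    pos3: int = 30_000
    strand3: str = "-"
    carrier_expression_prob: float = 0.9
    background_prob: float = 0.005
    score_range: tuple[float, float] = (0.7, 0.99)
    identity_range: tuple[float, float] = (0.3, 0.8)

    def validate(self) -> None:
        for p in (self.carrier_expression_prob, self.background_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0,1]")


@dataclass
class CohortTruth:
    """Simulator ground truth for a cohort.

    ``individuals``: individual_id, population, genotype (0/1/2).
    ``samples``: sample_id, individual_id, tissue.
    ``expression_truth``: sample_id × chimera_id boolean occurrence.
    ``phenotype_truth``: planted (code, model, odds_ratio) effects.
    """

    individuals: pd.DataFrame
    samples: pd.DataFrame | None = None
    expression_truth: pd.DataFrame | None = None
    phenotype_truth: list = field(default_factory=list)

    def carriers(self) -> pd.Series:
        return self.individuals.set_index("individual_id")["genotype"] > 0


def sample_cohort(populations, seed: int = 0) -> CohortTruth:
    """Draw per-individual genotypes as Binomial(2, population frequency)."""
    rng = np.random.default_rng(seed)
    rows = []
    for pop in populations:
        pop = pop if isinstance(pop, Population) else Population(*pop)
        pop.validate()
        genotypes = rng.binomial(2, pop.allele_frequency, size=pop.n)
        for i, g in enumerate(genotypes):
            rows.append((f"{pop.label}_{i:05d}", pop.label, int(g)))
    individuals = pd.DataFrame(rows, columns=["individual_id", "population", "genotype"])
    return CohortTruth(individuals=individuals)


def attach_samples(
    cohort: CohortTruth,
    tissues=DEFAULT_TISSUES,
    samples_per_individual: int | None = None,
    seed: int = 0,
) -> CohortTruth:
    """Give every individual one sample per tissue (or a random subset)."""
    rng = np.random.default_rng(seed)
    tissues = list(tissues)
    rows = []
    for ind in cohort.individuals["individual_id"]:
        if samples_per_individual is None or samples_per_individual >= len(tissues):
            chosen = tissues
        else:
            chosen = [tissues[j] for j in rng.choice(len(tissues), samples_per_individual, replace=False)]
        for t in chosen:
            rows.append((f"{ind}_{t}", ind, t))
    cohort.samples = pd.DataFrame(rows, columns=["sample_id", "individual_id", "tissue"])
    return cohort


OCCURRENCE_COLUMNS = [
    "chimera_id", "gene5", "gene3", "chrom5", "pos5", "strand5",
    "chrom3", "pos3", "strand3", "score", "identity",
    "sample_id", "individual_id", "tissue",
]


def simulate_chimera_table(
    cohort: CohortTruth, chimeras, seed: int = 0
) -> pd.DataFrame:
    """Emit a chimeric-RNA prediction table over the cohort's samples.

    For each chimera, a carrier sample expresses it with the spec's
    ``carrier_expression_prob`` and any sample with ``background_prob``
    (a sample expressing through both routes yields one row).  Truth is
    recorded on ``cohort.expression_truth``.
    """
    if cohort.samples is None:
        raise ValueError("cohort has no samples; call attach_samples first")
    rng = np.random.default_rng(seed)
    samples = cohort.samples
    genotype = cohort.individuals.set_index("individual_id")["genotype"]
    is_carrier = (genotype.reindex(samples["individual_id"]) > 0).to_numpy()
    n = len(samples)

    frames = []
    truth_cols = {}
    for spec in chimeras:
        spec.validate()
        p = np.where(is_carrier,
                     1 - (1 - spec.carrier_expression_prob) * (1 - spec.background_prob),
                     spec.background_prob)
        expressed = rng.random(n) < p
        truth_cols[spec.chimera_id] = expressed
        idx = np.nonzero(expressed)[0]
        part = samples.iloc[idx][["sample_id", "individual_id", "tissue"]].reset_index(drop=True)
        part.insert(0, "chimera_id", spec.chimera_id)
        for col, val in (("gene5", spec.gene5), ("gene3", spec.gene3),
                         ("chrom5", spec.chrom5), ("pos5", spec.pos5),
                         ("strand5", spec.strand5), ("chrom3", spec.chrom3),
                         ("pos3", spec.pos3), ("strand3", spec.strand3)):
            part[col] = val
        part["score"] = np.round(rng.uniform(*spec.score_range, size=len(idx)), 4)
        part["identity"] = np.round(rng.uniform(*spec.identity_range, size=len(idx)), 4)
        frames.append(part[OCCURRENCE_COLUMNS])
    truth = pd.DataFrame(truth_cols, index=samples["sample_id"])
    cohort.expression_truth = truth
    if not frames:
        return pd.DataFrame(columns=OCCURRENCE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def simulate_phenotypes(
    cohort: CohortTruth,
    codes,
    baseline_prevalences,
    planted=None,
    n_pcs: int = 5,
    pc_shift: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate clinical codes and covariates for every individual.

    Code presence follows ``logit(p) = logit(prevalence) + ln(OR)·g`` where
    ``g`` is carrier status (dominant coding) or allele count (additive),
    per the planted effect's model.  ``planted`` is an iterable of
    ``(code, odds_ratio)`` or ``(code, odds_ratio, model)`` tuples.

    Covariates: age ~ Uniform(20, 80) years, sex ~ Bernoulli(0.5), and
    ``n_pcs`` ancestry PCs drawn standard normal around a per-population
    mean shift on PC1.

    Returns ``(phenotype long table, covariate table)``.
    """
    rng = np.random.default_rng(seed)
    individuals = cohort.individuals
    n = len(individuals)
    g = individuals["genotype"].to_numpy()

    codes = list(codes)
    prevalences = np.broadcast_to(np.asarray(baseline_prevalences, dtype=float), (len(codes),))
    effects = {}
    for item in planted or []:
        code, oratio, *rest = item
        model = rest[0] if rest else "dominant"
        if oratio <= 0:
            raise ValueError("odds ratios must be positive")
        effects[code] = (float(np.log(oratio)), model)
    cohort.phenotype_truth = [(c, float(np.exp(b)), m) for c, (b, m) in effects.items()]

    pheno_rows = []
    with np.errstate(divide="ignore"):
        for code, prev in zip(codes, prevalences):
            if prev <= 0:
                continue
            beta0 = np.log(prev / (1 - prev))
            beta_g, model = effects.get(code, (0.0, "dominant"))
            dose = (g > 0).astype(float) if model == "dominant" else g.astype(float)
            p = 1.0 / (1.0 + np.exp(-(beta0 + beta_g * dose)))
            present = rng.random(n) < p
            for ind in individuals.loc[present, "individual_id"]:
                pheno_rows.append((ind, code, True))
    phenotypes = pd.DataFrame(pheno_rows, columns=["individual_id", "code", "present"])

    pop_labels = individuals["population"].to_numpy()
    pop_index = {label: i for i, label in enumerate(pd.unique(pop_labels))}
    shift = np.array([pop_index[p] for p in pop_labels], dtype=float) * pc_shift
    pcs = rng.normal(size=(n, n_pcs))
    pcs[:, 0] += shift
    covariates = pd.DataFrame({
        "individual_id": individuals["individual_id"],
        "age": np.round(rng.uniform(20, 80, size=n)).astype(int),
        "sex": np.where(rng.random(n) < 0.5, "M", "F"),
        "ancestry": pop_labels,
    })
    for k in range(n_pcs):
        covariates[f"PC{k + 1}"] = pcs[:, k]
    return phenotypes, covariates
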