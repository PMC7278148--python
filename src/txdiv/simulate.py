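"""Synthetic two-subspecies genotype and expression panels.

The generator emulates the statistical structure of a population-level rice
transcriptome study: two divergent subpopulations of inbred accessions
(Balding-Nichols allele frequencies), replicate-level negative-binomial read
counts, and gene architectures covering differential expression,
presence-absence expression variation, polygenic heritability, and
subspecies-specific or shared cis-eQTL, plus low-diversity ("swept")
windows for selection-scan fixtures.

Default panel sizes mirror the study design the pipeline targets: 35 Indica
and 56 Japonica accessions with two biological replicates each.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CountTable, Dataset, GeneTable, GenotypeTable, SampleTable

logger = logging.getLogger(__name__)

POPS = ("I", "J")
GENE_CLASSES = ("null", "de", "pav", "heritable", "eqtl_I", "eqtl_J", "eqtl_both")

__all__ = [
    "SimulationConfig",
    "GeneArchitecture",
    "simulate_genotypes",
    "inject_sweep",
    "simulate_architecture",
    "simulate_counts",
    "simulate_dataset",
    "architectures_to_frame",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic panel.

    ``fst_per_pop`` is the Balding-Nichols divergence parameter F per
    subpopulation; rice Indica/Japonica are strongly differentiated, so the
    default is 0.4 for both. ``nb_dispersion`` is the negative-binomial
    dispersion phi with Var = mu + mu^2/phi (phi=inf -> Poisson).
    ``architecture_mix`` gives the proportion of genes in each class.
    """

    n_accessions_per_pop: tuple = (35, 56)
    n_replicates: int = 2
    n_snps: int = 20_000
    n_genes: int = 1_000
    chromosome_lengths: dict = field(
        default_factory=lambda: {f"chr{i}": 8_000_000 for i in range(1, 6)}
    )
    fst_per_pop: tuple = (0.4, 0.4)
    # nested substructure: each subspecies splits into subpopulations
    # (rice panels do: temperate/tropical japonica, indica subgroups, ...)
    n_subpops_per_pop: int = 3
    fst_subpop: float = 0.15
    nb_dispersion: float = 10.0
    size_factor_range: tuple = (0.7, 1.4)
    architecture_mix: dict = field(
        default_factory=lambda: {
            "null": 0.40,
            "de": 0.15,
            "pav": 0.10,
            "heritable": 0.15,
            "eqtl_I": 0.05,
            "eqtl_J": 0.05,
            "eqtl_both": 0.10,
        }
    )
    sweep_regions: list = field(default_factory=list)
    seed: int = 0

    # effect-size defaults (log-e scale unless noted)
    de_shift: float = 1.0
    pav_logit_shift: float = 1.7
    target_h2: float = 0.5
    cis_h2: float = 0.4
    accession_var: float = 0.25  # total accession-level (genetic+env) log variance
    cis_window: int = 100_000
    baseline_log_mean: tuple = (5.0, 1.0)  # mean, sd of b0 draws

    def __post_init__(self):
        if abs(sum(self.architecture_mix.values()) - 1.0) > 1e-9:
            raise ValueError("architecture_mix proportions must sum to 1")
        unknown = set(self.architecture_mix) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {unknown}")
        if any(n <= 0 for n in self.n_accessions_per_pop):
            raise ValueError("accession counts must be positive")
        if min(self.n_snps, self.n_genes, self.n_replicates) <= 0:
            raise ValueError("counts must be positive")
        for f in self.fst_per_pop:
            if not 0.0 < f < 1.0:
                raise ValueError("F must be in the open interval (0, 1)")
        if any(L <= 0 for L in self.chromosome_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be positive")

    def pop_labels(self) -> np.ndarray:
        """Subspecies label per accession, pop I first."""
        nI, nJ = self.n_accessions_per_pop
        return np.array(["I"] * nI + ["J"] * nJ)

    def accession_ids(self) -> list:
        nI, nJ = self.n_accessions_per_pop
        return [f"accI{i:03d}" for i in range(nI)] + [f"accJ{i:03d}" for i in range(nJ)]


@dataclass
class GeneArchitecture:
    """Ground-truth generative architecture of one gene."""

    gene_id: str
    gene_class: str
    baseline_log_mean: float
    de_shift: float = 0.0
    pav_logit_shift: float = 0.0
    target_h2: float = 0.0
    cis_snp_id: str | None = None
    cis_effect: float = 0.0
    cis_active: tuple = (False, False)  # (active in I, active in J)
    # accession-level latent values, aligned to config accession order
    genetic_value: np.ndarray | None = None
    env_value: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.target_h2 < 1.0:
            raise ValueError("target_h2 must be in [0, 1)")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if not self.gene_class.startswith("eqtl") and self.cis_snp_id is not None:
            raise ValueError("cis fields only valid for eQTL classes")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_genotypes(config: SimulationConfig) -> GenotypeTable:
    """Draw inbred haploid genotypes under the Balding-Nichols model.

    Ancestral frequency p ~ U(0.05, 0.95); per-population frequency
    p_k ~ Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k); accession allele ~
    Bernoulli(p_k). SNPs are placed uniformly over the chromosomes
    (probability proportional to length) and sorted.
    """
    rng = _rng(config, 1)
    chroms = list(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    n_per = rng.multinomial(config.n_snps, lengths / lengths.sum())

    recs = []
    for c, L, k in zip(chroms, lengths.astype(int), n_per):
        k = min(k, L)  # cannot place more unique positions than bases
        pos = np.sort(rng.choice(L, size=k, replace=False) + 1)
        for p in pos:
            recs.append((f"{c}_{p}", c, int(p)))
    snps = pd.DataFrame(recs, columns=["snp_id", "chrom", "pos"])
    m = len(snps)
    ref_alt = rng.choice(list("ACGT"), size=(m, 2))
    same = ref_alt[:, 0] == ref_alt[:, 1]
    ref_alt[same, 1] = np.where(ref_alt[same, 0] == "A", "G", "A")
    snps["ref"], snps["alt"] = ref_alt[:, 0], ref_alt[:, 1]

    p_anc = rng.uniform(0.05, 0.95, size=m)
    blocks = []
    for n_k, F in zip(config.n_accessions_per_pop, config.fst_per_pop):
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_k = rng.beta(a, b)
        # nested subpopulations drift around the subspecies frequency
        n_sub = max(config.n_subpops_per_pop, 1)
        Fs = config.fst_subpop
        sub_sizes = np.full(n_sub, n_k // n_sub)
        sub_sizes[: n_k % n_sub] += 1
        for size in sub_sizes:
            if n_sub > 1 and Fs > 0:
                pc = np.clip(p_k, 1e-6, 1 - 1e-6)
                p_s = rng.beta(pc * (1 - Fs) / Fs, (1 - pc) * (1 - Fs) / Fs)
            else:
                p_s = p_k
            blocks.append((rng.random((size, m)) < p_s).astype(float))
    dosages = np.vstack(blocks)
    return GenotypeTable(config.accession_ids(), snps, dosages)


def inject_sweep(
    genotypes: GenotypeTable, regions, pop_labels: np.ndarray
) -> GenotypeTable:
    """Near-fix alleles in the target population inside each region.

    ``regions`` is a list of (chrom, start, end, target_pop) closed
    intervals. Inside a region, the target population's dosages are
    overwritten with that population's major allele, keeping at most one
    copy of the minor allele; other populations are untouched.
    """
    dosages = genotypes.dosages.copy()
    snps = genotypes.snps
    for chrom, start, end, target in regions:
        in_win = (snps["chrom"] == chrom) & (snps["pos"] >= start) & (snps["pos"] <= end)
        idx = np.flatnonzero(in_win.to_numpy())
        if idx.size == 0:
            warnings.warn(f"sweep region {chrom}:{start}-{end} contains no SNPs")
            continue
        rows = np.flatnonzero(pop_labels == target)
        for j in idx:
            col = dosages[np.ix_(rows, [j])].ravel()
            obs = ~np.isnan(col)
            if obs.sum() == 0:
                continue
            major = 1.0 if np.nansum(col) * 2 >= obs.sum() else 0.0
            carriers = np.flatnonzero(obs & (col != major))
            col[obs] = major
            if carriers.size:
                col[carriers[0]] = 1.0 - major  # leave one minor-allele copy
            dosages[rows, j] = col
    return GenotypeTable(genotypes.accessions, snps.reset_index(drop=True), dosages)


def simulate_gene_table(config: SimulationConfig) -> GeneTable:
    """Place genes uniformly; TSS uniform over chromosome lengths."""
    rng = _rng(config, 2)
    chroms = list(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    n_per = rng.multinomial(config.n_genes, lengths / lengths.sum())
    recs, g = [], 0
    for c, L, k in zip(chroms, lengths.astype(int), n_per):
        for p in np.sort(rng.integers(1, L + 1, size=k)):
            recs.append((f"g{g:05d}", c, int(p), rng.choice(["+", "-"])))
            g += 1
    return GeneTable(pd.DataFrame(recs, columns=["gene_id", "chrom", "tss", "strand"]))


def _scaled_effects(x: np.ndarray, betas: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale betas so Var(x @ betas) over accessions equals target_var."""
    g = x @ betas
    v = g.var()
    if v <= 0:
        return np.zeros_like(betas)
    return betas * np.sqrt(target_var / v)


def simulate_architecture(
    config: SimulationConfig, genotypes: GenotypeTable, gene_table: GeneTable
) -> list:
    """Assign a generative class and latent accession values to every gene.

    Heritable genes get a polygenic value from a random SNP subset, rescaled
    so its accession variance is ``target_h2`` times the total accession
    variance ``accession_var`` (the remainder is a non-genetic accession
    effect, so realized heritability matches the target). eQTL genes get a
    single cis effect (variance share ``cis_h2``) active in one or both
    subspecies; genes with no polymorphic cis SNP in the required
    subspecies are reassigned to the heritable class.
    """
    rng = _rng(config, 3)
    labels = config.pop_labels()
    n_acc = len(labels)
    mask_I, mask_J = labels == "I", labels == "J"
    classes = list(config.architecture_mix)
    probs = np.array([config.architecture_mix[c] for c in classes])
    draw = rng.choice(len(classes), size=len(gene_table.table), p=probs)

    V = config.accession_var
    snp_chrom = genotypes.snps["chrom"].to_numpy()
    snp_pos = genotypes.snps["pos"].to_numpy()
    maf_I = genotypes.maf(rows=np.flatnonzero(mask_I))
    maf_J = genotypes.maf(rows=np.flatnonzero(mask_J))

    archs = []
    for rec, ci in zip(gene_table.table.itertuples(index=False), draw):
        cls = classes[ci]
        b0 = rng.normal(*config.baseline_log_mean)
        de = pav = 0.0
        h2 = 0.0
        cis_snp = None
        cis_eff = 0.0
        active = (False, False)
        genetic = np.zeros(n_acc)

        if cls == "de":
            de = config.de_shift * rng.choice([-1.0, 1.0])
        elif cls == "pav":
            pav = config.pav_logit_shift * rng.choice([-1.0, 1.0])
        if cls in ("heritable", "eqtl_I", "eqtl_J", "eqtl_both"):
            h2 = config.target_h2 if cls == "heritable" else config.cis_h2
        if cls.startswith("eqtl"):
            need_I = cls in ("eqtl_I", "eqtl_both")
            need_J = cls in ("eqtl_J", "eqtl_both")
            near = (snp_chrom == rec.chrom) & (
                np.abs(snp_pos - rec.tss) <= config.cis_window
            )
            usable = near.copy()
            if need_I:
                usable &= maf_I >= 0.1
            if need_J:
                usable &= maf_J >= 0.1
            cand = np.flatnonzero(usable)
            if cand.size == 0:
                logger.info(
                    "gene %s: no usable cis SNP for class %s; reassigned to heritable",
                    rec.gene_id, cls,
                )
                cls, h2 = "heritable", config.target_h2
            else:
                j = int(rng.choice(cand))
                cis_snp = genotypes.snps["snp_id"].iloc[j]
                x = np.nan_to_num(genotypes.dosages[:, j], nan=0.5)
                act = np.zeros(n_acc)
                if need_I:
                    act[mask_I] = 1.0
                if need_J:
                    act[mask_J] = 1.0
                xa = (x - x.mean()) * act
                beta = _scaled_effects(xa[:, None], np.ones(1), h2 * V)[0]
                cis_eff = float(beta)
                genetic = xa * beta
                active = (need_I, need_J)
        if cls == "heritable":
            k = min(50, genotypes.n_snps)
            cols = rng.choice(genotypes.n_snps, size=k, replace=False)
            X = np.nan_to_num(genotypes.dosages[:, cols], nan=0.5)
            X = X - X.mean(axis=0)
            betas = _scaled_effects(X, rng.normal(size=k), h2 * V)
            genetic = X @ betas

        env_sd = np.sqrt(max(V - genetic.var(), 0.0)) if h2 > 0 else 0.0
        env = rng.normal(0.0, env_sd, size=n_acc) if env_sd > 0 else np.zeros(n_acc)
        if cls in ("eqtl_I", "eqtl_J"):
            # subspecies-specific genes vary at the accession level only in
            # the active subspecies; elsewhere variation is replicate noise
            env = env * (mask_I if cls == "eqtl_I" else mask_J).astype(float)
        archs.append(
            GeneArchitecture(
                gene_id=rec.gene_id,
                gene_class=cls,
                baseline_log_mean=float(b0),
                de_shift=float(de),
                pav_logit_shift=float(pav),
                target_h2=float(h2),
                cis_snp_id=cis_snp,
                cis_effect=cis_eff,
                cis_active=active,
                genetic_value=genetic,
                env_value=env,
            )
        )
    return archs


def simulate_counts(
    genotypes: GenotypeTable, architectures: list, config: SimulationConfig
) -> tuple[CountTable, SampleTable]:
    """Draw replicate-level negative-binomial read counts.

    count_gij ~ NB(mean = s_j * exp(b0 + genetic_i + env_i + de_shift*S_i),
    dispersion phi). PAV genes first draw an accession on/off state from a
    logistic model with the subspecies shift; the off state draws
    Poisson(0.1) background counts.
    """
    rng = _rng(config, 4)
    labels = config.pop_labels()
    n_acc = len(labels)
    r = config.n_replicates
    acc_ids = config.accession_ids()
    sample_ids = [f"{a}_r{k+1}" for a in acc_ids for k in range(r)]
    size_factors = rng.uniform(*config.size_factor_range, size=n_acc * r)
    s_is_J = np.repeat(labels == "J", r).astype(float)
    phi = config.nb_dispersion

    counts = np.empty((len(architectures), n_acc * r), dtype=np.int64)
    for gi, arch in enumerate(architectures):
        # de_shift > 0 raises expression in Japonica (sign convention: J - I)
        eta = arch.baseline_log_mean + arch.genetic_value + arch.env_value
        mu = np.repeat(np.exp(eta), r) * size_factors * np.exp(arch.de_shift * s_is_J)
        if not np.all(np.isfinite(mu)):
            raise ValueError(f"non-finite count mean for gene {arch.gene_id}")
        if arch.gene_class == "pav":
            logit = 0.0 + arch.pav_logit_shift * (labels == "J").astype(float)
            p_on = 1.0 / (1.0 + np.exp(-(logit + rng.normal(0, 0.5, size=n_acc))))
            on = np.repeat(rng.random(n_acc) < p_on, r)
            row = np.where(
                on,
                _nb_draw(rng, mu, phi),
                rng.poisson(0.1, size=mu.size),
            )
        else:
            row = _nb_draw(rng, mu, phi)
        counts[gi] = row

    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "accession_id": np.repeat(acc_ids, r),
                "replicate": np.tile(np.arange(1, r + 1), n_acc),
                "subspecies": np.repeat(labels, r),
            }
        )
    )
    table = CountTable([a.gene_id for a in architectures], sample_ids, counts)
    return table, samples


def _nb_draw(rng, mu, phi):
    if np.isinf(phi):
        return rng.poisson(mu)
    # NB with mean mu, Var = mu + mu^2/phi  <=>  n=phi, p=phi/(phi+mu)
    return rng.negative_binomial(phi, phi / (phi + mu))


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, list]:
    """Run the full generator; returns the dataset and the ground truth."""
    genotypes = simulate_genotypes(config)
    if config.sweep_regions:
        genotypes = inject_sweep(genotypes, config.sweep_regions, config.pop_labels())
    gene_table = simulate_gene_table(config)
    archs = simulate_architecture(config, genotypes, gene_table)
    counts, samples = simulate_counts(genotypes, archs, config)
    return Dataset(genotypes, counts, gene_table, samples), archs


def architectures_to_frame(archs: list) -> pd.DataFrame:
    """Flatten ground-truth architectures for truth.tsv export."""
    return pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in archs],
            "gene_class": [a.gene_class for a in archs],
            "baseline_log_mean": [a.baseline_log_mean for a in archs],
            "de_shift": [a.de_shift for a in archs],
            "pav_logit_shift": [a.pav_logit_shift for a in archs],
            "target_h2": [a.target_h2 for a in archs],
            "cis_snp_id": [a.cis_snp_id for a in archs],
            "cis_effect": [a.cis_effect for a in archs],
            "cis_active_I": [a.cis_active[0] for a in archs],
            "cis_active_J": [a.cis_active[1] for a in archs],
        }
    )
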