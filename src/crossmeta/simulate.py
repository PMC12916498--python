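"""Synthetic GWAS data with known ground truth.

The simulator emulates the statistical structure the downstream analysis
assumes: LD-block genotypes, overlapping case/control cohorts, multiple
traits with shared, discordant and trait-specific causal variants under a
liability-threshold model, score-test summary statistics, expression
matrices with planted column shifts, and internally consistent annotation
lookup tables (gene intervals, eQTLs, chromatin loops, pathways, families,
interactions, trait classes, known loci).

Haplotypes follow a first-order Markov chain within each LD block: allele
``j+1`` copies allele ``j`` with probability ``block_rho`` and is otherwise
a fresh Bernoulli draw at the block's allele frequency.  This gives
haplotype (and genotype) correlation exactly ``rho**d`` at distance ``d``
— an AR(1) LD profile — while preserving the marginal frequency, which a
Gaussian-copula construction would not (thresholding attenuates binary
correlations).  One frequency is drawn per block so the copy step keeps
marginals exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from crossmeta.errors import ConfigError
from crossmeta.sumstats import z_to_p

ROLE_NULL = "null"
ROLE_SHARED = "shared"
ROLE_DISCORDANT = "discordant"
ROLE_SPECIFIC = "specific"


@dataclass
class SimConfig:
    """Parameters of one simulated study collection.

    ``cohort_sizes[s]`` is the number of individuals in study ``s`` and
    ``study_traits[s]`` the trait it measures (default: one study per
    trait).  ``overlap_matrix[s, t]`` is the number of individuals shared
    between studies ``s`` and ``t``; shared individuals are realized as
    dedicated pair-specific index sets, which reproduces any feasible
    pairwise overlap spec exactly.
    """

    n_variants: int = 2000
    n_blocks: int = 100
    block_rho: float = 0.5
    #: when set, each block draws its own AR(1) parameter uniformly from
    #: this range (heterogeneous LD, as in real genomes); block_rho is
    #: then ignored.  Moment checks against a single rho use the scalar.
    block_rho_range: tuple[float, float] | None = None
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    n_traits: int = 4
    n_populations: int = 1
    cohort_sizes: tuple[int, ...] | None = None
    study_traits: tuple[int, ...] | None = None
    overlap_matrix: np.ndarray | None = None
    n_shared_causal: int = 20
    n_discordant_causal: int = 10
    n_specific_causal: int = 8
    effect_size_sd: float = 0.05
    prevalence: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.cohort_sizes is None:
            self.cohort_sizes = tuple([10_000] * self.n_traits)
        if self.study_traits is None:
            if len(self.cohort_sizes) % self.n_traits:
                raise ConfigError("cannot infer study_traits: give it explicitly")
            reps = len(self.cohort_sizes) // self.n_traits
            self.study_traits = tuple(
                t for t in range(self.n_traits) for _ in range(reps))
        n_studies = len(self.cohort_sizes)
        if self.overlap_matrix is None:
            self.overlap_matrix = np.zeros((n_studies, n_studies), dtype=int)
        self.overlap_matrix = np.asarray(self.overlap_matrix, dtype=int)
        self.validate()

    @property
    def n_studies(self) -> int:
        return len(self.cohort_sizes)

    def validate(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError(f"invalid allele frequency range ({lo}, {hi})")
        if not (0.0 <= self.block_rho < 1.0):
            raise ConfigError("block_rho must be in [0, 1)")
        if self.block_rho_range is not None:
            rlo, rhi = self.block_rho_range
            if not (0.0 <= rlo <= rhi < 1.0):
                raise ConfigError("block_rho_range must lie within [0, 1)")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigError("prevalence must be in (0, 1)")
        if self.n_variants % self.n_blocks:
            raise ConfigError("n_variants must be divisible by n_blocks")
        om = self.overlap_matrix
        n = self.n_studies
        if om.shape != (n, n):
            raise ConfigError("overlap_matrix shape does not match cohort count")
        if not np.array_equal(om, om.T) or np.any(np.diag(om) != 0):
            raise ConfigError("overlap_matrix must be symmetric with zero diagonal")
        for s in range(n):
            if om[s].sum() > self.cohort_sizes[s]:
                raise ConfigError(f"study {s}: overlaps exceed its cohort size")
            for t in range(n):
                if om[s, t] > min(self.cohort_sizes[s], self.cohort_sizes[t]):
                    raise ConfigError(
                        f"overlap ({s},{t}) exceeds the smaller cohort")
        if len(self.study_traits) != n:
            raise ConfigError("study_traits length must equal cohort count")
        n_causal = (self.n_shared_causal + self.n_discordant_causal
                    + self.n_specific_causal)
        if n_causal > self.n_variants:
            raise ConfigError("causal counts exceed n_variants")


@dataclass
class GenotypeMatrix:
    """Additive dosages (individuals x variants, values 0/1/2) plus metadata."""

    dosages: np.ndarray
    variants: pd.DataFrame  # SNP, CHR, BP, A1, A2, FRQ, BLOCK

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class TruthTable:
    """Planted causal architecture: per-variant role, effects and signs."""

    roles: np.ndarray          # str array, one of the ROLE_* values
    beta: np.ndarray           # n_variants x n_traits liability effects
    variants: pd.DataFrame = field(repr=False, default=None)

    @property
    def signs(self) -> np.ndarray:
        return np.sign(self.beta)

    def indices(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"ROLE": self.roles})
        for t in range(self.beta.shape[1]):
            out[f"BETA_{t}"] = self.beta[:, t]
            out[f"SIGN_{t}"] = np.sign(self.beta[:, t]).astype(int)
        if self.variants is not None:
            out.insert(0, "SNP", self.variants["SNP"].to_numpy())
        return out


def _simulate_haplotypes(n_hap, n_variants, n_blocks, rho, freqs, rng):
    """Markov-chain haplotypes: allele correlation rho**d within blocks.

    ``rho`` is a scalar or a per-variant vector (constant within blocks).
    """
    block_len = n_variants // n_blocks
    fresh = rng.random((n_hap, n_variants)) < freqs[np.newaxis, :]
    if block_len == 1 or (np.isscalar(rho) and rho == 0.0):
        # draw the copy mask anyway so the stream consumed per call does
        # not depend on rho (same-seed runs stay comparable)
        rng.random((n_hap, n_variants))
        return fresh.astype(np.int8)
    rho_vec = np.broadcast_to(rho, (n_variants,))
    copy = rng.random((n_hap, n_variants)) < rho_vec[np.newaxis, :]
    # blocks are independent: iterate over the within-block offset only
    hap = fresh.reshape(n_hap, n_blocks, block_len).astype(np.int8).copy()
    cp = copy.reshape(n_hap, n_blocks, block_len)
    for j in range(1, block_len):
        np.copyto(hap[:, :, j], hap[:, :, j - 1], where=cp[:, :, j])
    return hap.reshape(n_hap, n_variants)


def simulate_genotypes(cfg: SimConfig, n_individuals: int,
                       rng: np.random.Generator | None = None,
                       chrom: str = "1", id_prefix: str = "rs") -> GenotypeMatrix:
    """Draw diploid genotypes on one pseudo-chromosome.

    Variants are evenly spaced every 10 kb; each LD block draws one allele
    frequency uniformly from ``allele_freq_range``.  Deterministic given
    the generator state.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    block_len = cfg.n_variants // cfg.n_blocks
    lo, hi = cfg.allele_freq_range
    # block frequencies and LD strengths are population parameters: they
    # derive from the config seed alone, so cohorts and reference panels
    # drawn with different generators share one LD structure
    param_rng = np.random.default_rng(cfg.seed + 101)
    block_freqs = param_rng.uniform(lo, hi, size=cfg.n_blocks)
    freqs = np.repeat(block_freqs, block_len)
    if cfg.block_rho_range is not None:
        rlo, rhi = cfg.block_rho_range
        rho = np.repeat(param_rng.uniform(rlo, rhi, size=cfg.n_blocks),
                        block_len)
    else:
        rho = cfg.block_rho
    h1 = _simulate_haplotypes(n_individuals, cfg.n_variants, cfg.n_blocks,
                              rho, freqs, rng)
    h2 = _simulate_haplotypes(n_individuals, cfg.n_variants, cfg.n_blocks,
                              rho, freqs, rng)
    dosages = (h1 + h2).astype(np.int8)
    variants = pd.DataFrame({
        "SNP": [f"{id_prefix}{j + 1}" for j in range(cfg.n_variants)],
        "CHR": chrom,
        "BP": 10_000 * (np.arange(cfg.n_variants) + 1),
        "A1": "A",
        "A2": "G",
        "FRQ": freqs,
        "BLOCK": np.repeat(np.arange(cfg.n_blocks), block_len),
    })
    return GenotypeMatrix(dosages=dosages, variants=variants)


def simulate_truth(cfg: SimConfig, variants: pd.DataFrame | None = None,
                   rng: np.random.Generator | None = None) -> TruthTable:
    """Plant shared, discordant and trait-specific causal variants.

    Shared variants carry one liability effect, identical (size and sign)
    across all traits.  Discordant variants flip the sign for a random
    nonempty proper subset of traits.  Specific variants affect a single
    trait, assigned round-robin.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    roles = np.array([ROLE_NULL] * cfg.n_variants, dtype=object)
    beta = np.zeros((cfg.n_variants, cfg.n_traits))
    n_causal = (cfg.n_shared_causal + cfg.n_discordant_causal
                + cfg.n_specific_causal)
    causal = rng.choice(cfg.n_variants, size=n_causal, replace=False)
    shared = causal[:cfg.n_shared_causal]
    discordant = causal[cfg.n_shared_causal:
                        cfg.n_shared_causal + cfg.n_discordant_causal]
    specific = causal[cfg.n_shared_causal + cfg.n_discordant_causal:]
    roles[shared] = ROLE_SHARED
    roles[discordant] = ROLE_DISCORDANT
    roles[specific] = ROLE_SPECIFIC
    for j in shared:
        b = rng.normal(0.0, cfg.effect_size_sd)
        while b == 0.0:  # pragma: no cover - measure-zero
            b = rng.normal(0.0, cfg.effect_size_sd)
        beta[j, :] = b
    for j in discordant:
        b = rng.normal(0.0, cfg.effect_size_sd)
        n_flip = int(rng.integers(1, cfg.n_traits)) if cfg.n_traits > 1 else 0
        flip = rng.choice(cfg.n_traits, size=n_flip, replace=False)
        beta[j, :] = b
        beta[j, flip] = -b
    for k, j in enumerate(specific):
        t = k % cfg.n_traits
        beta[j, t] = rng.normal(0.0, cfg.effect_size_sd)
    return TruthTable(roles=roles, beta=beta, variants=variants)


def scale_heritability(truth: TruthTable, geno: GenotypeMatrix,
                       h2_by_role: dict[str, float]) -> TruthTable:
    """Rescale planted effects so each role carries an exact heritability.

    For every trait and every role named in ``h2_by_role``, the effects of
    that role's variants are multiplied by one factor so the empirical
    variance of their genetic score equals the target (roles are nearly
    uncorrelated, so contributions add).  Modifies ``truth`` in place and
    returns it.
    """
    freqs = geno.variants["FRQ"].to_numpy()
    n_traits = truth.beta.shape[1]
    for role, target in h2_by_role.items():
        idx = truth.indices(role)
        if idx.size == 0:
            continue
        g = geno.dosages[:, idx].astype(np.float64) - 2.0 * freqs[idx]
        for t in range(n_traits):
            b = truth.beta[idx, t]
            if not np.any(b):
                continue
            var_r = float(np.var(g @ b))
            truth.beta[idx, t] = b * np.sqrt(target / var_r)
    return truth


def simulate_correlated_pair(cfg: SimConfig, rho_effects: float,
                             h2: float, n_causal: int | None = None):
    """Two traits whose causal effects correlate at ``rho_effects``.

    Per causal variant, an effect pair is drawn from a bivariate normal
    with the given correlation; each trait is scaled to heritability
    ``h2`` and observed as a quantitative liability on its own disjoint
    cohort (so any Z-score correlation reflects genetics, not samples).
    Returns ``(sumstats_1, sumstats_2, panel, truth)`` — the recovery
    harness for genetic-correlation estimation.
    """
    rng = np.random.default_rng(cfg.seed)
    if n_causal is None:
        n_causal = cfg.n_shared_causal
    n1, n2 = (cfg.cohort_sizes + (cfg.cohort_sizes[-1],))[:2]
    geno = simulate_genotypes(cfg, n1 + n2, rng)
    causal = rng.choice(cfg.n_variants, size=n_causal, replace=False)
    cov = np.array([[1.0, rho_effects], [rho_effects, 1.0]])
    effects = rng.multivariate_normal([0.0, 0.0], cov, size=n_causal)
    beta = np.zeros((cfg.n_variants, 2))
    beta[causal] = cfg.effect_size_sd * effects
    roles = np.array([ROLE_NULL] * cfg.n_variants, dtype=object)
    same = np.sign(beta[causal, 0]) == np.sign(beta[causal, 1])
    roles[causal[same]] = ROLE_SHARED
    roles[causal[~same]] = ROLE_DISCORDANT
    truth = TruthTable(roles=roles, beta=beta, variants=geno.variants)
    freqs = geno.variants["FRQ"].to_numpy()
    g = geno.dosages[:, causal].astype(np.float64) - 2.0 * freqs[causal]
    liab = np.empty((n1 + n2, 2))
    for t in range(2):
        var_t = float(np.var(g @ beta[causal, t]))
        beta[causal, t] *= np.sqrt(h2 / var_t)
        score_t = g @ beta[causal, t]
        liab[:, t] = score_t + rng.normal(
            0.0, np.sqrt(1.0 - h2), size=n1 + n2)
    s1 = compute_sumstats(geno, liab[:, 0], np.arange(n1))
    s2 = compute_sumstats(geno, liab[:, 1], np.arange(n1, n1 + n2))
    panel_rng = np.random.default_rng(cfg.seed + 88)
    panel = simulate_genotypes(cfg, 1000, panel_rng)
    return s1, s2, panel, truth


def simulate_phenotypes(geno: GenotypeMatrix, truth: TruthTable,
                        cfg: SimConfig,
                        rng: np.random.Generator | None = None):
    """Liability-threshold case/control labels for every trait.

    Liability of trait ``t`` is the centered genetic score plus Gaussian
    noise scaled so the total liability variance is 1; an individual is a
    case iff liability exceeds the standard-normal ``1 - prevalence``
    quantile.  Returns ``(labels, liabilities)``, both individuals x
    traits; liabilities support quantitative-trait analyses.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    freqs = geno.variants["FRQ"].to_numpy()
    centered_mean = 2.0 * freqs
    n, m = geno.dosages.shape
    n_traits = truth.beta.shape[1]
    liab = np.empty((n, n_traits))
    for t in range(n_traits):
        b = truth.beta[:, t]
        nz = np.flatnonzero(b)
        g = geno.dosages[:, nz].astype(np.float64) - centered_mean[nz]
        score = g @ b[nz]
        var_g = float(np.var(score))
        if var_g >= 1.0:
            raise ConfigError(
                f"trait {t}: genetic liability variance {var_g:.3f} >= 1")
        liab[:, t] = score + rng.normal(0.0, np.sqrt(1.0 - var_g), size=n)
    threshold = stats.norm.isf(cfg.prevalence)
    labels = (liab > threshold).astype(np.int8)
    return labels, liab


def compute_sumstats(geno: GenotypeMatrix, y: np.ndarray,
                     cohort: np.ndarray, chunk: int = 512) -> pd.DataFrame:
    """Score-test association of a phenotype on each variant's dosage.

    ``y`` may be binary case/control labels or a quantitative phenotype;
    the score statistic ``Z = g_c . y_c / sqrt(mean(y_c^2) * sum(g_c^2))``
    is standard-normal under the null in both cases.  Monomorphic variants
    in the cohort yield a flagged record with missing statistics.
    """
    cohort = np.asarray(cohort)
    if cohort.size == 0:
        raise ConfigError("empty cohort")
    yc = np.asarray(y, dtype=np.float64)[cohort]
    if np.all(yc == yc[0]):
        raise ConfigError("cohort phenotype is constant (one class only)")
    yc = yc - yc.mean()
    s2y = float(np.mean(yc ** 2))
    m = geno.n_variants
    u = np.empty(m)
    ssg = np.empty(m)
    frq = np.empty(m)
    G = geno.dosages[cohort]
    for start in range(0, m, chunk):
        block = G[:, start:start + chunk].astype(np.float64)
        mean = block.mean(axis=0)
        blockc = block - mean
        u[start:start + chunk] = yc @ blockc
        ssg[start:start + chunk] = np.einsum("ij,ij->j", blockc, blockc)
        frq[start:start + chunk] = mean / 2.0
    mono = ssg == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = u / np.sqrt(s2y * ssg)
        beta = u / ssg
    z[mono] = np.nan
    beta[mono] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(z != 0, np.abs(beta / z), np.nan)
    out = geno.variants[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    out["Z"] = z
    out["P"] = z_to_p(z)
    out["N"] = float(cohort.size)
    out["FRQ"] = frq
    out["BETA"] = beta
    out["SE"] = se
    out["MONOMORPHIC"] = mono
    return out


def build_cohorts(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Index sets realizing the configured pairwise overlaps.

    Each study pair with a nonzero entry in ``overlap_matrix`` receives a
    dedicated set of individuals belonging to exactly that pair; the
    remainder of each cohort is private.  Returns ``(cohorts, n_total)``.
    """
    cfg.validate()
    n_studies = cfg.n_studies
    cohorts = [[] for _ in range(n_studies)]
    cursor = 0
    for s in range(n_studies):
        for t in range(s + 1, n_studies):
            k = int(cfg.overlap_matrix[s, t])
            if k:
                idx = np.arange(cursor, cursor + k)
                cohorts[s].append(idx)
                cohorts[t].append(idx)
                cursor += k
    out = []
    for s in range(n_studies):
        have = int(sum(a.size for a in cohorts[s]))
        rest = cfg.cohort_sizes[s] - have
        idx = np.arange(cursor, cursor + rest)
        cursor += rest
        out.append(np.concatenate(cohorts[s] + [idx]) if cohorts[s] else idx)
    return out, cursor


@dataclass
class StudyCollection:
    """Everything one simulated analysis needs, with ground truth."""

    config: SimConfig
    genotypes: GenotypeMatrix
    truth: TruthTable
    labels: np.ndarray
    liabilities: np.ndarray
    cohorts: list[np.ndarray]
    studies: dict[str, pd.DataFrame]


def simulate_collection(cfg: SimConfig, quantitative: bool = False,
                        study_names: list[str] | None = None) -> StudyCollection:
    """Run the whole generator: genotypes, phenotypes, per-study sumstats.

    Study ``s`` observes trait ``cfg.study_traits[s]`` on its cohort; with
    ``quantitative=True`` the liability itself is analyzed instead of the
    thresholded case/control label.
    """
    rng = np.random.default_rng(cfg.seed)
    cohorts, n_total = build_cohorts(cfg, rng)
    geno = simulate_genotypes(cfg, n_total, rng)
    truth = simulate_truth(cfg, geno.variants, rng)
    labels, liab = simulate_phenotypes(geno, truth, cfg, rng)
    pheno = liab if quantitative else labels
    if study_names is None:
        study_names = [f"study{s}_trait{t}"
                       for s, t in enumerate(cfg.study_traits)]
    studies = {}
    for s, name in enumerate(study_names):
        t = cfg.study_traits[s]
        studies[name] = compute_sumstats(geno, pheno[:, t], cohorts[s])
    return StudyCollection(config=cfg, genotypes=geno, truth=truth,
                           labels=labels, liabilities=liab,
                           cohorts=cohorts, studies=studies)


def generate_expression(n_genes: int, n_columns: int,
                        planted_set: np.ndarray | list[int],
                        planted_shift: float, seed: int,
                        planted_columns: np.ndarray | list[int] | None = None,
                        gene_ids: list[str] | None = None) -> pd.DataFrame:
    """Log-normal expression matrix with a planted column shift.

    Every gene draws a log-normal baseline per column; genes in
    ``planted_set`` additionally receive ``+planted_shift`` in the
    designated columns (default: the first column).  Returns a genes x
    columns DataFrame indexed by gene id.
    """
    rng = np.random.default_rng(seed)
    if planted_columns is None:
        planted_columns = [0]
    expr = rng.lognormal(mean=1.0, sigma=0.5, size=(n_genes, n_columns))
    planted_set = np.asarray(planted_set, dtype=int)
    for c in planted_columns:
        expr[planted_set, c] += planted_shift
    if gene_ids is None:
        gene_ids = [f"GENE{g + 1}" for g in range(n_genes)]
    cols = [f"col{c + 1}" for c in range(n_columns)]
    return pd.DataFrame(expr, index=pd.Index(gene_ids, name="GENE"), columns=cols)


def generate_annotations(cfg: SimConfig, truth: TruthTable,
                         variants: pd.DataFrame, n_genes: int = 50,
                         rng: np.random.Generator | None = None) -> dict:
    """Gene intervals and all evidence lookup tables, with truth links.

    Genes tile the pseudo-chromosome; each planted shared causal variant
    is linked to its nearest gene by an eQTL record and by a chromatin
    loop (anchors within 2 Mb), and half the shared variants seed the
    known-locus table.  The returned dict records the construction truth
    under ``"truth_links"`` so recovery is checkable.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    chrom = variants["CHR"].iloc[0]
    max_bp = int(variants["BP"].max())
    step = max(max_bp // n_genes, 20_001)
    genes = pd.DataFrame({
        "GENE": [f"GENE{g + 1}" for g in range(n_genes)],
        "CHR": chrom,
        "START": [g * step + 1 for g in range(n_genes)],
        "END": [g * step + step // 2 for g in range(n_genes)],
        "STRAND": "+",
    })
    shared = truth.indices(ROLE_SHARED)
    bp = variants["BP"].to_numpy()
    snp = variants["SNP"].to_numpy()
    centers = (genes["START"].to_numpy() + genes["END"].to_numpy()) / 2
    eqtl_rows, loop_rows, links = [], [], []
    for j in shared:
        g = int(np.argmin(np.abs(centers - bp[j])))
        eqtl_rows.append({"SNP": snp[j], "GENE": genes["GENE"][g],
                          "TISSUE": "brain"})
        a1 = (int(bp[j]) - 5_000, int(bp[j]) + 5_000)
        a2 = (int(genes["START"][g]), int(genes["END"][g]))
        lo, hi = (a1, a2) if a1[0] <= a2[0] else (a2, a1)
        loop_rows.append({"CHR": chrom, "START1": lo[0], "END1": lo[1],
                          "START2": hi[0], "END2": hi[1]})
        links.append({"SNP": snp[j], "GENE": genes["GENE"][g]})
    eqtls = pd.DataFrame(eqtl_rows, columns=["SNP", "GENE", "TISSUE"])
    loops = pd.DataFrame(
        loop_rows, columns=["CHR", "START1", "END1", "START2", "END2"])
    gene_ids = genes["GENE"].tolist()
    half = max(1, n_genes // 5)
    pathway_members = gene_ids[:half]
    pathways = {"addiction_pathway": set(pathway_members)}
    families = pd.DataFrame({
        "GENE": gene_ids,
        "FAMILY": [f"FAM{g % (n_genes // 2 or 1)}" for g in range(n_genes)],
    })
    interactions = pd.DataFrame({
        "GENE1": pathway_members,
        "GENE2": gene_ids[half:2 * half],
        "SCORE": np.round(rng.uniform(0.7, 1.0, size=half), 3),
        "EVIDENCE": "database",
    })
    trait_classes = pd.DataFrame({
        "GENE": gene_ids,
        "TRAIT_CLASS": [
            "psychiatric" if g % 3 == 0 else "other" for g in range(n_genes)],
    })
    known_shared = shared[: len(shared) // 2]
    known = pd.DataFrame({
        "CHR": chrom,
        "START": bp[known_shared] - 1_000,
        "END": bp[known_shared] + 1_000,
    })
    return {
        "genes": genes,
        "eqtls": eqtls,
        "loops": loops,
        "pathways": pathways,
        "families": families,
        "interactions": interactions,
        "trait_classes": trait_classes,
        "known_loci": known,
        "truth_links": pd.DataFrame(links, columns=["SNP", "GENE"]),
    }
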