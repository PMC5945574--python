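"""Synthetic NC II study generator.

Emulates the statistical structure of a hybrid-rice genomic-selection
study: fully homozygous parental panels (inbred female lines plus a few
male-sterile testers), their full-factorial F1 hybrids, multi-environment
replicated phenotypes at chosen broad-sense heritabilities, and a candidate
panel for exhaustive cross prediction.

Phenotype model for hybrid i in environment j, replicate l:

    y_ijl = mu + g_i + ge_ij + eps_ijl

with g the additive genetic value from a random QTL subset, rescaled to
variance exactly 1, and the noise variances chosen so that the broad-sense
heritability of genotype means,

    H = s2_g / (s2_g + s2_ge / e + s2_eps / (e r)),

hits the target exactly: s2_ge/e + s2_eps/(e r) = (1 - H)/H, split 50/50
between interaction and residual by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .crossing import CrossSet, deduce_hybrid_genotypes, enumerate_crosses
from .evaluation import spawn_rng
from .genotype_io import MARKER_COLUMNS, GenotypeMatrix

#: Broad-sense heritabilities of the eight agronomic traits the default
#: bundle emulates (grain yield, thousand-grain weight, panicle number,
#: plant height, secondary branch number, grain number, panicle length,
#: primary branch number).
DEFAULT_TRAIT_H = {
    "GY": 0.3031,
    "TGW": 0.8501,
    "PN": 0.2550,
    "PH": 0.7501,
    "SB": 0.6676,
    "GN": 0.6262,
    "PL": 0.7802,
    "PB": 0.6944,
}

# field-plausible trait means (grams, counts, cm) so relative gains are
# computed on a realistic scale
DEFAULT_TRAIT_MEAN = {
    "GY": 38.0,
    "TGW": 25.0,
    "PN": 10.0,
    "PH": 110.0,
    "SB": 35.0,
    "GN": 150.0,
    "PL": 23.0,
    "PB": 12.0,
}


@dataclass
class SimulationConfig:
    n_females: int = 115
    n_males: int = 5
    n_candidates: int = 200  # desk-scale stand-in for a 3,023-accession panel
    n_markers: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_females, self.n_males, self.n_candidates, self.n_markers) < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")


@dataclass
class TraitArchitecture:
    name: str
    target_H: float
    n_qtl: int = 50
    effect_distribution: str = "normal"  # or "mixture"
    mixture_major_fraction: float = 0.1  # fraction of QTL that are major under "mixture"
    e: int = 2
    r: int = 2
    dominance_ratio: float = 0.0
    mean: float = 50.0

    def __post_init__(self):
        if not 0 < self.target_H <= 1:
            raise ValueError("target_H must be in (0, 1]")
        if self.target_H < 0.01:
            raise ValueError("target_H below 0.01: noise variances overflow sanity cap")
        if self.effect_distribution not in ("normal", "mixture"):
            raise ValueError("effect_distribution must be 'normal' or 'mixture'")
        if self.dominance_ratio < 0:
            raise ValueError("dominance_ratio must be >= 0")


def default_trait_architectures(n_qtl: int = 50) -> list[TraitArchitecture]:
    return [
        TraitArchitecture(name, H, n_qtl=n_qtl, mean=DEFAULT_TRAIT_MEAN[name])
        for name, H in DEFAULT_TRAIT_H.items()
    ]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _homozygous_panel(rng: np.random.Generator, n: int, p_plus: np.ndarray, ld_rho: float) -> np.ndarray:
    """Codes in {-1,+1}: latent AR(1) Gaussian thresholded at each marker's
    allele frequency, giving first-order LD with correlation ~ ld_rho."""
    m = p_plus.size
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    if ld_rho > 0:
        innov = np.sqrt(1 - ld_rho**2)
        for j in range(1, m):
            z[:, j] = ld_rho * z[:, j - 1] + innov * rng.standard_normal(n)
    else:
        z[:, 1:] = rng.standard_normal((n, m - 1))
    thresh = stats.norm.ppf(1 - p_plus)  # P(z > thresh) = p_plus
    return np.where(z > thresh, 1.0, -1.0)


def _synthetic_markers(m: int) -> pd.DataFrame:
    per_chrom = int(np.ceil(m / 12))
    rows = []
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    for j in range(m):
        chrom = f"chr{j // per_chrom + 1:02d}"
        pos = (j % per_chrom) * 1000 + 1
        ref, alt = alleles[j % 4]
        rows.append((f"snp{j + 1:06d}", chrom, pos, ref, alt))
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def simulate_parent_genotypes(cfg: SimulationConfig, group: str = "line", prefix: str = "L", rng=None) -> GenotypeMatrix:
    """Fully homozygous parental panel with allele frequencies drawn from
    ``maf_range`` and optional first-order LD."""
    rng = rng if rng is not None else spawn_rng(cfg.seed, "parents", group, prefix)
    maf = rng.uniform(*cfg.maf_range, size=cfg.n_markers)
    # randomly orient which allele is the minor one
    p_plus = np.where(rng.random(cfg.n_markers) < 0.5, 1 - maf, maf)
    n = {"line": cfg.n_females, "tester": cfg.n_males, "candidate": cfg.n_candidates}[group]
    calls = _homozygous_panel(rng, n, p_plus, cfg.ld_rho)
    samples = [f"{prefix}{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(samples, _synthetic_markers(cfg.n_markers), calls, {s: group for s in samples})


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    hybrids: GenotypeMatrix, arch: TraitArchitecture, seed: int
) -> tuple[pd.DataFrame, dict]:
    """Multi-environment replicated phenotypes at the target heritability.

    Returns the long-format phenotype table (hybrid_id, trait, environment,
    replicate, value) and a truth record with the QTL ids, effects, genetic
    values, per-hybrid means and the nominal variance components.
    """
    if arch.n_qtl > hybrids.n_markers:
        raise ValueError("n_qtl exceeds marker count")
    rng = spawn_rng(seed, "pheno", arch.name)
    n = hybrids.n_samples
    qtl = np.sort(rng.choice(hybrids.n_markers, size=arch.n_qtl, replace=False))
    if arch.effect_distribution == "normal":
        gamma = rng.standard_normal(arch.n_qtl)
    else:
        n_major = max(1, int(round(arch.mixture_major_fraction * arch.n_qtl)))
        gamma = rng.standard_normal(arch.n_qtl) * 0.1
        major = rng.choice(arch.n_qtl, size=n_major, replace=False)
        gamma[major] = rng.standard_normal(n_major) * 3.0

    g = hybrids.calls[:, qtl] @ gamma
    if arch.dominance_ratio > 0:
        het = (hybrids.calls[:, qtl] == 0).astype(float)
        dev = het @ rng.standard_normal(arch.n_qtl)
        dev = dev - dev.mean()
        sd_target = np.sqrt(arch.dominance_ratio) * np.std(g)
        if np.std(dev) > 0:
            g = g + dev * sd_target / np.std(dev)
    sd_g = np.std(g)
    if sd_g == 0:
        raise ValueError("degenerate genetic values (no QTL variation)")
    scale = 1.0 / sd_g
    g = (g - g.mean()) * scale  # realized genetic variance exactly 1
    gamma_scaled = gamma * scale

    H, e, r = arch.target_H, arch.e, arch.r
    noise_total = (1 - H) / H  # variance of the genotype-mean noise
    s2_ge = e * noise_total / 2.0
    s2_eps = e * r * noise_total / 2.0

    ge = rng.standard_normal((n, e)) * np.sqrt(s2_ge) if s2_ge > 0 else np.zeros((n, e))
    eps = rng.standard_normal((n, e, r)) * np.sqrt(s2_eps) if s2_eps > 0 else np.zeros((n, e, r))
    y = arch.mean + g[:, None, None] + ge[:, :, None] + eps

    rows = []
    for j in range(e):
        for l in range(r):
            rows.append(
                pd.DataFrame(
                    {
                        "hybrid_id": hybrids.samples,
                        "trait": arch.name,
                        "environment": f"E{j + 1}",
                        "replicate": l + 1,
                        "value": y[:, j, l],
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    truth: dict = {
        "trait": arch.name,
        "qtl_indices": qtl,
        "qtl_ids": [hybrids.marker_ids[i] for i in qtl],
        "gamma": gamma_scaled,
        "g": g,
        "hybrid_means": y.reshape(n, -1).mean(axis=1),
        "mu": arch.mean,
        "sigma2_g": float(np.var(g)),
        "sigma2_ge": s2_ge,
        "sigma2_eps": s2_eps,
        "e": e,
        "r": r,
        "target_H": H,
    }
    truth["realized_H"] = truth["sigma2_g"] / (
        truth["sigma2_g"] + s2_ge / e + s2_eps / (e * r)
    )
    return table, truth


# ---------------------------------------------------------------------------
# full study bundle
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    config: SimulationConfig
    parents: GenotypeMatrix          # females + testers, homozygous
    females: list[str]
    males: list[str]
    crosses: CrossSet
    hybrids: GenotypeMatrix          # deduced NC II training hybrids
    candidates: GenotypeMatrix       # candidate panel for selection
    phenotypes: pd.DataFrame         # long format, all traits
    hybrid_means: pd.DataFrame       # hybrid_id x trait matrix of means
    truth: dict[str, dict] = field(default_factory=dict)


def make_study_bundle(
    cfg: SimulationConfig | None = None,
    architectures: list[TraitArchitecture] | None = None,
    seed: int | None = None,
) -> StudyBundle:
    """One call yields every input the pipeline needs, reproducibly."""
    cfg = cfg or SimulationConfig()
    seed = cfg.seed if seed is None else seed
    architectures = architectures or default_trait_architectures()

    rng = spawn_rng(seed, "bundle")
    maf = rng.uniform(*cfg.maf_range, size=cfg.n_markers)
    p_plus = np.where(rng.random(cfg.n_markers) < 0.5, 1 - maf, maf)
    markers = _synthetic_markers(cfg.n_markers)

    def panel(n, prefix, group, stream):
        calls = _homozygous_panel(spawn_rng(seed, "panel", stream), n, p_plus, cfg.ld_rho)
        samples = [f"{prefix}{i + 1:04d}" for i in range(n)]
        return GenotypeMatrix(samples, markers.copy(), calls, {s: group for s in samples})

    females_gm = panel(cfg.n_females, "F", "line", "females")
    males_gm = panel(cfg.n_males, "M", "tester", "males")
    candidates = panel(cfg.n_candidates, "C", "candidate", "candidates")

    parents = GenotypeMatrix(
        females_gm.samples + males_gm.samples,
        markers.copy(),
        np.vstack([females_gm.calls, males_gm.calls]),
        {**(females_gm.groups or {}), **(males_gm.groups or {})},
    )
    crosses = enumerate_crosses(females_gm.samples, males_gm.samples)
    hybrids = deduce_hybrid_genotypes(parents, crosses)

    tables = []
    truth = {}
    means = {}
    for arch in architectures:
        tab, tr = simulate_phenotypes(hybrids, arch, seed)
        tables.append(tab)
        truth[arch.name] = tr
        means[arch.name] = tr["hybrid_means"]
    phenotypes = pd.concat(tables, ignore_index=True)
    hybrid_means = pd.DataFrame(means, index=hybrids.samples)
    hybrid_means.index.name = "hybrid_id"
    return StudyBundle(
        cfg, parents, females_gm.samples, males_gm.samples, crosses, hybrids,
        candidates, phenotypes, hybrid_means, truth,
    )
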