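"""Predictability evaluation: replicated k-fold cross-validation, the
trait x method ANOVA with Tukey letter groups, marker-density and
training-size subsampling experiments, and broad-sense heritability.

Predictability is the Pearson correlation between observed phenotypes and
their out-of-fold predictions.  Each cross-validation replicate draws a
fresh balanced random partition, predicts every sample exactly once, and
yields a single correlation over the pooled out-of-fold predictions; the
summary is the mean and sd over replicates.

Broad-sense heritability of genotype means over e environments and r
replicates comes from the expected-mean-squares decomposition of the
balanced two-way ANOVA:

    H = sigma2_g / (sigma2_g + sigma2_ge / e + sigma2_eps / (e r)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import learners
from .genotype_io import GenotypeMatrix


def spawn_rng(seed: int, *names) -> np.random.Generator:
    """Independent named random stream derived from a master seed."""
    import zlib

    entropy = [int(seed)] + [
        zlib.crc32(str(n).encode()) for n in names
    ]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))


def derive_seed(seed: int, *names) -> int:
    """Deterministic child seed below 2^31 for APIs that take plain ints."""
    return int(spawn_rng(seed, *names).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# folds and predictability
# ---------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    n: int
    k: int
    fold_of: np.ndarray  # fold id in 1..k per sample index
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def kfold_partition(n: int, k: int, seed: int | np.random.Generator) -> FoldAssignment:
    """Uniformly random balanced partition into k folds (sizes differ <= 1)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot partition {n} samples into {k} folds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.Generator(np.random.PCG64(seed))
    fold_of = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    fold_of[perm] = np.arange(n) % k + 1
    return FoldAssignment(n, k, fold_of, seed if isinstance(seed, int) else -1)


def predictability(observed, predicted) -> float:
    """Pearson correlation between observed and predicted phenotypes."""
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.size != predicted.size or observed.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.std(observed) == 0 or np.std(predicted) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(observed, predicted)[0, 1])


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Per-replicate predictabilities, one row per trait x method x replicate."""

    records: pd.DataFrame  # columns: trait, method, replicate, r

    def summary(self) -> pd.DataFrame:
        return (
            self.records.groupby(["trait", "method"])["r"]
            .agg(["mean", "std"])
            .reset_index()
        )


def _out_of_fold_predictions(fit_fn, M: np.ndarray, y: np.ndarray, folds: FoldAssignment) -> np.ndarray:
    pred = np.empty_like(y)
    for fold in range(1, folds.k + 1):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        model = fit_fn(M[tr], y[tr])
        pred[te] = model.predict(M[te])
    return pred


def _resolve_fit_fn(method, seed: int, method_kwargs: dict | None):
    kwargs = dict(method_kwargs or {})
    if callable(method):
        return lambda M, y: method(M, y, **kwargs)
    return lambda M, y: learners.fit(method, M, y, seed=seed, **kwargs)


def cross_validate(
    method,
    geno: GenotypeMatrix | np.ndarray,
    pheno,
    k: int = 5,
    replicates: int = 20,
    seed: int = 0,
    trait: str = "trait",
    method_kwargs: dict | None = None,
) -> CVResult:
    """Replicated k-fold CV predictability for one method on one trait.

    ``method`` is a learner name from :data:`hybridgs.learners.METHODS` or a
    callable ``fit(M, y) -> model`` (test hook).  Each replicate reports one
    correlation over the pooled out-of-fold predictions of all samples.
    """
    M = geno.calls if isinstance(geno, GenotypeMatrix) else np.asarray(geno, dtype=float)
    y = np.asarray(pheno, dtype=float).ravel()
    if M.shape[0] != y.size:
        raise ValueError("genotype and phenotype sample counts differ")
    name = method if isinstance(method, str) else getattr(method, "__name__", "custom")
    rows = []
    for rep in range(1, replicates + 1):
        rng = spawn_rng(seed, "folds", trait, name, rep)
        folds = kfold_partition(y.size, k, rng)
        fit_fn = _resolve_fit_fn(method, derive_seed(seed, "fit", trait, name, rep), method_kwargs)
        pred = _out_of_fold_predictions(fit_fn, M, y, folds)
        rows.append((trait, name, rep, predictability(y, pred)))
    return CVResult(pd.DataFrame(rows, columns=["trait", "method", "replicate", "r"]))


def cross_validate_grid(
    methods: list,
    geno,
    phenos: dict[str, np.ndarray],
    k: int = 5,
    replicates: int = 20,
    seed: int = 0,
    method_kwargs: dict[str, dict] | None = None,
) -> CVResult:
    """CV every method on every trait; concatenated CVResult."""
    frames = []
    for trait, y in phenos.items():
        for method in methods:
            kw = (method_kwargs or {}).get(method if isinstance(method, str) else "custom")
            frames.append(
                cross_validate(method, geno, y, k, replicates, seed, trait, kw).records
            )
    return CVResult(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# ANOVA of predictabilities and Tukey letter groups
# ---------------------------------------------------------------------------


def predictability_anova(cv: CVResult) -> pd.DataFrame:
    """Two-way fixed-effects factorial ANOVA (trait, method, interaction).

    Requires a balanced trait x method x replicate table; returns a table
    with source, df, SS, MS, F and p.
    """
    df = cv.records
    counts = df.groupby(["trait", "method"])["r"].count()
    if counts.nunique() != 1:
        raise ValueError("unbalanced trait x method x replicate records")
    reps = int(counts.iloc[0])
    a = df["trait"].nunique()
    b = df["method"].nunique()
    if reps < 2:
        raise ValueError("need >= 2 replicates per cell for a residual term")

    grand = df["r"].mean()
    t_means = df.groupby("trait")["r"].mean()
    m_means = df.groupby("method")["r"].mean()
    cell_means = df.groupby(["trait", "method"])["r"].mean()

    ss_trait = b * reps * float(((t_means - grand) ** 2).sum())
    ss_method = a * reps * float(((m_means - grand) ** 2).sum())
    inter = cell_means - t_means.reindex(cell_means.index.get_level_values(0)).to_numpy() \
        - m_means.reindex(cell_means.index.get_level_values(1)).to_numpy() + grand
    ss_inter = reps * float((inter**2).sum())
    cell_of = df.set_index(["trait", "method"]).index
    ss_resid = float(((df["r"].to_numpy() - cell_means.reindex(cell_of).to_numpy()) ** 2).sum())

    dfs = [a - 1, b - 1, (a - 1) * (b - 1), a * b * (reps - 1)]
    sss = [ss_trait, ss_method, ss_inter, ss_resid]
    mss = [s / d if d > 0 else np.nan for s, d in zip(sss, dfs)]
    ms_resid = mss[3]
    fs = [
        m / ms_resid if d > 0 and ms_resid > 0 else np.nan
        for m, d in zip(mss[:3], dfs[:3])
    ] + [np.nan]
    ps = [float(stats.f.sf(f, d, dfs[3])) if np.isfinite(f) else np.nan for f, d in zip(fs, dfs)]
    return pd.DataFrame(
        {
            "source": ["trait", "method", "trait:method", "residual"],
            "df": dfs,
            "SS": sss,
            "MS": mss,
            "F": fs,
            "p": ps,
        }
    )


def tukey_groups(cv: CVResult, factor: str = "method", alpha: float = 0.05) -> dict[str, str]:
    """Tukey HSD letter groups for the main-effect means of one factor.

    Uses the residual MS of the two-way ANOVA; levels sharing a letter do
    not differ significantly at level ``alpha``.  Letters follow the
    standard sorted-means sweep (best mean gets 'A').
    """
    if factor not in ("trait", "method"):
        raise ValueError("factor must be 'trait' or 'method'")
    anova = predictability_anova(cv)
    ms_resid = float(anova.loc[anova["source"] == "residual", "MS"].iloc[0])
    df_resid = int(anova.loc[anova["source"] == "residual", "df"].iloc[0])
    means = cv.records.groupby(factor)["r"].mean().sort_values(ascending=False)
    n_per = len(cv.records) // means.size
    k = means.size
    if k < 2:
        raise ValueError("need at least two levels")
    qcrit = stats.studentized_range.ppf(1 - alpha, k, df_resid)
    hsd = qcrit * np.sqrt(ms_resid / n_per)

    levels = means.index.tolist()
    vals = means.to_numpy()
    # sorted-means sweep: each group is a maximal run of levels whose extremes
    # differ by less than the HSD
    groups: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and vals[i] - vals[j + 1] < hsd:
            j += 1
        if not groups or j > groups[-1][1]:
            groups.append((i, j))
    letters = {lv: "" for lv in levels}
    for gi, (i, j) in enumerate(groups):
        letter = chr(ord("A") + gi)
        for idx in range(i, j + 1):
            letters[levels[idx]] += letter
    return letters


# ---------------------------------------------------------------------------
# subsampling experiments
# ---------------------------------------------------------------------------


def subsample_experiment(
    axis: str,
    sizes: list[int],
    method,
    geno,
    pheno,
    selections_per_size: int = 100,
    k: int = 5,
    seed: int = 0,
    method_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Predictability as a function of marker number or training size.

    For each size, ``selections_per_size`` uniform random subsets (without
    replacement) of the chosen axis are drawn; each subset is scored by one
    k-fold CV replicate.  Returns a table (size, mean, sd, n_selections).
    """
    if axis not in ("markers", "individuals"):
        raise ValueError("axis must be 'markers' or 'individuals'")
    M = geno.calls if isinstance(geno, GenotypeMatrix) else np.asarray(geno, dtype=float)
    y = np.asarray(pheno, dtype=float).ravel()
    limit = M.shape[1] if axis == "markers" else M.shape[0]
    rows = []
    for size in sizes:
        if size > limit:
            raise ValueError(f"subset size {size} exceeds available {axis} ({limit})")
        rs = []
        for sel in range(selections_per_size):
            rng = spawn_rng(seed, "subsample", axis, size, sel)
            idx = rng.choice(limit, size=size, replace=False)
            Msub = M[:, idx] if axis == "markers" else M[np.sort(idx)]
            ysub = y if axis == "markers" else y[np.sort(idx)]
            folds = kfold_partition(ysub.size, k, rng)
            fit_fn = _resolve_fit_fn(method, derive_seed(seed, "subfit", axis, size, sel), method_kwargs)
            pred = _out_of_fold_predictions(fit_fn, Msub, ysub, folds)
            rs.append(predictability(ysub, pred))
        rows.append((size, float(np.mean(rs)), float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0, len(rs)))
    return pd.DataFrame(rows, columns=["size", "mean", "sd", "n_selections"])


# ---------------------------------------------------------------------------
# broad-sense heritability
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_ge: float
    sigma2_eps: float
    e: int
    r: int

    @property
    def H(self) -> float:
        denom = self.sigma2_g + self.sigma2_ge / self.e + self.sigma2_eps / (self.e * self.r)
        return self.sigma2_g / denom if denom > 0 else 0.0


def estimate_broad_sense_H(pheno: pd.DataFrame, trait: str | None = None) -> VarianceComponents:
    """Expected-mean-squares heritability from a balanced two-way layout.

    ``pheno`` is long-format with columns hybrid_id, environment, replicate,
    value (optionally trait, filtered by ``trait``).  Estimators:
    sigma2_eps = MS_resid, sigma2_ge = (MS_GE - MS_resid)/r,
    sigma2_g = (MS_G - MS_GE)/(e r); negatives clamp to zero.
    """
    df = pheno
    if trait is not None:
        df = df[df["trait"] == trait]
    g_levels = df["hybrid_id"].unique()
    e_levels = df["environment"].unique()
    r_levels = df["replicate"].unique()
    n_g, e, r = len(g_levels), len(e_levels), len(r_levels)
    if e < 2 or r < 2:
        raise ValueError("need >= 2 environments and >= 2 replicates to separate GE and residual")
    counts = df.groupby(["hybrid_id", "environment", "replicate"])["value"].count()
    if len(counts) != n_g * e * r or counts.nunique() != 1:
        raise ValueError("unbalanced genotype x environment x replicate layout")

    grand = df["value"].mean()
    gm = df.groupby("hybrid_id")["value"].mean()
    em = df.groupby("environment")["value"].mean()
    gem = df.groupby(["hybrid_id", "environment"])["value"].mean()

    ss_g = e * r * float(((gm - grand) ** 2).sum())
    inter = gem - gm.reindex(gem.index.get_level_values(0)).to_numpy() \
        - em.reindex(gem.index.get_level_values(1)).to_numpy() + grand
    ss_ge = r * float((inter**2).sum())
    cell = gem.reindex(df.set_index(["hybrid_id", "environment"]).index).to_numpy()
    ss_resid = float(((df["value"].to_numpy() - cell) ** 2).sum())

    ms_g = ss_g / (n_g - 1)
    ms_ge = ss_ge / ((n_g - 1) * (e - 1))
    ms_resid = ss_resid / (n_g * e * (r - 1))

    s2_eps = ms_resid
    s2_ge = max((ms_ge - ms_resid) / r, 0.0)
    s2_g = max((ms_g - ms_ge) / (r * e), 0.0)
    return VarianceComponents(s2_g, s2_ge, s2_eps, e, r)
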