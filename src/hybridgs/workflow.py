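"""One-command reproduction of the study skeleton on simulated data.

Chains: simulate an NC II bundle -> replicated CV of the requested methods
on every trait -> ANOVA of predictabilities with Tukey letters ->
marker-density and training-size subsampling -> exhaustive candidate-cross
ranking with top-k gains.  Everything is driven by a config + seed, and the
emitted report embeds both so any table can be regenerated.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evaluation, learners, selection, simdata
from .evaluation import derive_seed

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Desk-scale defaults; the real-study scale is reachable by config."""

    simulation: simdata.SimulationConfig = field(default_factory=simdata.SimulationConfig)
    methods: list[str] = field(default_factory=lambda: ["gblup", "lasso", "pls", "svm"])
    cv_folds: int = 5
    cv_replicates: int = 20
    marker_sizes: list[int] = field(default_factory=lambda: [100, 250, 500, 1000, 2000])
    individual_sizes: list[int] = field(default_factory=lambda: [115, 230, 345, 460, 575])
    selections_per_size: int = 20
    subsample_method: str = "gblup"
    subsample_trait: str = "TGW"
    top_k: int = 100
    gain_curve_k_max: int = 500
    n_qtl: int = 50
    method_kwargs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = simdata.SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


@dataclass
class StudyReport:
    config: dict
    seed: int
    predictability: pd.DataFrame
    anova: pd.DataFrame
    tukey_letters: dict[str, dict[str, str]]
    marker_curve: pd.DataFrame
    individual_curve: pd.DataFrame
    gains: pd.DataFrame
    runtimes: dict[str, float]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "tukey_letters": self.tukey_letters,
                    "runtimes": self.runtimes,
                },
                indent=2,
                default=str,
            )
        )
        self.predictability.to_csv(outdir / "predictability.tsv", sep="\t", index=False)
        self.anova.to_csv(outdir / "anova.tsv", sep="\t", index=False)
        self.marker_curve.to_csv(outdir / "subsample_markers.tsv", sep="\t", index=False)
        self.individual_curve.to_csv(outdir / "subsample_individuals.tsv", sep="\t", index=False)
        self.gains.to_csv(outdir / "top_k_gains.tsv", sep="\t", index=False)


def run_full_study(config: StudyConfig | str | Path | None = None, seed: int = 0) -> StudyReport:
    """Execute every stage on a simulated bundle; idempotent for fixed seed."""
    if config is None:
        config = StudyConfig()
    elif not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)
    runtimes: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s", name)
        runtimes[name] = time.perf_counter()
        return name

    def done(name):
        runtimes[name] = round(time.perf_counter() - runtimes[name], 3)

    try:
        name = stage("simulate")
        archs = simdata.default_trait_architectures(n_qtl=config.n_qtl)
        bundle = simdata.make_study_bundle(config.simulation, archs, seed=seed)
        done(name)

        name = stage("cross_validation")
        phenos = {t: bundle.hybrid_means[t].to_numpy() for t in bundle.hybrid_means.columns}
        cv = evaluation.cross_validate_grid(
            config.methods,
            bundle.hybrids,
            phenos,
            k=config.cv_folds,
            replicates=config.cv_replicates,
            seed=derive_seed(seed, "cv"),
            method_kwargs=config.method_kwargs,
        )
        done(name)

        name = stage("anova")
        anova = evaluation.predictability_anova(cv)
        letters = {
            "trait": evaluation.tukey_groups(cv, "trait"),
            "method": evaluation.tukey_groups(cv, "method"),
        }
        done(name)

        name = stage("subsampling")
        trait = config.subsample_trait
        y = bundle.hybrid_means[trait].to_numpy()
        marker_curve = evaluation.subsample_experiment(
            "markers",
            [s for s in config.marker_sizes if s <= bundle.hybrids.n_markers],
            config.subsample_method,
            bundle.hybrids,
            y,
            selections_per_size=config.selections_per_size,
            k=config.cv_folds,
            seed=derive_seed(seed, "sub_markers"),
        )
        individual_curve = evaluation.subsample_experiment(
            "individuals",
            [s for s in config.individual_sizes if s <= bundle.hybrids.n_samples],
            config.subsample_method,
            bundle.hybrids,
            y,
            selections_per_size=config.selections_per_size,
            k=config.cv_folds,
            seed=derive_seed(seed, "sub_individuals"),
        )
        done(name)

        name = stage("selection")
        gain_rows = []
        for t in bundle.hybrid_means.columns:
            model = learners.fit_gblup(bundle.hybrids, bundle.hybrid_means[t].to_numpy())
            ranked = selection.predict_all_crosses(
                model, bundle.parents, bundle.candidates, bundle.females, trait=t
            )
            k = min(config.top_k, len(ranked))
            mean_top, mean_all, gain, rel = selection.top_k_gain(ranked, k)
            gain_rows.append((t, k, mean_top, mean_all, gain, rel))
        gains = pd.DataFrame(
            gain_rows,
            columns=["trait", "k", "mean_top_k", "mean_all", "absolute_gain", "relative_gain_percent"],
        )
        done(name)
    except Exception as exc:
        raise RuntimeError(f"study stage {name!r} failed: {exc}") from exc

    return StudyReport(
        config=asdict(config),
        seed=seed,
        predictability=cv.summary(),
        anova=anova,
        tukey_letters=letters,
        marker_curve=marker_curve,
        individual_curve=individual_curve,
        gains=gains,
        runtimes=runtimes,
    )
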