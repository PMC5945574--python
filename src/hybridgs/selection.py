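"""Ranking untested crosses: exhaustive prediction, top-k gain, gain curves
and between-method overlap.

The breeding use case: a model trained on the phenotyped NC II hybrids is
applied to every female x candidate cross, predictions are sorted in
descending order, and the expected gain of selecting the best k crosses is
the difference between the top-k mean and the mean over all crosses
(absolute, and as a percentage of the all-cross mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossing import CrossSet, deduce_hybrid_genotypes, hybrid_id
from .genotype_io import GenotypeMatrix
from .learners import PredictorModel

BLOCK_SIZE = 10_000  # hybrids deduced/predicted per streamed block


@dataclass
class RankedPredictions:
    """Predictions sorted descending; ties broken by hybrid id (stable)."""

    entries: pd.DataFrame  # columns: hybrid_id, female, male, predicted
    trait: str = "trait"
    method: str = "unknown"

    def __post_init__(self):
        df = self.entries
        required = ["hybrid_id", "female", "male", "predicted"]
        if list(df.columns[:4]) != required:
            raise ValueError(f"entries must have columns {required}")
        self.entries = (
            df.sort_values(["predicted", "hybrid_id"], ascending=[False, True], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def predicted(self) -> np.ndarray:
        return self.entries["predicted"].to_numpy()

    def top(self, k: int) -> pd.DataFrame:
        return self.entries.head(k)


def predict_all_crosses(
    model: PredictorModel,
    parents: GenotypeMatrix,
    candidates: GenotypeMatrix,
    females: list[str],
    trait: str = "trait",
) -> RankedPredictions:
    """Predict every female x candidate cross in streamed blocks.

    ``parents`` and ``candidates`` must already share an intersected,
    consistently encoded marker set (see
    :func:`hybridgs.genotype_io.intersect_marker_sets`).
    """
    if parents.marker_ids != candidates.marker_ids:
        raise ValueError("parents and candidates must share an identical marker set")
    males = list(candidates.samples)
    pairs = [(f, m) for f in females for m in males]
    combined = GenotypeMatrix(
        list(parents.samples) + males,
        parents.markers.copy(),
        np.vstack([parents.calls, candidates.calls]),
    )
    frames = []
    for start in range(0, len(pairs), BLOCK_SIZE):
        block = pairs[start : start + BLOCK_SIZE]
        hybrids = deduce_hybrid_genotypes(combined, CrossSet(block))
        pred = model.predict(hybrids)
        frames.append(
            pd.DataFrame(
                {
                    "hybrid_id": [hybrid_id(f, m) for f, m in block],
                    "female": [f for f, _ in block],
                    "male": [m for _, m in block],
                    "predicted": pred,
                }
            )
        )
    return RankedPredictions(pd.concat(frames, ignore_index=True), trait, getattr(model, "method", "unknown"))


def top_k_gain(ranked: RankedPredictions, k: int) -> tuple[float, float, float, float]:
    """(mean_top_k, mean_all, absolute_gain, relative_gain_percent).

    relative gain = 100 * (mean_top_k - mean_all) / mean_all.
    """
    n = len(ranked)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    vals = ranked.predicted
    mean_top = float(vals[:k].mean())
    mean_all = float(vals.mean())
    if mean_all == 0:
        raise ZeroDivisionError("relative gain undefined: mean over all crosses is 0")
    gain = mean_top - mean_all
    return mean_top, mean_all, gain, 100.0 * gain / mean_all


def gain_curve(
    ranked: RankedPredictions,
    k_max: int,
    n_boot: int = 1000,
    seed: int = 0,
    ci: bool = True,
) -> pd.DataFrame:
    """Mean predicted value of the top k crosses for k = 1..k_max.

    The point estimate is the cumulative mean of the descending-sorted
    predictions (non-increasing in k).  When ``ci`` is true a nonparametric
    bootstrap (``n_boot`` resamples of the top-k set) gives a 95% interval
    of the top-k mean.
    """
    n = len(ranked)
    if k_max > n:
        raise ValueError(f"k_max {k_max} exceeds number of entries {n}")
    vals = ranked.predicted[:k_max]
    ks = np.arange(1, k_max + 1)
    means = np.cumsum(vals) / ks
    out = pd.DataFrame({"k": ks, "mean_top_k": means})
    if ci:
        rng = np.random.Generator(np.random.PCG64(seed))
        lo = np.empty(k_max)
        hi = np.empty(k_max)
        for i, k in enumerate(ks):
            boots = vals[rng.integers(0, k, size=(n_boot, k))].mean(axis=1)
            lo[i], hi[i] = np.quantile(boots, [0.025, 0.975])
        out["ci_lower"] = lo
        out["ci_upper"] = hi
    return out


def method_overlap(a: RankedPredictions, b: RankedPredictions, k: int) -> tuple[int, float]:
    """Top-k overlap count and full-vector prediction correlation.

    Both rankings must cover the same hybrid universe; the correlation is
    Pearson over predictions aligned by hybrid id.
    """
    ids_a = set(a.entries["hybrid_id"])
    ids_b = set(b.entries["hybrid_id"])
    if ids_a != ids_b:
        raise ValueError("rankings cover different hybrid universes")
    top_a = set(a.top(k)["hybrid_id"])
    top_b = set(b.top(k)["hybrid_id"])
    sa = a.entries.set_index("hybrid_id")["predicted"]
    sb = b.entries.set_index("hybrid_id")["predicted"].reindex(sa.index)
    corr = float(np.corrcoef(sa.to_numpy(), sb.to_numpy())[0, 1])
    return len(top_a & top_b), corr
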