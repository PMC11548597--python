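"""Model-evaluation statistics and GLUE-style parameter calibration.

Statistics follow the conventions used for the field-study comparisons:

- MRE (%): mean of |S_i - O_i| / S_i, i.e. with the *simulated* value in the
  denominator (a ``denominator`` flag switches to the observed-value
  convention).
- nRMSE (%): RMSE normalized by the observed range O_max - O_min.
- R^2: squared Pearson correlation between simulated and observed values.

GLUE (Generalized Likelihood Uncertainty Estimation) samples parameter sets
from uniform priors by Latin hypercube, scores each with a likelihood
exp(-nRMSE^2 / 2 sigma^2) combined across observation variables, retains the
top fraction as the behavioural set, and reports the best-scoring vector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import qmc

log = logging.getLogger(__name__)


class EvaluationError(ValueError):
    """Degenerate evaluation input."""


@dataclass(frozen=True)
class PairedSeries:
    """Simulated/observed value pairs for one variable."""

    simulated: np.ndarray
    observed: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self):
        sim = np.asarray(self.simulated, dtype=float)
        obs = np.asarray(self.observed, dtype=float)
        if sim.shape != obs.shape or sim.ndim != 1:
            raise EvaluationError("simulated and observed must be equal-length 1-d")
        if sim.size == 0:
            raise EvaluationError("empty paired series")
        object.__setattr__(self, "simulated", sim)
        object.__setattr__(self, "observed", obs)

    @property
    def n(self) -> int:
        return self.simulated.size


def mre(pairs: PairedSeries, denominator: str = "simulated") -> float:
    """Mean relative error, percent.

    The study convention puts the simulated value in the denominator;
    ``denominator="observed"`` switches to the textbook form.
    """
    s, o = pairs.simulated, pairs.observed
    denom = s if denominator == "simulated" else o
    if np.any(denom == 0):
        raise EvaluationError("zero denominator value in MRE")
    return float(np.mean(np.abs(s - o) / np.abs(denom)) * 100.0)


def nrmse(pairs: PairedSeries) -> float:
    """Normalized RMSE, percent of the observed range."""
    if pairs.n < 2:
        raise EvaluationError("nRMSE needs at least two pairs")
    s, o = pairs.simulated, pairs.observed
    orange = float(o.max() - o.min())
    if orange <= 0:
        raise EvaluationError("constant observations: zero range")
    rmse = float(np.sqrt(np.mean((s - o) ** 2)))
    return rmse / orange * 100.0


def r_squared(pairs: PairedSeries) -> float:
    """Coefficient of determination: squared Pearson correlation, in [0, 1]."""
    if pairs.n < 2:
        raise EvaluationError("R^2 needs at least two pairs")
    s, o = pairs.simulated, pairs.observed
    if np.std(s) == 0 or np.std(o) == 0:
        raise EvaluationError("zero variance in a series")
    r = float(np.corrcoef(s, o)[0, 1])
    return r * r


def evaluation_report(series: list[PairedSeries]) -> pd.DataFrame:
    """One row of (n, MRE, nRMSE, R^2) per variable."""
    rows = []
    for p in series:
        rows.append(
            {
                "variable": p.label,
                "units": p.units,
                "n": p.n,
                "mre_pct": mre(p),
                "nrmse_pct": nrmse(p) if p.n >= 2 else np.nan,
                "r_squared": r_squared(p) if p.n >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# --- GLUE calibration --------------------------------------------------------

@dataclass(frozen=True)
class GlueConfig:
    """Uniform prior bounds per parameter plus sampling settings."""

    priors: Mapping[str, tuple[float, float]]
    n_samples: int = 500
    sigma: float = 10.0                # likelihood temperature, nRMSE % units
    behavioural_fraction: float = 0.05  # top share retained
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise EvaluationError("need at least one sample")
        for name, (lo, hi) in self.priors.items():
            if hi < lo:
                raise EvaluationError(f"prior bounds for {name!r} are inverted")


@dataclass(frozen=True)
class GlueResult:
    samples: pd.DataFrame          # parameter columns + score + likelihood
    best_params: dict[str, float]
    best_score: float
    behavioural: pd.DataFrame


def combined_nrmse(
    simulated: Mapping[str, np.ndarray],
    observed: Mapping[str, np.ndarray],
) -> float:
    """Mean nRMSE (%) across observation variables."""
    scores = []
    for name, obs in observed.items():
        pair = PairedSeries(np.asarray(simulated[name], dtype=float),
                            np.asarray(obs, dtype=float), label=name)
        scores.append(nrmse(pair))
    if not scores:
        raise EvaluationError("no observation variables")
    return float(np.mean(scores))


def glue_calibrate(
    runner: Callable[[dict[str, float]], Mapping[str, np.ndarray]],
    config: GlueConfig,
    observations: Mapping[str, np.ndarray],
) -> GlueResult:
    """Latin-hypercube GLUE calibration.

    ``runner`` maps a parameter dict to simulated arrays keyed like
    ``observations``.  The score is the combined nRMSE across variables
    (lower is better); likelihood = exp(-score^2 / 2 sigma^2).  Reproducible
    for a fixed ``config.seed``.
    """
    names = list(config.priors)
    lo = np.array([config.priors[n][0] for n in names])
    hi = np.array([config.priors[n][1] for n in names])
    if config.n_samples == 1 or np.all(hi == lo):
        unit = np.full((config.n_samples, len(names)), 0.5)
    else:
        sampler = qmc.LatinHypercube(d=len(names), seed=config.seed)
        unit = sampler.random(config.n_samples)
    points = lo + unit * (hi - lo)

    records = []
    for row in points:
        params = dict(zip(names, (float(v) for v in row)))
        sim = runner(params)
        score = combined_nrmse(sim, observations)
        records.append({**params, "score": score})
    samples = pd.DataFrame(records)
    samples["likelihood"] = np.exp(-samples["score"] ** 2 / (2.0 * config.sigma ** 2))

    best_idx = int(samples["score"].idxmin())
    best_params = {n: float(samples.loc[best_idx, n]) for n in names}
    n_keep = max(1, int(round(config.behavioural_fraction * len(samples))))
    behavioural = samples.nlargest(n_keep, "likelihood")
    if behavioural["likelihood"].max() <= 0:
        warnings.warn("no sample achieved positive likelihood; "
                      "returning best-effort result")
    return GlueResult(
        samples=samples,
        best_params=best_params,
        best_score=float(samples.loc[best_idx, "score"]),
        behavioural=behavioural,
    )
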