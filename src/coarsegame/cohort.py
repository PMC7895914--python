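"""Synthetic patient cohorts and the empirical coarsening pipeline.

Emulates the shape of the clinical application: a cohort of young children
hospitalized with RSV bronchiolitis, a minority of whom (about 235/1202,
prevalence ~0.196) also have bacterial pneumonia.  In the real application a
classifier maps 27 clinical variables to a posterior probability of bacterial
co-infection per patient; the smoothed distribution of those posteriors is
the game's information system, from which the minimal stable coarsening
threshold is read off.

Real records are not distributable, so the generator produces posteriors
directly: true posteriors ``p`` are drawn from a right-skewed beta family
whose mean is matched to the prevalence (Bayes consistency: the mean of the
posterior must equal the prior), and the condition label is drawn
Bernoulli(p), so calibration holds by construction.  The default shape
parameter ``a = 0.8`` gives a right-skewed density qualitatively like
classifier output on a mostly-viral cohort; it is a convention of this
package, not an estimate from the clinical data.

``cohort_pipeline`` then mirrors the published analysis shape:
posterior samples -> smoothed density (logit-KDE + 1e-4 floor) -> threshold
profile -> minimal stable threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coarsening import min_stable_threshold, threshold_profile
from .signal_models import SignalDistribution, make_beta, make_empirical

__all__ = ["CohortConfig", "CohortReport", "generate_cohort",
           "estimate_signal_density", "cohort_pipeline"]

#: Cohort size and bacterial-pneumonia prevalence of the emulated dataset.
DEFAULT_N = 1202
DEFAULT_PREVALENCE = 235 / 1202

#: Beta shape parameter of the default right-skewed posterior family.
DEFAULT_SHAPE_A = 0.8


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for a synthetic cohort."""

    n: int = DEFAULT_N
    prevalence: float = DEFAULT_PREVALENCE
    seed: int = 0
    shape_a: float = DEFAULT_SHAPE_A

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie strictly inside (0, 1)")
        if self.shape_a <= 0:
            raise ValueError("shape parameter must be positive")

    def posterior_family(self) -> SignalDistribution:
        """Beta(a, b) with b solved so that the mean equals the prevalence."""
        a = self.shape_a
        b = a * (1.0 - self.prevalence) / self.prevalence
        return make_beta(a, b)


@dataclass
class CohortReport:
    """Artifacts of the synthetic-cohort coarsening pipeline."""

    config: CohortConfig
    cohort: pd.DataFrame
    density: SignalDistribution
    profile: pd.DataFrame
    min_stable_T: float | None
    analytic_min_stable_T: float | None = None

    def summary(self) -> dict:
        return {
            "n": self.config.n,
            "prevalence": self.config.prevalence,
            "seed": self.config.seed,
            "posterior_mean": float(self.cohort["p"].mean()),
            "label_B_count": int((self.cohort["label"] == "B").sum()),
            "estimated_E_p": float(self.density.mean),
            "min_stable_T": self.min_stable_T,
            "analytic_min_stable_T": self.analytic_min_stable_T,
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(outdir / "cohort.csv", index=False,
                           float_format="%.12g")
        self.profile.to_csv(outdir / "profile.csv", index=False,
                            float_format="%.12g")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic cohort: columns ``id``, ``p`` (true posterior), ``label``.

    Posteriors come from the mean-matched beta family; labels are
    Bernoulli(p), so the expected label frequency equals the prevalence and
    calibration within posterior bins holds by construction.
    """
    fam = config.posterior_family()
    rng = np.random.default_rng(config.seed)
    p = np.asarray(fam.ppf(rng.uniform(size=config.n)), dtype=float)
    # keep strictly inside (0,1) for downstream logit smoothing
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    labels = np.where(rng.uniform(size=config.n) < p, "B", "N")
    return pd.DataFrame({"id": np.arange(config.n), "p": p, "label": labels})


def estimate_signal_density(records: pd.DataFrame,
                            floor_const: float = 1e-4) -> SignalDistribution:
    """Smoothed signal density from a cohort's posterior column."""
    return make_empirical(records["p"].to_numpy(), floor_const=floor_const)


def cohort_pipeline(config: CohortConfig, grid_size: int = 999,
                    tol: float = 1e-6, outdir=None) -> CohortReport:
    """Generate -> smooth -> profile -> minimal stable threshold.

    Also computes the analytic minimal stable threshold of the *generating*
    beta family as the recovery target.  Writes CSV/JSON artifacts when
    ``outdir`` is given.
    """
    cohort = generate_cohort(config)
    density = estimate_signal_density(cohort)
    grid = np.linspace(0.0, 1.0, grid_size + 2)[1:-1]
    profile = threshold_profile(density, grid)
    min_T = min_stable_threshold(density, tol=tol)
    analytic = min_stable_threshold(config.posterior_family(), tol=tol)
    report = CohortReport(config=config, cohort=cohort, density=density,
                          profile=profile, min_stable_T=min_T,
                          analytic_min_stable_T=analytic)
    if outdir is not None:
        report.write(outdir)
    return report
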