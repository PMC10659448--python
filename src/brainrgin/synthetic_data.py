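"""Synthetic cohorts of FNC-like graphs with a planted, recoverable signal.

The generator emulates the *shape* of an ICA-derived resting-state
cohort — 53 ROIs organised into 7 functional communities, one Pearson
correlation matrix per subject, a continuous cognitive-style score, and
nuisance covariates (age, acquisition site) — without any claim of
hemodynamic realism.  It exists so that graph construction, training,
evaluation and salient-ROI recovery are all exercisable end to end.

Generative model (per subject ``m``):

* each community ``c`` has a latent factor time course ``f_c(t)``; ROI
  ``i`` in community ``c`` emits ``y_i = lam * f_c + noise`` so that
  within-community correlations are ``lam^2`` and between-community
  correlations are 0 — a block-structured, positive-semidefinite
  correlation model by construction.
* a small *planted* set of ROIs (default 5, in 5 different communities)
  additionally loads on a shared coupling factor ``g(t)`` with
  subject-specific loading ``sqrt(u_m)``, so every planted-planted pair
  has model correlation ``u_m``.  The coupling level ``u_m`` is uniform
  on ``coupling_range`` and *is* the latent trait: the true score is
  ``effect_size * u_m``.
* the observed score adds a linear age effect, additive site offsets and
  Gaussian noise; covariates are emitted alongside so that
  residualisation can remove them again.

Time series are drawn from this factor model and the empirical Pearson
matrix is computed through :mod:`brainrgin.graph_construction`, so the
planted signal lives in the *edge weights* — exactly the channel the
edge-weighted convolution can exploit — and FNC matrices are valid
correlation matrices with realistic sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .graph_construction import FNCMatrix, ROITimeSeries, build_graph, compute_fnc
from .model_pipeline import GraphBatch, SplitDataset, residualize_scores

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "oracle_predictor",
    "default_split",
    "to_split_dataset",
]


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort.

    Defaults model a mid-sized single-session cohort: 600 subjects,
    53 ROIs in 7 communities, 200 time points, 5 planted ROIs whose
    mutual connectivity carries the trait.  ``coupling_range`` is the
    range of planted-pair correlations across subjects; ``effect_size``
    converts the coupling level into score units; ``noise_sd`` is the
    score noise (same units), set so that the planted-connectivity
    oracle reaches a test correlation of about 0.7.
    """

    n_subjects: int = 600
    n_rois: int = 53
    n_communities: int = 7
    t_points: int = 200
    planted_rois: tuple[int, ...] = (2, 10, 18, 26, 40)
    effect_size: float = 10.0
    noise_sd: float = 1.35
    within_loading: float = 0.6
    coupling_range: tuple[float, float] = (0.05, 0.55)
    age_range: tuple[float, float] = (9.0, 11.0)
    age_slope: float = 1.0
    site_offsets: tuple[float, ...] = (0.0, 0.8, -0.5, 0.4)
    seed: int = 0

    def __post_init__(self):
        if not all(0 <= r < self.n_rois for r in self.planted_rois):
            raise ValueError("planted ROIs must lie in [0, n_rois)")
        if len(set(self.planted_rois)) != len(self.planted_rois):
            raise ValueError("planted ROIs must be distinct")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.coupling_range
        if not (0.0 <= lo < hi < 1.0):
            raise ValueError("coupling_range must satisfy 0 <= lo < hi < 1")
        if self.within_loading**2 + hi >= 1.0:
            raise ValueError(
                "within_loading^2 + max coupling must stay below 1 "
                "(unit-variance factor model would break)"
            )
        if self.t_points < 3:
            raise ValueError("need at least 3 time points")

    def communities(self) -> list[np.ndarray]:
        """ROI membership of each community (near-equal contiguous blocks)."""
        return np.array_split(np.arange(self.n_rois), self.n_communities)

    def community_of(self) -> np.ndarray:
        labels = np.empty(self.n_rois, dtype=np.int64)
        for c, members in enumerate(self.communities()):
            labels[members] = c
        return labels


@dataclass
class SyntheticCohort:
    """Generated subjects plus the ground truth that created them."""

    config: SyntheticConfig
    timeseries: list[ROITimeSeries]
    coupling: np.ndarray  # u_m, the latent trait per subject
    true_scores: np.ndarray  # effect_size * u_m
    observed_scores: np.ndarray  # + covariate effects + noise
    covariates: pd.DataFrame  # columns: age (years), site (categorical)
    planted_rois: tuple[int, ...]
    seed: int
    _fnc_cache: list[FNCMatrix] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.timeseries)

    @property
    def subject_ids(self) -> list[str]:
        return [ts.subject_id for ts in self.timeseries]

    def fnc_matrices(self) -> list[FNCMatrix]:
        """Empirical Pearson FNC per subject (computed once, cached)."""
        if self._fnc_cache is None:
            self._fnc_cache = [compute_fnc(ts) for ts in self.timeseries]
        return self._fnc_cache


def generate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Draw a cohort from the factor model; bit-reproducible from
    ``(config, seed)`` (a single generator drives every draw)."""
    rng = np.random.default_rng(cfg.seed)
    lam = cfg.within_loading
    lo, hi = cfg.coupling_range
    community = cfg.community_of()
    planted = np.array(cfg.planted_rois, dtype=np.int64)
    is_planted = np.zeros(cfg.n_rois, dtype=bool)
    is_planted[planted] = True

    n, t = cfg.n_subjects, cfg.t_points
    coupling = rng.uniform(lo, hi, size=n)
    ages = rng.uniform(*cfg.age_range, size=n)
    sites = rng.integers(0, len(cfg.site_offsets), size=n)
    score_noise = rng.normal(0.0, cfg.noise_sd, size=n)

    timeseries = []
    for m in range(n):
        factors = rng.normal(size=(cfg.n_communities, t))
        g = rng.normal(size=t)
        eps = rng.normal(size=(cfg.n_rois, t))
        gamma = np.sqrt(coupling[m])
        load_g = np.where(is_planted, gamma, 0.0)
        resid_sd = np.sqrt(1.0 - lam**2 - load_g**2)
        values = (
            lam * factors[community]
            + load_g[:, None] * g
            + resid_sd[:, None] * eps
        )
        timeseries.append(ROITimeSeries(values, subject_id=f"sub-{m:04d}"))

    true_scores = cfg.effect_size * coupling
    age_mid = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    observed = (
        true_scores
        + cfg.age_slope * (ages - age_mid)
        + np.asarray(cfg.site_offsets)[sites]
        + score_noise
    )
    covariates = pd.DataFrame(
        {"age": ages, "site": [f"site_{s}" for s in sites]}
    )
    return SyntheticCohort(
        config=cfg,
        timeseries=timeseries,
        coupling=coupling,
        true_scores=true_scores,
        observed_scores=observed,
        covariates=covariates,
        planted_rois=tuple(cfg.planted_rois),
        seed=cfg.seed,
    )


def planted_connectivity(cohort: SyntheticCohort) -> np.ndarray:
    """Mean empirical correlation over all planted-planted ROI pairs,
    one value per subject — the sufficient statistic of the trait."""
    planted = np.array(cohort.planted_rois)
    ii, jj = np.triu_indices(len(planted), k=1)
    rows, cols = planted[ii], planted[jj]
    return np.array(
        [fnc.values[rows, cols].mean() for fnc in cohort.fnc_matrices()]
    )


def default_split(n: int) -> dict[str, np.ndarray]:
    """Deterministic 4:1:1 subject split (400/100/100 at the default 600).

    Subjects are exchangeable by construction, so contiguous blocks are
    an unbiased split and keep the assignment independent of any seed.
    """
    n_val = n // 6
    n_test = n // 6
    n_train = n - n_val - n_test
    idx = np.arange(n)
    return {
        "train": idx[:n_train],
        "val": idx[n_train : n_train + n_val],
        "test": idx[n_train + n_val :],
    }


def oracle_predictor(
    cohort: SyntheticCohort,
    split: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Upper-bound reference: regress the (residualised) score on the
    mean planted-pair connectivity.

    The fit uses the training subjects only; the reported
    ``test_pearson_r`` is the ceiling against which a trained network on
    the same split is judged.  Returns per-subject estimates and a dict
    with slope, intercept and train/test correlations.
    """
    split = split or default_split(len(cohort))
    feature = planted_connectivity(cohort)
    target = residualize_scores(
        cohort.observed_scores, cohort.covariates, split["train"]
    )
    tr = split["train"]
    slope, intercept = np.polyfit(feature[tr], target[tr], deg=1)
    estimates = slope * feature + intercept

    def _r(idx):
        return float(np.corrcoef(estimates[idx], target[idx])[0, 1])

    info = {
        "slope": float(slope),
        "intercept": float(intercept),
        "train_pearson_r": _r(split["train"]),
        "test_pearson_r": _r(split["test"]),
    }
    return estimates, info


def to_split_dataset(
    cohort: SyntheticCohort,
    keep_percent: float = 100.0,
    split: dict[str, np.ndarray] | None = None,
) -> SplitDataset:
    """Graphs + residualised scores, packaged for the training loop.

    Residualisation (age + site OLS) is fitted on the training subjects
    only and applied to all, matching how a real cohort is handled.
    """
    split = split or default_split(len(cohort))
    graphs = [build_graph(fnc, keep_percent) for fnc in cohort.fnc_matrices()]
    residual = residualize_scores(
        cohort.observed_scores, cohort.covariates, split["train"]
    )
    batch = GraphBatch.from_graphs(graphs, residual)
    return SplitDataset(
        train=batch.subset(split["train"]),
        val=batch.subset(split["val"]),
        test=batch.subset(split["test"]),
    )
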