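"""Synthetic cohort generator for the uncertainty analysis.

The meta-analysis population of corn silage fermentation outcomes is
non-normal for every metric, so each metric is simulated on a transformed
scale where it is approximately Gaussian: square root for lactic acid and
Box-Cox (with a stated lambda, plus a +10 shift for vcDML to make it
positive) for the others. Draws are independent normal variates with the
published transformed-space mean and SD, back-transformed to % of DM and
converted to mg/kg.

Back-transforms are undefined when lambda*y + 1 <= 0 (and, for the square
root, when y < 0); such draws are rejection-resampled with a recorded count.
The ethanol spec is the only one where this occurs at a noticeable rate
(about 0.4% of draws), so the truncation bias is negligible.

Metrics are drawn independently — the source meta-analysis publishes no
correlation structure. One master seed spawns a child stream per metric, so
results for one metric are unaffected by adding another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import boxcox as _boxcox, inv_boxcox as _inv_boxcox

from .constants import MG_PER_KG_PER_PERCENT
from .emissions import FermentationProfile

__all__ = ["TransformSpec", "TABLE_SPECS", "transform_forward",
           "transform_inverse", "generate_mock_cohort", "MockCohort"]

#: Metrics in generation order (fixed so seeds map stably to metrics).
METRICS = ("lactic", "acetic", "ammonia", "ethanol", "vcdml")


@dataclass(frozen=True)
class TransformSpec:
    """Distribution of one metric on its normalizing transformed scale.

    ``t_mean``/``t_sd`` are the mean and SD of the transformed values, on
    the % DM scale of the source data. ``shift`` is added before the
    transform (only vcDML uses it, +10, to clear negative values).
    """

    metric: str
    kind: str  # "sqrt" or "box-cox"
    t_mean: float
    t_sd: float
    lam: float | None = None
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.t_sd <= 0:
            raise ValueError(f"{self.metric}: transformed SD must be positive")
        if self.kind not in ("sqrt", "box-cox"):
            raise ValueError(f"{self.metric}: unknown transform kind {self.kind!r}")
        if self.kind == "box-cox" and self.lam is None:
            raise ValueError(f"{self.metric}: box-cox needs lambda")


#: Published per-metric transform specifications (% DM scale).
TABLE_SPECS: dict[str, TransformSpec] = {
    "lactic": TransformSpec("lactic", "sqrt", 2.27, 0.48),
    "acetic": TransformSpec("acetic", "box-cox", 0.44, 0.60, lam=0.47),
    "ammonia": TransformSpec("ammonia", "box-cox", -2.43, 1.26, lam=-0.21),
    "ethanol": TransformSpec("ethanol", "box-cox", -0.24, 0.89, lam=0.38),
    "vcdml": TransformSpec("vcdml", "box-cox", 2.95, 0.51, lam=0.18, shift=10.0),
}


def transform_forward(x, spec: TransformSpec):
    """Map raw % DM values to the transformed (approximately normal) scale."""
    x = np.asarray(x, dtype=float)
    if spec.kind == "sqrt":
        if np.any(x < 0):
            raise ValueError(f"{spec.metric}: square-root transform needs x >= 0")
        return np.sqrt(x)
    shifted = x + spec.shift
    if np.any(shifted <= 0):
        raise ValueError(f"{spec.metric}: box-cox needs x + shift > 0")
    return _boxcox(shifted, spec.lam)


def transform_inverse(y, spec: TransformSpec):
    """Map transformed values back to % DM; raises outside the domain."""
    y = np.asarray(y, dtype=float)
    if spec.kind == "sqrt":
        if np.any(y < 0):
            raise ValueError(f"{spec.metric}: inverse square root needs y >= 0")
        return y ** 2
    if np.any(spec.lam * y + 1 <= 0):
        raise ValueError(f"{spec.metric}: inverse box-cox needs lambda*y + 1 > 0")
    return _inv_boxcox(y, spec.lam) - spec.shift


def _inverse_domain_ok(y: np.ndarray, spec: TransformSpec) -> np.ndarray:
    if spec.kind == "sqrt":
        return y >= 0
    return spec.lam * y + 1 > 0


@dataclass
class MockCohort:
    """A generated cohort of synthetic fermentation profiles."""

    n: int
    seed: int
    frame_pct: pd.DataFrame  # per-metric values, % of DM
    resample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def frame(self) -> pd.DataFrame:
        """Profiles in mg per kg DM (the scale the emission equations use)."""
        return self.frame_pct * MG_PER_KG_PER_PERCENT

    def profiles(self) -> list[FermentationProfile]:
        mg = self.frame
        return [
            FermentationProfile(
                acetic=r.acetic, ethanol=r.ethanol, lactic=r.lactic,
                ammonia=r.ammonia, vcdml=r.vcdml, sample_id=f"mock-{i}",
            )
            for i, r in enumerate(mg.itertuples(index=False))
        ]


def _draw_metric(spec: TransformSpec, n: int, rng: np.random.Generator,
                 max_resample_frac: float = 0.05) -> tuple[np.ndarray, int]:
    y = rng.normal(spec.t_mean, spec.t_sd, size=n)
    resampled = 0
    bad = ~_inverse_domain_ok(y, spec)
    while bad.any():
        resampled += int(bad.sum())
        if resampled > max_resample_frac * n + 10:
            raise RuntimeError(
                f"{spec.metric}: resample fraction exceeded {max_resample_frac:.0%}; "
                "transform spec is inconsistent with its normal draw")
        y[bad] = rng.normal(spec.t_mean, spec.t_sd, size=int(bad.sum()))
        bad = ~_inverse_domain_ok(y, spec)
    return transform_inverse(y, spec), resampled


def generate_mock_cohort(specs: dict[str, TransformSpec] | None = None,
                         n: int = 1000, seed: int = 0) -> MockCohort:
    """Generate ``n`` synthetic fermentation profiles.

    Each metric is drawn independently in transformed space from its spec,
    back-transformed to % DM; draws outside the inverse-transform domain are
    resampled (counts recorded per metric; a rate above ~5% aborts).
    Metabolite values come out strictly positive; vcDML may be negative but
    is bounded below by -10% DM by the shifted transform.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if specs is None:
        specs = TABLE_SPECS
    children = np.random.SeedSequence(seed).spawn(len(METRICS))
    cols, counts = {}, {}
    for metric, child in zip(METRICS, children):
        if metric not in specs:
            continue
        rng = np.random.default_rng(child)
        cols[metric], counts[metric] = _draw_metric(specs[metric], n, rng)
    return MockCohort(n=n, seed=seed, frame_pct=pd.DataFrame(cols),
                      resample_counts=counts)
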