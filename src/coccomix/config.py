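"""Run configuration: sampler knobs and pipeline-level constants.

Two profiles are shipped for the Gibbs sampler iteration schedule:

``paper``
    500,000 iterations, 50,000 burn-in, thinning 100 — the schedule used
    for the published field samples.
``desk``
    50,000 iterations, 5,000 burn-in, thinning 10 — a ten-fold reduced
    schedule for interactive work and the test suite; posterior summaries
    agree with the long schedule well within their credible intervals for
    the sample sizes handled here.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: Count-derived Dirichlet hyperpriors used for the simulation study.
TWO_COMPONENT_ALPHA = (20.0, 80.0)
FOUR_COMPONENT_ALPHA = (10.0, 35.0, 35.0, 20.0)


@dataclass
class MixtureConfig:
    """All knobs of the count-informed normal-mixture Gibbs sampler.

    Parameters
    ----------
    k : int
        Number of mixture components (morphotypes retained in the sample).
    alpha : sequence of float
        Dirichlet hyperpriors for the component weights; for field samples
        these default to the observed SEM morphotype counts.
    iterations, burn_in, thinning, chains : int
        Iteration schedule; retained draws are every ``thinning``-th sweep
        after ``burn_in``, for each of ``chains`` independent chains.
    gamma_floor : float
        Lower clamp applied to the gamma draws of the normalised-gamma
        weight construction (avoids zero weights / infinities).
    sort_means : bool or None
        Relabel components by ascending mean at every retained draw.
        ``None`` resolves to ``k >= 3`` (no sorting for two-component
        models).
    prior_mean_location : float or None
        Common centre of the normal prior on every component mean, in
        um. The default ``None`` anchors each component's prior at the
        abundance-implied quantile of the pooled data instead (the
        midpoint quantile of the cumulative-abundance segment the
        component occupies), which is what identifies heavily
        overlapping components: it encodes the same "components are
        ordered slices of the pooled distribution" assumption that
        mean-sorting makes.
    prior_mean_precision : float or None
        Precision (1/variance) of the mean prior, in um^-2. ``None``
        (default) uses ``1 / pooled sample variance``, i.e. a prior
        standard deviation equal to the pooled spread of the data —
        informative about the scale, weak about the location within the
        data range.
    precision_shape : float
        Shape of the gamma prior on each component precision. The
        default 2 keeps the prior proper but loose (coefficient of
        variation ``1/sqrt(2)``).
    precision_rate : float or None
        Rate of the precision prior. ``None`` (default) uses
        ``precision_shape`` times the abundance-implied within-component
        variance (pooled variance minus the between-anchor variance), so
        component spreads are a priori of the order of the within-
        morphotype spread. This rules out the degenerate solution where
        a minor component inflates its variance to swallow the whole
        sample.
    """

    k: int = 2
    alpha: tuple[float, ...] = TWO_COMPONENT_ALPHA
    iterations: int = 500_000
    burn_in: int = 50_000
    thinning: int = 100
    chains: int = 3
    gamma_floor: float = 0.01
    sort_means: bool | None = None
    seed: int = 0
    prior_mean_location: float | None = None
    prior_mean_precision: float | None = None
    precision_shape: float = 2.0
    precision_rate: float | None = None

    def __post_init__(self):
        self.alpha = tuple(float(a) for a in self.alpha)
        self.validate()

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if len(self.alpha) != self.k:
            raise ValueError(
                f"alpha has length {len(self.alpha)} but k={self.k}"
            )
        if any(a <= 0 for a in self.alpha):
            raise ValueError(f"alpha entries must be > 0, got {self.alpha}")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError(
                f"burn_in ({self.burn_in}) must be < iterations "
                f"({self.iterations})"
            )
        if self.thinning < 1:
            raise ValueError(f"thinning must be >= 1, got {self.thinning}")
        if self.chains < 1:
            raise ValueError(f"chains must be >= 1, got {self.chains}")
        if self.gamma_floor <= 0:
            raise ValueError(
                f"gamma_floor must be > 0, got {self.gamma_floor}"
            )
        for name in ("prior_mean_precision", "precision_shape",
                     "precision_rate"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def resolved_sort_means(self) -> bool:
        return self.k >= 3 if self.sort_means is None else self.sort_means

    @property
    def n_retained(self) -> int:
        """Retained draws per chain."""
        span = self.iterations - self.burn_in
        return (span + self.thinning - 1) // self.thinning

    def replace(self, **changes) -> "MixtureConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def desk(cls, **overrides) -> "MixtureConfig":
        """Reduced-schedule profile for interactive and test runs."""
        base = dict(iterations=50_000, burn_in=5_000, thinning=10)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def paper_profile(cls, **overrides) -> "MixtureConfig":
        """The full 500k-iteration schedule."""
        return cls(**overrides)


@dataclass
class PipelineConfig:
    """Pipeline-level constants.

    ``outlier_multiplier`` scales the IQR in the Tukey outlier fence,
    ``rare_threshold`` is the relative-abundance floor below which a
    morphotype is dropped from the mixture, ``confidence`` the level for
    count margins of error, ``credible_mass`` the posterior interval mass
    (0.68 = the 16th-84th percentile band), ``coccoliths_per_cell`` the
    assumed coccoliths per coccosphere (minimum / mean / maximum), and
    ``calcite_density`` is in g/cm^3.
    """

    outlier_multiplier: float = 1.5
    rare_threshold: float = 0.01
    confidence: float = 0.95
    credible_mass: float = 0.68
    coccoliths_per_cell: tuple[int, ...] = (10, 23, 48)
    calcite_density: float = 2.71
    rhat_threshold: float = 1.1

    def __post_init__(self):
        self.coccoliths_per_cell = tuple(int(n) for n in self.coccoliths_per_cell)
        for name in ("rare_threshold", "confidence", "credible_mass"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.outlier_multiplier <= 0:
            raise ValueError("outlier_multiplier must be > 0")
        if self.calcite_density <= 0:
            raise ValueError("calcite_density must be > 0")
        if any(n <= 0 for n in self.coccoliths_per_cell):
            raise ValueError("coccoliths_per_cell entries must be > 0")


def load_config(path) -> tuple[PipelineConfig, MixtureConfig]:
    """Load a JSON or YAML configuration document.

    The document may contain ``pipeline`` and ``mixture`` mappings whose
    keys override the defaults; unspecified keys keep their defaults and
    unknown keys raise ``ValueError`` naming the offender. An empty
    document yields the default configuration (the full 500k iteration
    schedule).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        doc = json.loads(text) if text.strip() else {}
    else:
        doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: configuration root must be a mapping")
    unknown = set(doc) - {"pipeline", "mixture"}
    if unknown:
        raise ValueError(
            f"{path}: unknown top-level key(s): {', '.join(sorted(unknown))}"
        )
    sections = []
    for section, cls in (("pipeline", PipelineConfig),
                         ("mixture", MixtureConfig)):
        payload = doc.get(section) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - valid
        if bad:
            raise ValueError(
                f"{path}: unknown {section} key(s): {', '.join(sorted(bad))}"
            )
        if cls is MixtureConfig and "alpha" in payload and "k" not in payload:
            payload = dict(payload, k=len(payload["alpha"]))
        sections.append(cls(**payload))
    return sections[0], sections[1]
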