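"""Seedable generators for simulated thickness samples and field samples.

Two levels of synthesis are provided:

* the fixed two- and four-component simulation design used to validate
  the mixture sampler (:func:`table2_scenarios` and
  :func:`simulate_thickness_sample`), and
* full field-like samples (:func:`simulate_field_sample`) that emit
  SEM and LM measurement tables plus sample metadata with the
  correlation structure the analysis assumes: per-morphotype normal
  lengths, widths tied to length through a fixed aspect ratio,
  per-morphotype normal thickness, and LM mass computed from the
  volumetric model with multiplicative noise.

All randomness flows through ``numpy.random.default_rng(seed)``; the
same seed reproduces output exactly. Simulated thickness values are not
truncated at zero (a plain normal generator; at the means and standard
deviations used here negative draws are vanishingly rare).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import LmRecord, SampleMeta, SemRecord
from .morphometry import coccolith_mass

__all__ = [
    "Scenario",
    "table2_scenarios",
    "simulate_thickness_sample",
    "MorphotypeSpec",
    "FieldSampleSpec",
    "simulate_field_sample",
    "example_field_spec",
]


@dataclass(frozen=True)
class Scenario:
    """One row of the simulation design.

    ``n_sims`` replicate samples of size ``n`` are drawn from a
    ``k``-component normal mixture with the given weights, true
    component means (um) and common true per-component standard
    deviation ``true_sd`` (um). ``sample_sd``, when given, records the
    designed standard deviation of the pooled (mixed) sample
    distribution from which ``true_sd`` was derived.
    """

    group: int
    n_sims: int
    n: int
    k: int
    weights: tuple[float, ...]
    true_means: tuple[float, ...]
    true_sd: float
    sample_sd: float | None = None

    def __post_init__(self):
        if self.n_sims < 1 or self.n < 1:
            raise ValueError("n_sims and n must be >= 1")
        if len(self.weights) != self.k or len(self.true_means) != self.k:
            raise ValueError("weights and true_means must have length k")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if self.true_sd < 0:
            raise ValueError("true_sd must be >= 0")

    @classmethod
    def from_sample_sd(cls, group, n_sims, n, k, weights, true_means,
                       sample_sd) -> "Scenario":
        """Build a scenario whose *pooled* distribution has ``sample_sd``.

        The common component standard deviation is derived by removing
        the between-component-mean variance from the pooled variance:
        ``sd_comp = sqrt(sample_sd^2 - sum_j w_j (m_j - m_bar)^2)``.
        """
        w = np.asarray(weights, dtype=float)
        m = np.asarray(true_means, dtype=float)
        var_between = float(w @ (m - w @ m) ** 2)
        if sample_sd ** 2 < var_between:
            raise ValueError(
                "sample_sd^2 smaller than the between-mean variance"
            )
        comp_sd = float(np.sqrt(sample_sd ** 2 - var_between))
        return cls(group, n_sims, n, k, tuple(weights), tuple(true_means),
                   comp_sd, sample_sd=sample_sd)


def table2_scenarios() -> list[Scenario]:
    """The eight-group simulation design validating the sampler.

    Groups 1-4 are two-component mixtures (three replicates each, N=200);
    groups 5-8 are four-component mixtures (one replicate each, N=500).
    Groups 3-4 have both true means equal (0.110), probing the
    equal-mean degenerate case. In total 4*3 + 4*1 = 16 samples carrying
    12*2 + 4*4 = 40 simulated components.

    The designed SD (0.020 for every row) describes the pooled sample
    distribution; the common per-component standard deviation is derived
    from it (see :meth:`Scenario.from_sample_sd`), so the component SD
    equals 0.020 only in the equal-mean groups and shrinks as the
    between-mean spread grows (down to ~0.008 in group 8).
    """
    rows = [
        (1, 3, 200, 2, (0.25, 0.75), (0.100, 0.120), 0.020),
        (2, 3, 200, 2, (0.10, 0.90), (0.100, 0.120), 0.020),
        (3, 3, 200, 2, (0.25, 0.75), (0.110, 0.110), 0.020),
        (4, 3, 200, 2, (0.10, 0.90), (0.110, 0.110), 0.020),
        (5, 1, 500, 4, (0.10, 0.35, 0.35, 0.20),
         (0.085, 0.100, 0.110, 0.125), 0.02),
        (6, 1, 500, 4, (0.35, 0.10, 0.35, 0.20),
         (0.085, 0.100, 0.110, 0.125), 0.02),
        (7, 1, 500, 4, (0.35, 0.35, 0.10, 0.20),
         (0.085, 0.100, 0.110, 0.125), 0.02),
        (8, 1, 500, 4, (0.10, 0.35, 0.35, 0.20),
         (0.080, 0.100, 0.120, 0.140), 0.02),
    ]
    return [Scenario.from_sample_sd(*row) for row in rows]


def simulate_thickness_sample(
    scenario: Scenario, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one mixture sample; returns ``(values, labels)``.

    Labels are 1-based component indices drawn with the scenario
    weights; values are normal draws around the labelled component mean
    with the common true standard deviation.
    """
    rng = np.random.default_rng(seed)
    labels = rng.choice(scenario.k, size=scenario.n, p=scenario.weights) + 1
    values = rng.normal(
        np.asarray(scenario.true_means)[labels - 1], scenario.true_sd
    )
    return values, labels


@dataclass(frozen=True)
class MorphotypeSpec:
    """Per-morphotype generative parameters for a field-like sample.

    Lengths (um) are normal; widths derive from length through a fixed
    aspect ratio; thickness (um) is normal and independent of length
    within the morphotype. ``ct_l_mean/sd`` describe the central-tube
    width to length ratio and are recorded for Type A only.
    """

    proportion: float
    length_mean: float
    length_sd: float
    aspect_ratio: float
    thickness_mean: float
    thickness_sd: float
    ct_l_mean: float | None = None
    ct_l_sd: float | None = None

    def __post_init__(self):
        if not 0 <= self.proportion <= 1:
            raise ValueError("proportion must be in [0, 1]")
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1 (length axis)")
        for name in ("length_sd", "thickness_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FieldSampleSpec:
    """Full generative description of one field sample."""

    sample_id: str
    morphotypes: Mapping[str, MorphotypeSpec]
    n_coccoliths: int
    cell_density: float
    station: str = "synthetic"
    month: str = "synthetic"
    depth: float = 10.0
    mass_noise_cv: float = 0.14  # ~ relative LM mass uncertainty

    def __post_init__(self):
        total = sum(m.proportion for m in self.morphotypes.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("morphotype proportions must sum to 1")
        if self.n_coccoliths < 1:
            raise ValueError("n_coccoliths must be >= 1")
        if self.cell_density < 0:
            raise ValueError("cell_density must be >= 0")


def simulate_field_sample(
    spec: FieldSampleSpec, seed: int
) -> tuple[list[SemRecord], list[LmRecord], SampleMeta]:
    """Generate matched SEM and LM tables plus metadata for one sample.

    Each simulated coccolith receives a morphotype by the spec
    proportions; only "Overcalcified" Type A is distinguishable in the
    light microscope, so LM records carry ``central_area='overcalcified'``
    for OA and ``'open'`` otherwise. LM mass is the volumetric model of
    the generated length/width/thickness times multiplicative lognormal-
    free noise ``(1 + cv*eps)``; with ``mass_noise_cv=0`` the recorded
    mass equals the volumetric model exactly.
    """
    rng = np.random.default_rng(seed)
    morphs = list(spec.morphotypes)
    props = np.array([spec.morphotypes[m].proportion for m in morphs])
    assign = rng.choice(len(morphs), size=spec.n_coccoliths, p=props)

    sem_records: list[SemRecord] = []
    lm_records: list[LmRecord] = []
    for idx in assign:
        m = morphs[idx]
        ms = spec.morphotypes[m]
        length = max(rng.normal(ms.length_mean, ms.length_sd), 0.5)
        width = min(length / ms.aspect_ratio, length)
        thickness = max(
            rng.normal(ms.thickness_mean, ms.thickness_sd), 1e-4
        )
        ct_left = ct_right = None
        if ms.ct_l_mean is not None:
            sd = ms.ct_l_sd or 0.0
            ct_left = max(rng.normal(ms.ct_l_mean, sd), 0.0) * length
            ct_right = max(rng.normal(ms.ct_l_mean, sd), 0.0) * length
        sem_records.append(SemRecord(
            sample_id=spec.sample_id, morphotype=m,
            length=length, width=width,
            ct_left=ct_left, ct_right=ct_right,
        ))
        mass = coccolith_mass(length, width, thickness)
        if spec.mass_noise_cv > 0:
            mass = max(mass * (1 + spec.mass_noise_cv * rng.standard_normal()),
                       0.0)
        lm_records.append(LmRecord(
            sample_id=spec.sample_id, length=length, mass=mass,
            mean_thickness=thickness,
            central_area="overcalcified" if m == "OA" else "open",
        ))
    meta = SampleMeta(
        sample_id=spec.sample_id, station=spec.station, month=spec.month,
        depth=spec.depth, cell_density=spec.cell_density,
    )
    return sem_records, lm_records, meta


def example_field_spec(sample_id: str = "synthetic-coastal") -> FieldSampleSpec:
    """A field spec mimicking a January coastal sample.

    Type A dominates (77%) with Group B second (22%) and a trace of
    malformed coccoliths; sizes, thicknesses and the cell density follow
    the magnitudes typical of winter coastal *E. huxleyi* populations
    (lengths ~3.2-3.4 um, thickness ~0.10-0.13 um, SD ~0.02 um,
    ~4e4 cells/L).
    """
    return FieldSampleSpec(
        sample_id=sample_id,
        morphotypes={
            "A": MorphotypeSpec(0.77, 3.36, 0.30, 1.21, 0.131, 0.022,
                                ct_l_mean=0.07, ct_l_sd=0.01),
            "B": MorphotypeSpec(0.22, 3.18, 0.35, 1.20, 0.097, 0.018),
            "M": MorphotypeSpec(0.01, 2.77, 0.30, 1.24, 0.090, 0.018),
        },
        n_coccoliths=300,
        cell_density=41003.0,
    )
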