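"""Per-sample orchestration: preprocessing -> mixture fit -> mass/calcite.

This is the programmatic counterpart of the ``coccomix fit`` command:
it takes SEM and LM measurement records for one sample, applies outlier
removal and rare-morphotype exclusion, fits the count-informed mixture,
and combines the posterior thickness with SEM sizes into per-morphotype
mass estimates and (when metadata is available) population calcite
concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import MixtureConfig, PipelineConfig
from .io import MORPHOTYPES, LmRecord, SampleMeta, SemRecord
from .mixture import MixtureResults, NormalMixtureModel
from .morphometry import calcite_table, morphotype_mass_table
from .preprocess import relative_abundance, summarize

logger = logging.getLogger("coccomix")


@dataclass
class SampleFit:
    """Bundle of per-sample outputs."""

    sample_id: str
    counts: dict[str, int]
    abundance: pd.DataFrame
    results: MixtureResults
    mass_table: pd.DataFrame
    mean_lm_mass: float
    calcite: dict[int, float] | None

    def posterior_table(self) -> pd.DataFrame:
        table = self.results.posterior_summary().to_frame().copy()
        table.insert(0, "morphotype", self.results.component_labels())
        table.insert(0, "sample_id", self.sample_id)
        return table


def morphotype_counts(sem_records: Sequence[SemRecord]) -> dict[str, int]:
    """SEM counts per morphotype, in canonical vocabulary order."""
    counts = {m: 0 for m in MORPHOTYPES}
    for r in sem_records:
        counts[r.morphotype] += 1
    return {m: c for m, c in counts.items() if c > 0}


def fit_sample(
    sample_id: str,
    sem_records: Sequence[SemRecord],
    lm_records: Sequence[LmRecord],
    meta: SampleMeta | None = None,
    pipeline: PipelineConfig | None = None,
    mixture: MixtureConfig | None = None,
    seed: int | None = None,
) -> SampleFit:
    """Run the full per-sample analysis.

    Note that when the fit sorts component means (three or more
    morphotypes) the component-to-morphotype mapping rests on the
    count input order and is ambiguous when abundances are similar;
    the posterior table reports components with their count provenance.
    """
    pipeline = pipeline or PipelineConfig()
    sem = [r for r in sem_records if r.sample_id == sample_id]
    lm = [r for r in lm_records if r.sample_id == sample_id]
    if not sem or not lm:
        raise ValueError(f"no SEM or LM records for sample {sample_id!r}")
    counts = morphotype_counts(sem)
    thickness = [r.mean_thickness for r in lm]
    model = NormalMixtureModel.from_sample(thickness, counts,
                                           pipeline=pipeline, config=mixture)
    results = model.fit(seed=seed)

    abundance = relative_abundance(counts, pipeline.confidence)
    sem_stats = {}
    for morph in model.morphotypes:
        rows = [r for r in sem if r.morphotype == morph]
        if len(rows) >= 2:
            sem_stats[morph] = (
                summarize([r.length for r in rows], pipeline.confidence),
                summarize([r.width for r in rows], pipeline.confidence),
            )
    thickness_map = results.thickness_by_morphotype(pipeline.credible_mass)
    mass_table = morphotype_mass_table(
        sem_stats, thickness_map, pipeline.calcite_density
    )
    mean_mass = float(np.mean([r.mass for r in lm]))
    calcite = None
    if meta is not None:
        calcite = calcite_table(meta.cell_density, mean_mass,
                                pipeline.coccoliths_per_cell)
    return SampleFit(
        sample_id=sample_id, counts=counts, abundance=abundance,
        results=results, mass_table=mass_table,
        mean_lm_mass=mean_mass, calcite=calcite,
    )
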