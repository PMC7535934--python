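"""Neuroblast lineage composition model and cell-death progression metrics.

A proliferating postembryonic neuroblast (NB) lineage observed at a single
time point contains the NB itself, a pool of ganglion mother cells (GMCs),
and the neurons already produced. With the NB cycling every ~55 min, each
GMC taking ~6.5 h to divide, and ~7 GMCs present at any time, a labelled
cluster of ``n`` cells implies ``n - 1 - 7`` neurons; since each GMC
division yields two siblings, those neurons arose from ``ceil(neurons / 2)``
divisions spaced one NB cycle apart. The oldest neuron is therefore at most
``divisions x 55 min`` old — which bounds how soon after birth programmed
cell death (PCD) can have been initiated in the dying cells seen inside such
clusters.

Per-cell death staging uses a caspase-reporter readout: an intact reporter
sits at the membrane, while caspase cleavage sends one fluorophore to the
nucleus. The nuclear fraction of that fluorophore is a monotone
translocation index in [0, 1] that orders cells along the death programme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LineageModelParams",
    "CompositionEstimate",
    "StageThresholds",
    "DeathTally",
    "composition_estimate",
    "death_stage_score",
    "progression_index",
    "death_tally",
]


@dataclass(frozen=True)
class LineageModelParams:
    """Timing constants of the lineage-composition model.

    nb_cycle: neuroblast division cycle, minutes.
    gmc_cycle: ganglion-mother-cell cycle, hours (carried for completeness;
        the age bound depends only on the NB cycle and the GMC pool size).
    gmc_pool: number of GMCs present in a proliferating lineage at any time.
    neurons_per_division: progeny per GMC division (two siblings).
    """

    nb_cycle: float = 55.0
    gmc_cycle: float = 6.5
    gmc_pool: int = 7
    neurons_per_division: int = 2

    def __post_init__(self) -> None:
        if min(self.nb_cycle, self.gmc_cycle) <= 0 or self.gmc_pool <= 0 \
                or self.neurons_per_division <= 0:
            raise ValueError("all lineage model parameters must be positive")


@dataclass(frozen=True)
class CompositionEstimate:
    """Neuron count, division count and age window inferred from a cluster."""

    labelled_count: int
    n_neurons: int
    n_divisions: int
    age_upper: float  # minutes
    age_lower: float = 0.0
    flagged: bool = False  # True when no neurons are inferable

    @property
    def age_upper_hours(self) -> float:
        return self.age_upper / 60.0


def composition_estimate(labelled_count: int,
                         params: LineageModelParams | None = None
                         ) -> CompositionEstimate:
    """Infer neurons, divisions and the age window from a labelled cluster.

    neurons = labelled_count - 1 (NB) - gmc_pool; divisions = ceil(neurons/2)
    (odd counts can arise when one sibling has already died and been
    cleared); age window = [0, divisions x nb_cycle] minutes.

    Clusters of ``1 + gmc_pool`` cells or fewer carry no inferable neurons
    and come back flagged with a zero-neuron estimate.
    """
    if labelled_count < 1:
        raise ValueError("labelled_count must be >= 1")
    params = params or LineageModelParams()
    n_neurons = labelled_count - 1 - params.gmc_pool
    if n_neurons <= 0:
        return CompositionEstimate(labelled_count, 0, 0, 0.0, flagged=True)
    n_divisions = math.ceil(n_neurons / params.neurons_per_division)
    return CompositionEstimate(
        labelled_count=labelled_count,
        n_neurons=n_neurons,
        n_divisions=n_divisions,
        age_upper=n_divisions * params.nb_cycle,
    )


@dataclass(frozen=True)
class StageThresholds:
    """Translocation-index cut points separating alive / early / late death."""

    theta1: float = 0.3
    theta2: float = 0.7

    def __post_init__(self) -> None:
        if not 0 <= self.theta1 < self.theta2 <= 1:
            raise ValueError("need 0 <= theta1 < theta2 <= 1")


def death_stage_score(venus_nuclear: float, venus_membrane: float,
                      thresholds: StageThresholds | None = None
                      ) -> tuple[str, float]:
    """Score one cell: (stage, translocation index).

    index = nuclear / (nuclear + membrane); stage is ``alive`` below theta1,
    ``early-death`` in [theta1, theta2), ``late-death`` at or above theta2.
    The index is invariant to a common gain on both compartments. Cells with
    no signal in either compartment are unscorable.
    """
    thresholds = thresholds or StageThresholds()
    if venus_nuclear < 0 or venus_membrane < 0:
        raise ValueError("intensities must be non-negative")
    total = venus_nuclear + venus_membrane
    if total == 0:
        return "unscorable", float("nan")
    index = venus_nuclear / total
    if index < thresholds.theta1:
        stage = "alive"
    elif index < thresholds.theta2:
        stage = "early-death"
    else:
        stage = "late-death"
    return stage, index


def _score_snapshot(snapshot: pd.DataFrame,
                    thresholds: StageThresholds) -> pd.DataFrame:
    scored = snapshot.copy()
    stages, indices = [], []
    for _, row in scored.iterrows():
        stage, idx = death_stage_score(row["venus_nuc"], row["venus_mem"],
                                       thresholds)
        stages.append(stage)
        indices.append(idx)
    scored["stage"] = stages
    scored["translocation_index"] = indices
    return scored


def progression_index(snapshot: pd.DataFrame,
                      thresholds: StageThresholds | None = None
                      ) -> tuple[float, bool | None]:
    """Spearman correlation of (distance from NB, translocation index).

    Computed over the dying cells of one lineage snapshot (columns
    ``distance_um``, ``venus_nuc``, ``venus_mem``). A lineage "displays a
    progression" when cells further from the NB are at later death stages,
    i.e. the correlation is strictly positive. With fewer than two dying
    cells the quantity is undefined and ``(nan, None)`` is returned.
    """
    thresholds = thresholds or StageThresholds()
    scored = _score_snapshot(snapshot, thresholds)
    dying = scored[scored["stage"].isin(["early-death", "late-death"])]
    if len(dying) < 2:
        return float("nan"), None
    import warnings
    with warnings.catch_warnings():
        # constant ranks (e.g. all indices clipped at 1) mean no orderable
        # progression; the NaN result maps to False below
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(dying["distance_um"],
                              dying["translocation_index"]).statistic
    if np.isnan(rho):  # constant ranks on either axis
        return float(rho), False
    return float(rho), bool(rho > 0)


@dataclass(frozen=True)
class DeathTally:
    """Population summary of dying cells across lineage snapshots."""

    dying_per_lineage: np.ndarray
    mean: float
    sd: float
    n_lineages: int
    n_multi: int          # lineages with more than one dying cell
    n_progression: int    # of those, lineages with a distal-later progression


def death_tally(snapshots: list[pd.DataFrame],
                thresholds: StageThresholds | None = None) -> DeathTally:
    """Tally dying cells per lineage and death-stage progressions.

    ``n_progression`` counts, among lineages with >= 2 dying cells, those
    whose Spearman correlation between distance from the NB and the
    translocation index is strictly positive.
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    thresholds = thresholds or StageThresholds()
    counts = []
    n_multi = n_progression = 0
    for snap in snapshots:
        scored = _score_snapshot(snap, thresholds)
        n_dying = int(scored["stage"].isin(["early-death",
                                            "late-death"]).sum())
        counts.append(n_dying)
        if n_dying > 1:
            n_multi += 1
            _, progressed = progression_index(snap, thresholds)
            if progressed:
                n_progression += 1
    counts = np.asarray(counts)
    sd = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    return DeathTally(
        dying_per_lineage=counts,
        mean=float(counts.mean()),
        sd=sd,
        n_lineages=len(snapshots),
        n_multi=n_multi,
        n_progression=n_progression,
    )
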