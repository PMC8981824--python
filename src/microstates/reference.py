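"""Published group-level microstate statistics used to parameterize the
synthetic generator.

These are the printed summary statistics of an interictal
migraine-without-aura (MwoA) cohort (n=61) and matched healthy controls
(HC, n=66): per-class mean duration / occurrence / coverage, the 12
ordered transition percentages, and demographics.  They serve two roles:
(1) planted ground truth for parameter-recovery simulations, and (2)
worked-example inputs for the summary-statistic tests.
"""

from __future__ import annotations

import numpy as np

from .synth import SemiMarkovSpec, stationary_distribution

__all__ = [
    "MWOA",
    "HC",
    "DEMOGRAPHICS",
    "transition_matrix",
    "semimarkov_from_group",
]

# per-class (A, B, C, D): mean +/- SD
MWOA = {
    "n": 61,
    "duration_ms": np.array([65.13, 64.99, 61.44, 63.61]),
    "duration_sd": np.array([10.94, 8.23, 8.70, 10.03]),
    "occurrence_hz": np.array([3.86, 3.99, 3.70, 4.18]),
    "occurrence_sd": np.array([0.62, 0.67, 0.65, 0.62]),
    "coverage_pct": np.array([24.55, 25.41, 22.41, 27.62]),
    "coverage_sd": np.array([5.18, 4.11, 4.62, 5.15]),
    # ordered transitions, row = from, col = to, % of all transitions
    "transitions_pct": np.array(
        [
            [0.0, 7.92, 7.00, 8.67],
            [8.06, 0.0, 7.38, 8.88],
            [6.99, 7.30, 0.0, 8.24],
            [8.53, 9.14, 8.15, 0.0],
        ]
    ),
}

HC = {
    "n": 66,
    "duration_ms": np.array([68.06, 64.74, 69.45, 67.25]),
    "duration_sd": np.array([8.50, 9.67, 11.52, 9.68]),
    "occurrence_hz": np.array([3.83, 3.72, 4.04, 3.76]),
    "occurrence_sd": np.array([0.70, 0.62, 0.51, 0.55]),
    "coverage_pct": np.array([25.51, 23.64, 27.30, 23.56]),
    "coverage_sd": np.array([4.81, 4.52, 4.82, 4.45]),
    "transitions_pct": np.array(
        [
            [0.0, 7.42, 8.58, 7.92],
            [7.33, 0.0, 8.54, 7.29],
            [8.71, 8.51, 0.0, 8.29],
            [7.88, 7.34, 8.36, 0.0],
        ]
    ),
}

DEMOGRAPHICS = {
    # group: (n, n_female, age mean, age sd, MoCA mean, MoCA sd)
    "MwoA": {"n": 61, "n_female": 50, "age": (32.79, 6.83), "moca": (28.18, 1.12)},
    "HC": {"n": 66, "n_female": 50, "age": (31.44, 4.63), "moca": (28.50, 0.90)},
    "hit6": (65.85, 6.91),
}


def transition_matrix(group: dict) -> np.ndarray:
    """Row-normalized embedded transition matrix from the printed 12 cells."""
    cells = group["transitions_pct"]
    return cells / cells.sum(axis=1, keepdims=True)


def semimarkov_from_group(group: dict, duration_shape: float = 2.0) -> SemiMarkovSpec:
    """Semi-Markov spec planting a group's printed durations and syntax.

    The embedded chain is the row-normalized transition table and the
    segment weights are its stationary distribution, so the planted
    coverages/occurrences are emergent from durations + syntax (they land
    within a few percent of the printed per-class values).
    """
    P = transition_matrix(group)
    weights = stationary_distribution(P)
    return SemiMarkovSpec(
        mean_durations=group["duration_ms"],
        segment_weights=weights,
        embedded_transitions=P,
        duration_shape=duration_shape,
    )
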