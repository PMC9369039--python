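"""Shared fixtures: deterministic shapes and session-scoped synthetic cohorts."""

import numpy as np
import pytest

from lesionshape import synthetic as syn
from lesionshape.asymmetry import asymmetry_index
from lesionshape.pipeline import descriptor_table


def radial_shape(amplitudes, phases, n=300, aspect=1.0):
    """Star-shaped outline r(theta) = ellipse * (1 + sum a_k cos(k theta + p_k))."""
    theta = 2 * np.pi * np.arange(n) / n
    r = aspect / np.sqrt(np.cos(theta) ** 2 + (aspect * np.sin(theta)) ** 2)
    for k, (a, p) in enumerate(zip(amplitudes, phases), start=2):
        r = r * (1 + a * np.cos(k * theta + p))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


@pytest.fixture
def irregular_outline():
    """A fixed asymmetric, irregular outline used across modules."""
    return radial_shape([0.08, 0.05, 0.03], [1.0, 2.2, 0.4], aspect=1.4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


class CohortData:
    def __init__(self, records, n_harmonics=12):
        self.records = records
        self.labels = np.array([r.label for r in records])
        self.outlines = [r.outline for r in records]
        self.malignant = np.isin(self.labels, syn.MALIGNANT_CLASSES)
        desc, coeffs, alphas = descriptor_table(
            list(range(len(records))), self.outlines, n_harmonics)
        self.descriptors = desc.to_numpy()
        self.coeffs = coeffs
        self.alphas = alphas
        self.asymmetry = np.array(
            [asymmetry_index(o).index for o in self.outlines])


@pytest.fixture(scope="session")
def default_cohort():
    """Default-preset cohort at the scaled-down study size (n = 202)."""
    records = syn.generate_cohort(syn.small_cohort_spec(seed=0))
    return CohortData(records)


@pytest.fixture(scope="session")
def separated_cohort():
    """Well-separated cohort (amplified irregularity contrast), n = 300."""
    spec = syn.small_cohort_spec(n_ben=150, n_bcc=70, n_iec=40, n_scc=40,
                                 seed=1, presets=syn.SEPARATED_PRESETS)
    return CohortData(syn.generate_cohort(spec))
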