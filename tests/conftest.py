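import numpy as np
import pytest

from hrvtriage.simulate import CohortSpec, TachogramSpec, make_cohort, make_tachogram


def match_beats(detected_s: np.ndarray, truth_s: np.ndarray, tol_s: float = 0.04):
    """Greedy one-to-one matching of detected beat times to ground truth.

    Returns (n_matched, n_false_positive).
    """
    detected_s = np.asarray(detected_s, dtype=float)
    truth_s = np.asarray(truth_s, dtype=float)
    used = np.zeros(truth_s.size, dtype=bool)
    matched = 0
    fp = 0
    for d in detected_s:
        if truth_s.size:
            j = int(np.argmin(np.abs(truth_s - d) + 1e9 * used))
            if not used[j] and abs(truth_s[j] - d) <= tol_s:
                used[j] = True
                matched += 1
                continue
        fp += 1
    return matched, fp


@pytest.fixture(scope="session")
def standard_tachogram():
    """A 5-minute mixed LF/HF tachogram with mild jitter."""
    rr, truth = make_tachogram(TachogramSpec(seed=7))
    return rr, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A quick 120-patient cohort at 10% prevalence for model unit tests."""
    return make_cohort(CohortSpec(n=120, prevalence=0.10, seed=11))
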