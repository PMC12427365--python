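import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from survscan import ClinicalTable, CutpointScanResult

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_cohort():
    """Ten samples with mixed censoring and tied times."""
    time = np.array([3.0, 5.0, 5.0, 7.0, 2.0, 9.0, 9.0, 4.0, 6.0, 8.0])
    event = np.array([1, 0, 1, 1, 1, 0, 1, 0, 1, 0])
    clin = ClinicalTable(tuple(f"S{i}" for i in range(10)), time, event)
    return clin


def make_scan_result(
    gene_id,
    best_p=0.5,
    observed_high=1.0,
    expected_high=2.0,
    excluded=False,
    reason=None,
    prognostic=False,
    direction="none",
):
    """Minimal CutpointScanResult for tests that feed combine_cohorts directly."""
    return CutpointScanResult(
        gene_id=gene_id,
        excluded=excluded,
        exclude_reason=reason,
        best_cutoff=math.nan if excluded else 1.0,
        best_p=math.nan if excluded else best_p,
        n_high=0 if excluded else 10,
        n_low=0 if excluded else 10,
        observed_high=observed_high,
        expected_high=expected_high,
        direction=direction,
        prognostic=prognostic,
        n_cutoffs_scanned=0 if excluded else 5,
    )
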