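import numpy as np
import pandas as pd
import pytest

from trajvuln import LongCohort


@pytest.fixture
def toy_cohort() -> LongCohort:
    """Three subjects with mixed missingness over the default schedule."""
    rows = [
        ("s1", "BASELINE", 0.0), ("s1", "POST_INT1", 1.5), ("s1", "M6", 2.0), ("s1", "M12", 1.0),
        ("s2", "BASELINE", 2.0), ("s2", "M6", np.nan), ("s2", "M12", 3.0),
        ("s3", "BASELINE", np.nan), ("s3", "POST_INT1", 3.0),
    ]
    return LongCohort(pd.DataFrame(rows, columns=["subject", "timepoint", "pain"]))


@pytest.fixture
def two_level_cohort() -> LongCohort:
    """Six subjects, two visits, two well-separated constant pain levels.

    Values are fixed literals so grid-search oracles can be frozen against
    them: three subjects near 0.5 and three near 5.
    """
    rows = []
    levels = {
        "a": (0.4, 0.6), "b": (0.5, 0.3), "c": (0.7, 0.5),
        "d": (4.8, 5.2), "e": (5.0, 5.1), "f": (5.3, 4.9),
    }
    for sid, (y0, y1) in levels.items():
        rows.append((sid, "BASELINE", y0))
        rows.append((sid, "M6", y1))
    return LongCohort(pd.DataFrame(rows, columns=["subject", "timepoint", "pain"]))
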