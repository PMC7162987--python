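import numpy as np
import pytest

import vibropsych as vp


@pytest.fixture
def sdt_short():
    """The short static-detection task spec (24 trials, start 20, step 2, floor 2)."""
    return next(s for s in vp.default_battery("short") if s.task_id == "sDT")


@pytest.fixture
def tiny_study():
    """A small deterministic trial-level study (4 subjects)."""
    cfg = vp.StudyConfig(n_subjects=4, seed=42)
    return cfg, vp.run_study(cfg)


def make_tidy(matrix, task="sDT", measure="threshold", units="um"):
    """Tidy measures table from a subjects x 3 matrix (columns = versions)."""
    import pandas as pd

    matrix = np.asarray(matrix, float)
    rows = []
    for i, row in enumerate(matrix, start=1):
        for j, v in enumerate(row, start=1):
            rows.append({
                "subject_id": i, "session_index": j,
                "version": ("Short1", "Short2", "Long")[j - 1],
                "task": task, "measure": measure, "value": v, "units": units,
            })
    return pd.DataFrame(rows)
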