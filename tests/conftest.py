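import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dkdprot.io import GroupDesign, MasterTable

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture
def small_design() -> GroupDesign:
    return GroupDesign(
        groups={
            "case": ("c1", "c2", "c3", "c4"),
            "ctrl": ("w1", "w2", "w3", "w4"),
        }
    )


@pytest.fixture
def small_raw_table(small_design) -> MasterTable:
    """4 proteins x 8 samples; P4 undetected in the case group."""
    rng = np.random.default_rng(7)
    samples = small_design.all_samples()
    data = pd.DataFrame(
        rng.lognormal(10, 0.2, size=(4, 8)),
        index=["P1", "P2", "P3", "P4"],
        columns=samples,
    )
    data.loc["P4", ["c1", "c2", "c3", "c4"]] = np.nan
    return MasterTable(data=data, normalized=False)


def write_report(path, rows, header="accession\tdescription\tintensity"):
    lines = [header] + ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
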