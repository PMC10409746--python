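import numpy as np
import pandas as pd
import pytest

from dropoutkeys.types import AbundanceTable, CommunityDesign, StrainInfo


@pytest.fixture
def small_roster() -> CommunityDesign:
    """Three-strain roster with distinct 16S copy numbers and DTLs."""
    return CommunityDesign(
        (
            StrainInfo("S1", "Strain one", 5, 10.0),
            StrainInfo("S2", "Strain two", 3, 20.0),
            StrainInfo("S3", "Strain three", 7, 5.0),
        )
    )


def build_table(values: dict, censored: dict | None = None) -> AbundanceTable:
    """AbundanceTable from {(community, strain): [replicate values]}.

    All samples share one environment "E"; replicate k of a community
    becomes well k (bio = k//3+1, tech = k%3+1).
    """
    censored = censored or {}
    data, samples, seen = [], [], set()
    for (comm, strain), vals in values.items():
        cens = censored.get((comm, strain), [False] * len(vals))
        for k, (v, c) in enumerate(zip(vals, cens)):
            sid = f"E.{comm}.w{k + 1}"
            if sid not in seen:
                seen.add(sid)
                samples.append(
                    {
                        "sample_id": sid,
                        "community": comm,
                        "environment": "E",
                        "bio_replicate": k // 3 + 1,
                        "tech_replicate": k % 3 + 1,
                        "amount": 1.0,
                        "amount_unit": "ml",
                    }
                )
            data.append(
                {"sample_id": sid, "strain_id": strain, "value": 0.0 if c else v, "censored": c}
            )
    return AbundanceTable(pd.DataFrame(data), pd.DataFrame(samples))
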