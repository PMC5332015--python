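import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lpscreen import io, pipeline, simulate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_screen():
    """A 320-gene single-plate-ish primary screen with planted truth."""
    cfg = simulate.GeneratorConfig(n_genes=300, seed=42)
    return simulate.generate_screen(cfg)


@pytest.fixture(scope="session")
def small_result(small_screen):
    ds, _ = small_screen
    return pipeline.run_primary(ds)


def make_plate(
    sample_values,
    ntc_values=(),
    plate="P01",
    readout="NFKB",
    extra_roles=(),
    design="primary",
):
    """Hand-build a minimal one-plate dataset from explicit well values.

    ``extra_roles`` is a sequence of (role, value) pairs for single
    control wells.  Both replicates carry the same value unless a pair is
    given.
    """
    rows = []
    addrs = iter(io.all_addresses())

    def add(role, value, gene=None):
        v1, v2 = value if isinstance(value, tuple) else (value, value)
        a = next(addrs)
        rows.append(
            {
                "PlateID": plate,
                "Well": a,
                "WellAnno": role,
                "GeneSymbol": gene,
                "EntrezID": 1 if gene else pd.NA,
                "siRNAID": f"s-{a}" if role == "sample" else None,
                "Readout": readout,
                "Rep1Value": v1,
                "Rep2Value": v2,
                "Rep1CellCount": 300,
                "Rep2CellCount": 300,
            }
        )

    for i, v in enumerate(sample_values):
        add("sample", v, gene=f"G{i}")
    for v in ntc_values:
        add("NTC2", v)
    for role, v in extra_roles:
        add(role, v)
    return io.new_dataset(pd.DataFrame(rows), design)
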