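import numpy as np
import pandas as pd
import pytest

from acetdyn import assoc, islands, profiles, synthdata


def small_config(**overrides) -> synthdata.SimConfig:
    base = dict(n_genes=600, n_control_probes=400, frac_up=0.05,
                frac_down=0.05, frac_esc=0.03, seed=11)
    base.update(overrides)
    return synthdata.SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset() -> synthdata.SimDataset:
    """One moderately sized dataset shared across test modules."""
    return synthdata.generate(small_config())


@pytest.fixture(scope="session")
def small_null(small_dataset):
    return islands.fit_null(small_dataset.probe_table)


@pytest.fixture(scope="session")
def small_binned(small_dataset, small_null):
    return profiles.bin_all(small_dataset.probe_table, small_null)


@pytest.fixture(scope="session")
def small_changes(small_dataset, small_binned):
    return assoc.build_changes(small_binned, small_dataset.expr_table)


def probe_rows(entries):
    """Helper: build a probe table from (probe, gene, offset, day, rep, signal)."""
    return pd.DataFrame(
        entries,
        columns=["probe_id", "gene_id", "offset_bp", "day", "replicate", "signal"],
    )


def control_rows(n, days, loc=0.0, scale=1.0, seed=0, replicates=1):
    rng = np.random.default_rng(seed)
    rows = []
    for day in days:
        for rep in range(1, replicates + 1):
            sig = rng.normal(loc, scale, size=n)
            rows.append(pd.DataFrame({
                "probe_id": [f"c{i:05d}" for i in range(n)],
                "gene_id": np.nan,
                "offset_bp": np.nan,
                "day": day,
                "replicate": rep,
                "signal": sig,
            }))
    return pd.concat(rows, ignore_index=True)
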