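"""Shared fixtures: hand-built call matrices and a small synthetic species."""

import numpy as np
import pandas as pd
import pytest

from clademix.basecalls import BaseCallMatrix, COUNT_COLUMNS

CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def matrix_from_strings(rows: dict) -> BaseCallMatrix:
    """Build a BaseCallMatrix directly from genome -> call-string mappings."""
    genomes = list(rows)
    calls = np.array([[CODE[ch] for ch in rows[g]] for g in genomes], dtype=np.int8)
    P = calls.shape[1]
    return BaseCallMatrix(
        genomes=genomes,
        positions=np.arange(P),
        calls=calls,
        genome_median_coverage=np.full(len(genomes), 20.0),
        position_median_coverage=np.full(P, 20.0),
        provenance=[{"event": "test_fixture"}],
    )


def counts_frame(calls: dict, depth: int = 20, depth_overrides: dict = None) -> pd.DataFrame:
    """Count table realizing given calls: `depth` clean reads split across strands.

    ``depth_overrides`` maps (genome, pos) -> total depth for that cell.
    """
    depth_overrides = depth_overrides or {}
    rows = []
    for g, s in calls.items():
        for pos, ch in enumerate(s):
            d = depth_overrides.get((g, pos), depth)
            fwd = [0, 0, 0, 0]
            rev = [0, 0, 0, 0]
            if ch != "N":
                fwd[CODE[ch]] = d - d // 2
                rev[CODE[ch]] = d // 2
            rows.append((g, "ref", pos, *fwd, *rev, -60.0, 0.0))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


@pytest.fixture(scope="session")
def small_species():
    from clademix.simulate import simulate_species

    return simulate_species(n_tips=12, mutation_scale=1500, seed=1)


@pytest.fixture(scope="session")
def small_db(small_species):
    from clademix.clades import build_database

    return build_database(small_species.to_basecall_matrix(), small_species.model)
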