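"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pandas as pd
import pytest

from pbmspec import DesignSpec, IntensityTable, generate_probe_set


def brute_force_escore(values, fg, bg):
    """Independent E-score oracle: literal rank-and-enumerate implementation.

    Ranks fg+bg by intensity descending (probe-id order breaks ties when
    halving), keeps the top ceil(n/2) of each set, and counts fg'-above-bg'
    pairs explicitly, ties as 1/2.  Deliberately naive; used only to check
    the package's implementations.
    """
    fg, bg = list(fg), list(bg)
    if not fg or not bg:
        return math.nan

    def top_half(members):
        ranked = sorted(members, key=lambda pid: (-values[pid], pid))
        return ranked[:math.ceil(len(ranked) / 2)]

    fg_top, bg_top = top_half(fg), top_half(bg)
    U = 0.0
    for f in fg_top:
        for b in bg_top:
            if values[f] > values[b]:
                U += 1.0
            elif values[f] == values[b]:
                U += 0.5
    return U / (len(fg_top) * len(bg_top)) - 0.5


@pytest.fixture(scope="session")
def small_probe_set():
    """A 400-probe array with a modest coverage floor; shared read-only."""
    return generate_probe_set(DesignSpec("SM", n_probes=400, variable_len=35,
                                         min_kmer_coverage=0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


def random_intensities(probes, rng, assay_id="assay"):
    vals = rng.lognormal(mean=7.0, sigma=0.5, size=len(probes))
    return IntensityTable(assay_id, probes.design_id,
                          pd.Series(vals, index=probes.ids))
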