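"""Packaged printed-table fixtures.

Three small TSVs ship with the package: the per-period modern/ancient
mutation-difference summary (per macrohaplogroup and pooled, with the
strict-clock expectation), the collection of published mtDNA evolutionary
rates with the two rates estimated here, and the haplogroup coalescence
ages under the two clock calibrations.  They serve as desk-check inputs for
the arithmetic engines; the synthetic generator stands in for the underlying
sequence data, which is not redistributed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    path = resources.files("mitotempo.data") / name
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", na_values=["NA"])


def load_period_differences() -> pd.DataFrame:
    """Per-period difference summary: mean ages, per-macrohaplogroup mean/sd/n,
    pooled observed mean and the strict-clock expected column."""
    return _load("table1_differences.tsv")


def load_published_rates() -> pd.DataFrame:
    """Published and newly estimated per-site evolutionary rates (x 1e-8/site/yr)."""
    return _load("table2_rates.tsv")


def load_coalescence_ages() -> pd.DataFrame:
    """Haplogroup coalescence ages (kyr) under both clocks, with prior estimates."""
    return _load("table3_ages.tsv")
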