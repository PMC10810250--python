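"""Density-decile space accounting for the compressed colors.

For each density decile (colors whose density |C|/N falls in ((i-1)*10%,
i*10%]), the report gives the percentage of colors, the percentage of
stored integers (reference ids), and the average bits per integer (bpi)
spent encoding them. The "total" row's bpi additionally charges the
Elias-Fano offset directory, so it reflects the full inverted-index space.
"""

from __future__ import annotations

import math

import pandas as pd


def decile_of(density: float) -> int:
    """1..10 for density in (0, 1]."""
    return min(10, max(1, math.ceil(density * 10)))


def stats_report(index) -> pd.DataFrame:
    store = index.color_store
    N = store.N
    lists = [0] * 10
    ints = [0] * 10
    bits = [0] * 10
    for j in range(1, store.M + 1):
        size = store.cardinality(j)
        d = decile_of(size / N)
        lists[d - 1] += 1
        ints[d - 1] += size
        bits[d - 1] += store.bit_length(j)
    total_lists = sum(lists)
    total_ints = sum(ints)
    total_bits = store.nbits + (store.offsets.bits if store.offsets else 0)
    rows = []
    for i in range(10):
        rows.append({
            "density": f"{i * 10}-{(i + 1) * 10}",
            "lists_pct": 100.0 * lists[i] / total_lists if total_lists else 0.0,
            "ints_pct": 100.0 * ints[i] / total_ints if total_ints else 0.0,
            "bpi": bits[i] / ints[i] if ints[i] else 0.0,
        })
    rows.append({
        "density": "total",
        "lists_pct": 100.0 if total_lists else 0.0,
        "ints_pct": 100.0 if total_ints else 0.0,
        "bpi": total_bits / total_ints if total_ints else 0.0,
    })
    return pd.DataFrame(rows)


def representation_census(index) -> dict[str, int]:
    """How many stored colors use each representation tag."""
    census = {"sparse": 0, "dense-complement": 0, "bitvector": 0}
    for j in range(1, index.color_store.M + 1):
        census[index.color_store.tag(j)] += 1
    return census
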