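"""Brute-force enumeration oracles for the evaluation metrics.

Kept outside the test modules so the hot exhaustive loop is not slowed by
assertion rewriting; the driver returns mismatches for the test to assert
on.  The oracles re-derive precision and the per-species FP rate by
explicit row enumeration, independent of the library implementation.
"""

from __future__ import annotations

import itertools
import math

from cabin.metrics import ConfusionMatrix, call_species, fp_rate, precision


def oracle_row_stats(row: tuple[int, ...]):
    """(majority count, called species with lowest-index ties, row sum)."""
    m = max(row)
    return m, row.index(m), sum(row)


def exhaustive_mismatches(k: int, ns: int, max_entry: int = 5) -> list:
    """Compare implementation vs enumeration on every k x ns matrix.

    Entries range over 0..max_entry; the all-zero matrix is skipped
    (rejected by the implementation).  Returns a list of offending
    matrices, empty when the implementations agree everywhere.
    """
    species = tuple(f"s{j}" for j in range(ns))
    cluster_ids = tuple(range(k))
    rows_pool = list(itertools.product(range(max_entry + 1), repeat=ns))
    stats = {row: oracle_row_stats(row) for row in rows_pool}

    mismatches = []
    isnan = math.isnan
    for rows in itertools.product(rows_pool, repeat=k):
        best = total = 0
        foreign = [0] * ns
        pooled = [0] * ns
        called = [False] * ns
        for row in rows:
            m, arg, s = stats[row]
            best += m
            total += s
            called[arg] = True
            pooled[arg] += s
            foreign[arg] += s - row[arg]
        if total == 0:
            continue

        cm = ConfusionMatrix(rows, cluster_ids, species)
        if precision(cm) != best / total:
            mismatches.append(("precision", rows))
            continue
        calls = call_species(cm)
        for s in range(ns):
            got = fp_rate(cm, calls, s)
            if not called[s] or pooled[s] == 0:
                if not isnan(got):
                    mismatches.append(("fp_nan", s, rows))
            elif got != foreign[s] / pooled[s]:
                mismatches.append(("fp", s, rows))
    return mismatches
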