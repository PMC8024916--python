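"""Genotype-activity landscape.

Assuming no interaction between the two alleles (and equal expression,
which is an explicit modelling assumption), an individual's total
enzymatic activity is the sum of the catalytic efficiencies of the two
allotypes they carry.  Combining a diplotype frequency table with a
per-allotype activity profile therefore maps the population onto an
activity-vs-frequency landscape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import ActivityProfile
from .popgen import DiplotypeTable, pair_key

logger = logging.getLogger(__name__)

#: Default substrate for the landscape: the 9mer epitope, for which
#: full catalytic-efficiency measurements are available.
DEFAULT_SUBSTRATE = "YTAFTIPSI"


def diplotype_activity(
    pair: tuple[str, str], profile: ActivityProfile, substrate: str
) -> float:
    """Total expected activity of one allotype pair: the sum of the two
    allelic values.  Raises ``KeyError`` naming a missing allotype."""
    a, b = pair
    return profile.get(a, substrate) + profile.get(b, substrate)


@dataclass
class Landscape:
    """Ranked diplotype activity/frequency table.

    ``entries`` columns: allotype_a, allotype_b, count, frequency_pct,
    activity, rank (1 = highest activity).  Carries the equal-expression
    assumption explicitly.
    """

    entries: pd.DataFrame
    spread: float  # max/min activity over observed pairs
    dropped: tuple[tuple[str, str], ...]
    substrate: str
    assumes_equal_expression: bool = True

    def scatter_frame(self) -> pd.DataFrame:
        """Activity vs population frequency, one row per pair."""
        return self.entries[
            ["allotype_a", "allotype_b", "frequency_pct", "activity"]
        ].copy()

    def bubble_frame(self) -> pd.DataFrame:
        """Pair grid (allotype x allotype) of frequencies, activity-ordered."""
        order = (
            self.entries.melt(
                id_vars="activity",
                value_vars=["allotype_a", "allotype_b"],
                value_name="allotype",
            )
            .groupby("allotype")["activity"]
            .max()
            .sort_values(ascending=False)
            .index.tolist()
        )
        grid = pd.DataFrame(0.0, index=order, columns=order)
        for row in self.entries.itertuples():
            grid.loc[row.allotype_a, row.allotype_b] = row.frequency_pct
            grid.loc[row.allotype_b, row.allotype_a] = row.frequency_pct
        return grid


def landscape_table(
    diplo: DiplotypeTable,
    profile: ActivityProfile,
    substrate: str = DEFAULT_SUBSTRATE,
) -> Landscape:
    """Attach summed allelic activities to every observed diplotype.

    Pairs containing an allotype without a profile value are dropped
    with a log note; an empty intersection is an error.
    """
    values = profile.values_for(substrate)
    rows = []
    dropped = []
    for (a, b), count in diplo.counts.items():
        if a in values.index and b in values.index:
            rows.append(
                {
                    "allotype_a": a,
                    "allotype_b": b,
                    "count": count,
                    "frequency_pct": 100.0 * count / diplo.n_samples,
                    "activity": float(values[a] + values[b]),
                }
            )
        else:
            dropped.append(pair_key(a, b))
    if not rows:
        raise ValueError("no diplotype has activity values for both alleles")
    if dropped:
        logger.info(
            "landscape(%s): dropped %d pairs lacking profile values: %s",
            substrate,
            len(dropped),
            sorted(set(dropped)),
        )
    entries = pd.DataFrame(rows).sort_values(
        "activity", ascending=False, ignore_index=True
    )
    entries["rank"] = np.arange(1, len(entries) + 1)
    spread = float(entries["activity"].max() / entries["activity"].min())
    return Landscape(
        entries=entries,
        spread=spread,
        dropped=tuple(sorted(set(dropped))),
        substrate=substrate,
    )
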