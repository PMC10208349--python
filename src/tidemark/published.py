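"""Published regional mangrove area estimates for Palawan (1988–2020).

A small reference table of observed per-region mangrove (and Palawan
non-mangrove) areas in hectares, plus the projected 2013/2030/2050 areas
from the associated Markov analysis.  These are *inputs*: the package uses
them to recompute change statistics — e.g. the 1988–1998 Puerto Princesa
City gain of +95.88% — with :func:`tidemark.change.percent_change`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .change import ChangeRecord, percent_change

__all__ = ["load_published_areas", "published_area", "published_change"]


def load_published_areas() -> pd.DataFrame:
    """The bundled area table: region, year, class, kind, area_ha."""
    with resources.files("tidemark.data").joinpath(
            "published_areas.csv").open() as fh:
        return pd.read_csv(fh)


def published_area(region: str, year: int, cls: str = "mangrove",
                   kind: str = "observed") -> float:
    df = load_published_areas()
    hit = df[(df.region == region) & (df.year == year)
             & (df["class"] == cls) & (df.kind == kind)]
    if len(hit) != 1:
        raise KeyError(f"no unique published area for "
                       f"{region}/{year}/{cls}/{kind}")
    return float(hit.area_ha.iloc[0])


def published_change(region: str, year_i: int, year_j: int,
                     cls: str = "mangrove", kind_i: str = "observed",
                     kind_j: str = "observed") -> ChangeRecord:
    """Percent change between two published areas, recomputed from the
    areas themselves."""
    return percent_change(published_area(region, year_i, cls, kind_i),
                          published_area(region, year_j, cls, kind_j))
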