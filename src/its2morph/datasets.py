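"""Bundled example survey: foliar endophytic fungi from three host plants.

A published survey of foliar endophytic fungi isolated from leaves of
*Aglaia elaeagnoidea*, *Flacourtia inermis* and *Premna serratifolia*
screened 300 leaf segments per host (75 segments per leaf region per
sampling event, two events, midrib and lamina regions) and recorded 392
isolates grouped into 98 morphotypes.  These printed sampling counts are the
worked-example inputs for the diversity statistics; raw per-isolate species
identities were not published, so only count-level statistics can be
recomputed from them.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["survey_effort", "survey_richness", "survey_shared", "HOSTS"]

HOSTS = ("A. elaeagnoidea", "F. inermis", "P. serratifolia")


def survey_effort() -> pd.DataFrame:
    """Sampling effort and isolate counts per host, event and leaf region."""
    rows = [
        # host, event, region, segments, infected segments, isolates
        (HOSTS[0], "I", "midrib", 75, 15, 17),
        (HOSTS[0], "I", "lamina", 75, 8, 8),
        (HOSTS[0], "II", "midrib", 75, 24, 24),
        (HOSTS[0], "II", "lamina", 75, 17, 17),
        (HOSTS[1], "I", "midrib", 75, 24, 31),
        (HOSTS[1], "I", "lamina", 75, 12, 13),
        (HOSTS[1], "II", "midrib", 75, 34, 39),
        (HOSTS[1], "II", "lamina", 75, 22, 22),
        (HOSTS[2], "I", "midrib", 75, 61, 69),
        (HOSTS[2], "I", "lamina", 75, 42, 44),
        (HOSTS[2], "II", "midrib", 75, 51, 61),
        (HOSTS[2], "II", "lamina", 75, 45, 47),
    ]
    return pd.DataFrame(
        rows, columns=["host", "event", "region", "segments", "infected", "isolates"]
    )


def survey_richness() -> pd.DataFrame:
    """Observed isolates (N), morphotypes and delimited species (S) per host."""
    rows = [
        (HOSTS[0], 66, 29, 21),
        (HOSTS[1], 105, 32, 20),
        (HOSTS[2], 221, 37, 23),
    ]
    return pd.DataFrame(rows, columns=["host", "isolates", "morphotypes", "species"])


def survey_shared() -> pd.DataFrame:
    """Observed shared-species counts for each host pair."""
    rows = [
        (HOSTS[0], HOSTS[1], 6),
        (HOSTS[0], HOSTS[2], 8),
        (HOSTS[1], HOSTS[2], 6),
    ]
    return pd.DataFrame(rows, columns=["first", "second", "shared_species"])
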