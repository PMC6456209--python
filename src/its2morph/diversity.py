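"""Diversity statistics for endophyte communities.

Implements the survey statistics used for foliar endophytic fungi:

* colonization frequency CF = isolates / segments screened x 100;
* endophytic infection rate EIR = infected segments / segments screened x 100;
* relative percentage of occurrence RPO = one group's colonization density
  over the total x 100;
* Shannon H' (natural log), inverse Simpson (unbiased finite-sample form
  1/D with D = sum n_i(n_i-1)/(N(N-1)); a plug-in variant is available);
* Fisher's log-series alpha, solving S = alpha ln(1 + N/alpha);
* Chao1 (bias-corrected by default) and ACE (rare cutoff 10) richness
  estimators;
* shared-species indices for a pair of communities: observed shared S,
  Chao-shared (Chao et al. 2000 form, bias-corrected denominators),
  classic Jaccard C/(S1+S2-C), abundance-based Chao-Jaccard
  (Chao et al. 2005 U/V estimators) and Bray-Curtis similarity;
* sample-based species accumulation curves by sample-order randomization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "CommunityTable",
    "SharedIndices",
    "AccumulationCurve",
    "colonization_frequency",
    "endophytic_infection_rate",
    "relative_percentage_occurrence",
    "shannon",
    "simpson_inverse",
    "fisher_alpha",
    "chao1",
    "ace",
    "shared_indices",
    "accumulation_curve",
    "host_report",
    "midrib_fold_excess",
]

REGIONS = ("midrib", "lamina")


@dataclass
class CommunityTable:
    """Isolate-level records: species, host, leaf region, sampling event,
    segment id; plus the per-host sampling effort (segments screened)."""

    isolates: pd.DataFrame  # columns: isolate, species, host, region, event, segment
    segments_per_host: Mapping[str, int]

    REQUIRED = ("isolate", "species", "host", "region", "event", "segment")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.isolates.columns]
        if missing:
            raise ValueError(f"community table missing columns: {missing}")
        bad = set(self.isolates["region"]) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown leaf regions: {sorted(bad)}")

    @property
    def hosts(self) -> list[str]:
        return sorted(self.isolates["host"].unique())

    def abundances(self, host: str) -> pd.Series:
        sub = self.isolates[self.isolates["host"] == host]
        return sub.groupby("species").size().sort_index()

    def infected_segments(self, host: str) -> int:
        sub = self.isolates[self.isolates["host"] == host]
        return sub.groupby(["event", "region", "segment"]).ngroups

    def n_isolates(self, host: str) -> int:
        return int((self.isolates["host"] == host).sum())

    def incidence(self, host: str, by: str = "event") -> pd.DataFrame:
        """Sample x species incidence (0/1) matrix for accumulation curves."""
        sub = self.isolates[self.isolates["host"] == host]
        tab = pd.crosstab(sub[by], sub["species"])
        return (tab > 0).astype(int)


def colonization_frequency(n_isolates: int, n_segments: int) -> float:
    """CF (%) = isolates recovered per 100 segments screened."""
    if n_segments <= 0:
        raise ValueError("segments screened must be positive")
    return round(100.0 * n_isolates / n_segments, 1)


def endophytic_infection_rate(n_infected_segments: int, n_segments: int) -> float:
    """EIR (%) = infected segments per 100 segments screened."""
    if n_segments <= 0:
        raise ValueError("segments screened must be positive")
    if n_infected_segments > n_segments:
        raise ValueError("infected segments cannot exceed segments screened")
    return round(100.0 * n_infected_segments / n_segments, 1)


def relative_percentage_occurrence(group_density: int, total_density: int) -> float:
    """RPO (%) of one taxon group within the total colonization density."""
    if total_density <= 0:
        raise ValueError("total density must be positive")
    if group_density > total_density:
        raise ValueError("group density cannot exceed the total")
    return 100.0 * group_density / total_density


def _abund(abundances) -> np.ndarray:
    a = np.asarray(list(abundances) if not isinstance(abundances, np.ndarray) else abundances)
    a = a[a > 0]
    if a.size == 0:
        raise ValueError("need at least one positive abundance")
    return a.astype(float)


def shannon(abundances: Sequence[int]) -> float:
    """Shannon diversity H' in nats."""
    a = _abund(abundances)
    p = a / a.sum()
    return float(-(p * np.log(p)).sum())


def simpson_inverse(abundances: Sequence[int], unbiased: bool = True) -> float:
    """Inverse Simpson index 1/D.

    Default is the unbiased finite-sample D = sum n_i(n_i-1) / (N(N-1));
    ``unbiased=False`` uses the plug-in sum p_i^2.  A single-species sample
    returns 1 (pure dominance).
    """
    a = _abund(abundances)
    N = a.sum()
    if N < 2:
        raise ValueError("need at least two individuals")
    if unbiased:
        D = float((a * (a - 1)).sum() / (N * (N - 1)))
    else:
        D = float(((a / N) ** 2).sum())
    if D == 0:  # every species a singleton: maximal evenness
        return float(a.size)
    return 1.0 / D


def fisher_alpha(S: int, N: int, tol: float = 1e-8) -> float:
    """Fisher's log-series alpha, the root of S = alpha ln(1 + N/alpha)."""
    if S < 1:
        raise ValueError("need at least one species")
    if S > N:
        raise ValueError("species count cannot exceed individuals")
    if S == N:
        raise ValueError("alpha diverges when every individual is a new species")

    def f(a: float) -> float:
        return a * math.log1p(N / a) - S

    lo, hi = 1e-10, 10.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket alpha")
    return float(brentq(f, lo, hi, xtol=tol))


def expected_species_logseries(alpha: float, N: int) -> float:
    """Expected richness of a log-series community: S = alpha ln(1 + N/alpha)."""
    return alpha * math.log1p(N / alpha)


def chao1(abundances: Sequence[int], bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts."""
    a = _abund(abundances)
    S_obs = float(a.size)
    f1 = float((a == 1).sum())
    f2 = float((a == 2).sum())
    if bias_corrected:
        return S_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    if f2 == 0:
        return S_obs + f1 * (f1 - 1) / 2.0
    return S_obs + f1 * f1 / (2 * f2)


def ace(abundances: Sequence[int], rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of species richness.

    Falls back to Chao1 when sample coverage of the rare class is zero
    (e.g. an all-singleton sample).
    """
    a = _abund(abundances)
    rare = a[a <= rare_cutoff]
    abundant = a[a > rare_cutoff]
    S_abund = float(abundant.size)
    S_rare = float(rare.size)
    if S_rare == 0:
        return S_abund
    N_rare = float(rare.sum())
    f1 = float((rare == 1).sum())
    C_ace = 1.0 - f1 / N_rare
    if C_ace == 0:
        return chao1(a)
    ks = np.arange(1, rare_cutoff + 1, dtype=float)
    fk = np.array([(rare == k).sum() for k in range(1, rare_cutoff + 1)], dtype=float)
    gamma = max(
        0.0,
        (S_rare / C_ace) * (ks * (ks - 1) * fk).sum() / (N_rare * (N_rare - 1)) - 1.0,
    ) if N_rare > 1 else 0.0
    return S_abund + S_rare / C_ace + (f1 / C_ace) * gamma


@dataclass(frozen=True)
class SharedIndices:
    shared_species: int
    chao_shared: float
    jaccard: float
    chao_jaccard: float
    bray_curtis: float


def shared_indices(a: Mapping[str, int], b: Mapping[str, int]) -> SharedIndices:
    """Shared-species statistics for two labelled abundance vectors."""
    for name, vec in (("first", a), ("second", b)):
        if any(v <= 0 for v in vec.values()):
            raise ValueError(f"{name} sample has non-positive abundances")
    sa, sb = set(a), set(b)
    shared = sorted(sa & sb)
    C = len(shared)
    S1, S2 = len(sa), len(sb)
    jac = C / (S1 + S2 - C) if (S1 + S2 - C) else 0.0

    n = sum(a.values())
    m = sum(b.values())
    # Bray-Curtis similarity
    bray = 2.0 * sum(min(a[s], b[s]) for s in shared) / (n + m)

    # Chao-shared (Chao et al. 2000), bias-corrected denominators
    f1p = sum(1 for s in shared if a[s] == 1)
    f2p = sum(1 for s in shared if a[s] == 2)
    fp1 = sum(1 for s in shared if b[s] == 1)
    fp2 = sum(1 for s in shared if b[s] == 2)
    f11 = sum(1 for s in shared if a[s] == 1 and b[s] == 1)
    f22 = sum(1 for s in shared if a[s] == 2 and b[s] == 2)
    chao_sh = (
        C
        + f1p * (f1p - 1) / (2 * (f2p + 1))
        + fp1 * (fp1 - 1) / (2 * (fp2 + 1))
        + f11 * (f11 - 1) / (4 * (f22 + 1))
    )

    # abundance-based Chao-Jaccard (Chao et al. 2005)
    if C == 0 or n == 0 or m == 0:
        chao_jac = 0.0
    else:
        U = sum(a[s] for s in shared) / n
        V = sum(b[s] for s in shared) / m
        if fp2 > 0:
            U += ((m - 1) / m) * (fp1 / (2 * fp2)) * sum(
                a[s] / n for s in shared if b[s] == 1
            )
        if f2p > 0:
            V += ((n - 1) / n) * (f1p / (2 * f2p)) * sum(
                b[s] / m for s in shared if a[s] == 1
            )
        U, V = min(U, 1.0), min(V, 1.0)
        chao_jac = U * V / (U + V - U * V) if (U + V - U * V) > 0 else 0.0

    return SharedIndices(C, chao_sh, jac, chao_jac, bray)


@dataclass
class AccumulationCurve:
    """Expected species count (with resampling SD) as samples accumulate."""

    samples: np.ndarray  # 1..n
    mean_species: np.ndarray
    sd_species: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"samples": self.samples, "mean_species": self.mean_species, "sd": self.sd_species}
        )


def accumulation_curve(
    incidence: "pd.DataFrame | np.ndarray", resamples: int = 100, seed: int = 0
) -> AccumulationCurve:
    """Sample-based accumulation curve by sample-order randomization."""
    inc = np.asarray(incidence, dtype=bool)
    if inc.ndim != 2 or inc.shape[0] < 1:
        raise ValueError("incidence must be a samples x species matrix")
    nsamp = inc.shape[0]
    rng = np.random.default_rng(seed)
    curves = np.empty((resamples, nsamp))
    for r in range(resamples):
        order = rng.permutation(nsamp)
        seen = np.zeros(inc.shape[1], dtype=bool)
        for k, s in enumerate(order):
            seen |= inc[s]
            curves[r, k] = seen.sum()
    return AccumulationCurve(
        np.arange(1, nsamp + 1), curves.mean(axis=0), curves.std(axis=0, ddof=0)
    )


def host_report(table: CommunityTable) -> pd.DataFrame:
    """Per-host summary mirroring a richness/evenness/diversity table."""
    rows = []
    for host in table.hosts:
        ab = table.abundances(host)
        n_seg = table.segments_per_host[host]
        N = int(ab.sum())
        S = int((ab > 0).sum())
        rows.append(
            {
                "host": host,
                "isolates": N,
                "species": S,
                "CF": colonization_frequency(N, n_seg),
                "EIR": endophytic_infection_rate(table.infected_segments(host), n_seg),
                "shannon": round(shannon(ab), 2),
                "simpson_inverse": round(simpson_inverse(ab), 2) if N >= 2 else float("nan"),
                "fisher_alpha": round(fisher_alpha(S, N), 2) if S < N else float("nan"),
                "chao1": round(chao1(ab), 2),
                "ace": round(ace(ab), 2),
            }
        )
    return pd.DataFrame(rows)


def pairwise_report(table: CommunityTable) -> pd.DataFrame:
    """Shared-species indices for every host pair."""
    hosts = table.hosts
    rows = []
    for i in range(len(hosts)):
        for j in range(i + 1, len(hosts)):
            a = table.abundances(hosts[i]).to_dict()
            b = table.abundances(hosts[j]).to_dict()
            sh = shared_indices(a, b)
            rows.append(
                {
                    "first": hosts[i],
                    "second": hosts[j],
                    "shared_species": sh.shared_species,
                    "chao_shared": round(sh.chao_shared, 2),
                    "jaccard": round(sh.jaccard, 3),
                    "chao_jaccard": round(sh.chao_jaccard, 3),
                    "bray_curtis": round(sh.bray_curtis, 3),
                }
            )
    return pd.DataFrame(rows)


def midrib_fold_excess(n_midrib: int, n_lamina: int) -> float:
    """Fold-excess of midrib over lamina isolates: (midrib - lamina) / lamina."""
    if n_lamina <= 0:
        raise ValueError("lamina isolate count must be positive")
    return (n_midrib - n_lamina) / n_lamina
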