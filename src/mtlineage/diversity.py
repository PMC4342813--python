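"""Forensic and population-genetic diversity statistics.

All statistics operate on a PopulationSample: one haplotype per
individual, all trimmed to a shared reading frame, compared under a
hotspot-masking policy.  Haplotype identity is equality of the masked,
trimmed variant sets; distances are counted per differing site.

* the frequency spectrum and the number/proportion of unique (singleton)
  haplotypes — proportions are of the *sample size* n, not of the number
  of distinct haplotypes;
* the random match probability, RMP = sum of squared haplotype
  frequencies (reported with its reciprocal "1:k" for forensic tables);
* the mean number of pairwise differences (MPD) within a population,
  with the Tajima (1983) no-recombination variance estimator supplying
  the conventional "±" value;
* MPD between populations, uncorrected (mean over all cross pairs) and
  corrected, i.e. reduced by the mean of the two within-population MPDs;
* haplotype sharing between two populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .codec import (
    DEFAULT_POLICY,
    FrameError,
    Haplotype,
    HotspotPolicy,
    ReadingFrame,
    canonical_key,
    pairwise_distance,
)


@dataclass
class PopulationSample:
    """Named collection of haplotypes; the unit of all diversity statistics."""

    name: str
    haplotypes: list[Haplotype]
    frame: ReadingFrame
    policy: HotspotPolicy = field(default_factory=lambda: DEFAULT_POLICY)

    def __post_init__(self) -> None:
        if not self.haplotypes:
            raise ValueError(f"population {self.name!r} is empty")
        for h in self.haplotypes:
            if h.frame != self.frame:
                raise FrameError(
                    f"haplotype {h.sample_id!r} frame {h.frame} != population frame {self.frame}"
                )

    @property
    def n(self) -> int:
        return len(self.haplotypes)


@dataclass(frozen=True)
class FrequencySpectrum:
    entries: dict[str, int]
    n: int

    def __post_init__(self) -> None:
        if sum(self.entries.values()) != self.n:
            raise ValueError("spectrum counts do not sum to n")

    @property
    def frequencies(self) -> dict[str, float]:
        return {k: c / self.n for k, c in self.entries.items()}


@dataclass(frozen=True)
class MpdResult:
    mean: float
    sd: float
    n: int


def spectrum(pop: PopulationSample) -> FrequencySpectrum:
    counts: dict[str, int] = {}
    for h in pop.haplotypes:
        key = canonical_key(h, pop.policy)
        counts[key] = counts.get(key, 0) + 1
    return FrequencySpectrum(counts, pop.n)


def unique_haplotype_stats(pop: PopulationSample) -> tuple[int, float]:
    """(number of singleton haplotypes, proportion of individuals)."""
    spec = spectrum(pop)
    singletons = sum(1 for c in spec.entries.values() if c == 1)
    return singletons, singletons / pop.n


def random_match_probability(pop: PopulationSample) -> float:
    """Sum of squared haplotype frequencies; in (0, 1]."""
    spec = spectrum(pop)
    return sum((c / pop.n) ** 2 for c in spec.entries.values())


def tajima_mpd_variance(pi: float, n: int) -> float:
    """Tajima-style total variance of the mean pairwise difference.

    For n > 6 the no-recombination estimator
    V = (3n(n+1)pi + 2(n^2+n+3)pi^2) / (11(n^2 - 7n + 6)) is used; its
    denominator vanishes at n = 6, so for n <= 6 the equivalent-purpose
    Tajima (1983) total-variance form
    V = (n+1)pi/(3(n-1)) + 2(n^2+n+3)pi^2/(9n(n-1)) applies instead.
    Isolated in one function so the estimator can be swapped without
    touching callers.
    """
    if n < 2:
        raise ValueError("variance estimator requires n >= 2")
    if n > 6:
        return (3 * n * (n + 1) * pi + 2 * (n * n + n + 3) * pi * pi) / (
            11 * (n * n - 7 * n + 6)
        )
    return (n + 1) * pi / (3 * (n - 1)) + 2 * (n * n + n + 3) * pi * pi / (
        9 * n * (n - 1)
    )


def mpd_within(pop: PopulationSample) -> MpdResult:
    """Mean number of pairwise differences over all C(n,2) pairs."""
    if pop.n < 2:
        raise ValueError("MPD requires n >= 2")
    hs = pop.haplotypes
    total = 0
    for i in range(pop.n):
        for j in range(i + 1, pop.n):
            total += pairwise_distance(hs[i], hs[j], pop.policy)
    mean = total / (pop.n * (pop.n - 1) / 2)
    sd = math.sqrt(tajima_mpd_variance(mean, pop.n))
    return MpdResult(mean=mean, sd=sd, n=pop.n)


def mpd_between(popA: PopulationSample, popB: PopulationSample) -> tuple[float, float]:
    """(uncorrected, corrected) between-population MPD.

    Uncorrected: mean distance over all n_A x n_B cross pairs.  Corrected:
    reduced by the mean of the two within-population MPDs.
    """
    if popA.frame != popB.frame:
        raise FrameError("populations must share a reading frame")
    if popA.n < 2 or popB.n < 2:
        raise ValueError("between-population MPD requires n >= 2 in both samples")
    total = 0
    for ha in popA.haplotypes:
        for hb in popB.haplotypes:
            total += pairwise_distance(ha, hb, popA.policy)
    uncorrected = total / (popA.n * popB.n)
    corrected = uncorrected - (mpd_within(popA).mean + mpd_within(popB).mean) / 2
    return uncorrected, corrected


def haplotype_sharing(
    popA: PopulationSample, popB: PopulationSample
) -> tuple[float, float]:
    """(share of A's haplotypes found in B, share of A's individuals carrying them)."""
    if popA.frame != popB.frame:
        raise FrameError("populations must share a reading frame")
    specA, specB = spectrum(popA), spectrum(popB)
    shared = set(specA.entries) & set(specB.entries)
    prop_types = len(shared) / len(specA.entries)
    prop_indiv = sum(specA.entries[k] for k in shared) / popA.n
    return prop_types, prop_indiv


def diversity_table(pops: list[PopulationSample]):
    """Forensic summary table: Population, n, hts, Unique hts (with %), MPD ± sd, RMP."""
    import pandas as pd

    rows = []
    for pop in pops:
        spec = spectrum(pop)
        uniq, prop = unique_haplotype_stats(pop)
        mpd = mpd_within(pop) if pop.n >= 2 else MpdResult(0.0, 0.0, pop.n)
        rmp = random_match_probability(pop)
        rows.append(
            {
                "Population": pop.name,
                "n": pop.n,
                "hts": len(spec.entries),
                "unique_hts": uniq,
                "unique_pct": round(100 * prop),
                "MPD": round(mpd.mean, 3),
                "MPD_sd": round(mpd.sd, 3),
                "RMP": round(rmp, 3),
                "RMP_reciprocal": f"1:{round(1 / rmp)}" if rmp > 0 else "",
            }
        )
    return pd.DataFrame(rows)
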