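"""Structured-population genotype simulator with latent disease subgroups.

Population structure follows the Balding–Nichols model: each marker has an
ancestral allele frequency p drawn uniformly from a configured range, and
every population draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F),
whose mean is p and variance F p (1-p).  Genotypes are then sampled under
Hardy–Weinberg equilibrium as Binomial(2, p_pop).  Latent disease subgroups
add frequency shifts at selected disease SNPs, subphenotypes are drawn from
subgroup-conditional categorical distributions, and per-SNP MCAR missingness
reproduces a configurable call-rate profile.

The default configuration emulates a strongly unbalanced three-population
cohort (430 / 17 / 3) typed on a high-FST panel of 30 ancestry informative
markers and a low-FST panel of 51 disease SNPs, one of which is highly
differentiated between populations, with disease-panel call rates between
0.5 and 0.95.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimTruth",
    "draw_population_freqs",
    "simulate_genotypes",
    "inject_subgroup_effects",
    "simulate_subphenotypes",
    "apply_missingness",
    "estimate_fst",
    "make_reference_panel",
    "simulate_cohort",
]

_CLIP = (0.01, 0.99)  # shifted sampling frequencies stay inside this range


@dataclass
class SimConfig:
    """Study-shaped simulation settings (defaults emulate the motivating cohort)."""

    pop_sizes: tuple = (430, 17, 3)
    pop_names: tuple = ("Europe", "Sub-Saharan Africa", "East Asia")
    # ancestry-informative panel: chosen to discriminate continents, high
    # FST; 0.3 makes the top two PCs of a 450 x 30 panel explain ~18% of
    # the variance, the scale reported for real continental AIM panels
    m_aim: int = 30
    F_aim: float = 0.3
    aim_call_rate_range: tuple = (0.95, 1.0)
    # disease panel: typical continental differentiation, plus optionally a
    # few unusually differentiated disease SNPs
    m_disease: int = 51
    F_disease: float = 0.1
    n_differentiated_disease_snps: int = 1
    F_differentiated: float = 0.6
    # call-rate profile: most SNPs call well, a handful assay poorly, so the
    # realised rates span roughly 0.5-0.95
    disease_call_rate_range: tuple = (0.75, 0.95)
    n_low_call_snps: int = 3
    low_call_rate: float = 0.5
    ancestral_range: tuple = (0.1, 0.9)
    # latent disease subgroups (within-population), empty by default
    n_subgroups: int = 1
    subgroup_proportions: tuple | None = None  # within each population
    affected_snps: tuple = ()                  # disease-panel marker indices
    subgroup_deltas: tuple = ()                # per subgroup, per affected SNP
    # categorical subphenotypes: name -> (categories, probs[subgroup, category])
    subphenotypes: dict = field(default_factory=dict)
    # labelled reference panel for ancestry assignment
    panel_sizes: tuple = (100, 100, 100)
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.pop_sizes):
            raise ValueError("population sizes must be >= 1")
        if len(self.pop_sizes) != len(self.pop_names):
            raise ValueError("pop_sizes and pop_names must align")
        for F in (self.F_aim, self.F_disease, self.F_differentiated):
            if not 0.0 <= F < 1.0:
                raise ValueError("FST values must lie in [0, 1)")
        if self.n_subgroups > 1:
            props = self.subgroup_proportions or tuple(
                [1.0 / self.n_subgroups] * self.n_subgroups)
            if abs(sum(props) - 1.0) > 1e-8:
                raise ValueError("subgroup proportions must sum to 1")
            self.subgroup_proportions = tuple(props)
            deltas = np.asarray(self.subgroup_deltas, dtype=float)
            if deltas.shape != (self.n_subgroups, len(self.affected_snps)):
                raise ValueError("subgroup_deltas must be n_subgroups x "
                                 "len(affected_snps)")
            if np.any(np.abs(deltas) >= 1):
                raise ValueError("frequency shifts must lie in (-1, 1)")
            if self.affected_snps and max(self.affected_snps) >= self.m_disease:
                raise ValueError("affected SNP index out of range")
        for name, (cats, probs) in self.subphenotypes.items():
            probs = np.asarray(probs, dtype=float)
            if probs.shape != (max(self.n_subgroups, 1), len(cats)):
                raise ValueError(f"subphenotype {name!r}: probs shape mismatch")
            if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-8):
                raise ValueError(f"subphenotype {name!r}: rows must sum to 1")


@dataclass
class SimTruth:
    population: np.ndarray          # per-sample population name
    subgroup: np.ndarray            # per-sample subgroup index (0-based)
    ancestral_freqs: dict           # panel -> (m,) ancestral frequencies
    pop_freqs: dict                 # panel -> (n_pops, m) population frequencies
    call_rates: dict                # panel -> realised per-marker call rate
    subphenotypes: SampleTable | None = None


def draw_population_freqs(m: int, n_pops: int, F, rng: np.random.Generator,
                          ancestral_range=(0.1, 0.9)
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Balding–Nichols per-population allele frequencies.

    ``F`` may be a scalar or a per-marker array; F = 0 means no drift (the
    population frequency equals the ancestral frequency exactly).
    """
    F = np.broadcast_to(np.asarray(F, dtype=float), (m,)).copy()
    if np.any((F < 0) | (F >= 1)):
        raise ValueError("F must lie in [0, 1)")
    lo, hi = ancestral_range
    p = rng.uniform(lo, hi, size=m)
    pop_freqs = np.empty((n_pops, m))
    drift = F > 0
    for k in range(n_pops):
        pop_freqs[k, ~drift] = p[~drift]
        if drift.any():
            a = p[drift] * (1 - F[drift]) / F[drift]
            b = (1 - p[drift]) * (1 - F[drift]) / F[drift]
            pop_freqs[k, drift] = rng.beta(a, b)
    return p, pop_freqs


def simulate_genotypes(pop_freqs: np.ndarray, sizes, rng: np.random.Generator,
                       pop_names=None, marker_prefix: str = "snp",
                       sample_prefix: str = "s") -> tuple[GenotypeMatrix, np.ndarray]:
    """Hardy–Weinberg genotypes: g ~ Binomial(2, p_pop,j), labels recorded."""
    n_pops, m = pop_freqs.shape
    if pop_names is None:
        pop_names = [f"pop{k}" for k in range(n_pops)]
    sizes = list(sizes)
    if len(sizes) != n_pops:
        raise ValueError("sizes must match the number of populations")
    labels = np.repeat(np.asarray(pop_names, dtype=object), sizes)
    n = int(sum(sizes))
    per_sample = np.repeat(pop_freqs, sizes, axis=0)
    vals = rng.binomial(2, per_sample).astype(float)
    G = GenotypeMatrix([f"{sample_prefix}{i}" for i in range(n)],
                       [f"{marker_prefix}{j}" for j in range(m)], vals)
    return G, labels


def inject_subgroup_effects(pop_freqs: np.ndarray, sizes, config: SimConfig,
                            rng: np.random.Generator
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample sampling frequencies with subgroup-specific shifts.

    Subgroup labels are drawn within each population from the configured
    proportions; at each affected SNP the sampling frequency of subgroup s
    becomes clip(p_pop,j + delta_s,j, 0.01, 0.99).  Returns the n x m
    frequency matrix and the subgroup labels.
    """
    per_sample = np.repeat(pop_freqs, list(sizes), axis=0)
    n = per_sample.shape[0]
    if config.n_subgroups <= 1:
        return per_sample, np.zeros(n, dtype=int)
    props = np.asarray(config.subgroup_proportions)
    subgroup = rng.choice(config.n_subgroups, size=n, p=props)
    deltas = np.asarray(config.subgroup_deltas, dtype=float)
    n_clipped = 0
    for si, j in enumerate(config.affected_snps):
        target = per_sample[:, j] + deltas[subgroup, si]
        clipped = np.clip(target, *_CLIP)
        n_clipped += int((clipped != target).sum())
        per_sample[:, j] = clipped
    if n_clipped:
        logger.info("inject_subgroup_effects: clipped %d shifted frequencies",
                    n_clipped)
    return per_sample, subgroup


def simulate_subphenotypes(subgroup: np.ndarray, config: SimConfig,
                           rng: np.random.Generator,
                           sample_ids=None) -> SampleTable:
    """Draw each categorical subphenotype from its subgroup-conditional
    distribution, independently across variables given the subgroup."""
    n = len(subgroup)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    data = {}
    for name, (cats, probs) in config.subphenotypes.items():
        probs = np.asarray(probs, dtype=float)
        u = rng.random(n)
        cum = probs.cumsum(axis=1)
        idx = (u[:, None] > cum[subgroup]).sum(axis=1)
        data[name] = [cats[i] for i in idx]
    return SampleTable(pd.DataFrame(data, index=[str(s) for s in sample_ids]))


def apply_missingness(G: GenotypeMatrix, call_rate_range,
                      rng: np.random.Generator, n_low_call: int = 0,
                      low_call_rate: float = 0.5
                      ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Mask entries MCAR with a per-SNP call rate drawn from the given range.

    ``n_low_call`` randomly chosen SNPs are instead given ``low_call_rate``,
    emulating a handful of poorly performing assays.
    """
    lo, hi = call_rate_range
    if lo <= 0 or hi > 1 or lo > hi:
        raise ValueError("call rates must lie in (0, 1] with lo <= hi")
    rates = rng.uniform(lo, hi, size=G.m)
    if n_low_call:
        if not 0 < low_call_rate <= 1:
            raise ValueError("low_call_rate must lie in (0, 1]")
        low = rng.choice(G.m, size=min(n_low_call, G.m), replace=False)
        rates[low] = low_call_rate
    mask = rng.random(G.values.shape) > rates[None, :]
    vals = G.values.copy()
    vals[mask] = np.nan
    out = GenotypeMatrix(G.sample_ids, G.marker_ids, vals)
    realised = 1.0 - np.isnan(vals).mean(axis=0)
    return out, realised


def estimate_fst(G: GenotypeMatrix, population_labels) -> tuple[np.ndarray, float]:
    """Hudson-style FST per marker, averaged over population pairs.

    Per marker and pair: N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D = p1(1-p2) + p2(1-p1), with n the observed allele counts.  The
    per-marker estimate is sum(N)/sum(D) over pairs and the mean is the
    ratio of averages over markers.  Markers monomorphic in the pooled
    sample are skipped (NaN, with a count logged).
    """
    labels = np.asarray(population_labels)
    pops = np.unique(labels)
    if pops.size < 2:
        raise ValueError("need at least two populations")
    freqs, counts = [], []
    for pop in pops:
        sub = G.values[labels == pop]
        if sub.shape[0] < 2:
            raise ValueError(f"population {pop!r} has fewer than two samples")
        n_obs = (~np.isnan(sub)).sum(axis=0)
        freqs.append(np.nansum(sub, axis=0) / np.maximum(2.0 * n_obs, 1.0))
        counts.append(2.0 * n_obs)
    freqs = np.array(freqs)
    counts = np.array(counts)

    overall = np.nansum(G.values, axis=0) / (2.0 * (~np.isnan(G.values)).sum(axis=0))
    mono = (overall <= 0.0) | (overall >= 1.0)
    if mono.any():
        logger.info("estimate_fst: skipping %d pooled-monomorphic markers",
                    int(mono.sum()))

    num = np.zeros(G.m)
    den = np.zeros(G.m)
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            p1, p2 = freqs[a], freqs[b]
            n1, n2 = counts[a], counts[b]
            num += ((p1 - p2) ** 2
                    - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
                    - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
            den += p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_marker = np.where(mono | (den <= 0), np.nan, num / den)
    keep = ~np.isnan(per_marker)
    if not keep.any():
        raise ValueError("no polymorphic markers to estimate FST from")
    mean_fst = float(num[keep].sum() / den[keep].sum())
    return per_marker, mean_fst


def make_reference_panel(config: SimConfig, rng: np.random.Generator,
                         pop_freqs: np.ndarray | None = None
                         ) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Labelled high-FST AIM genotypes for reference individuals.

    If ``pop_freqs`` is given (e.g. the cohort's AIM frequencies) the panel
    is drawn from those same population frequencies, which is what makes it
    informative for assigning cohort samples; otherwise fresh frequencies are
    drawn under the AIM profile.
    """
    if len(config.panel_sizes) != len(config.pop_names):
        raise ValueError("panel_sizes must match pop_names")
    if pop_freqs is None:
        _, pop_freqs = draw_population_freqs(
            config.m_aim, len(config.pop_names), config.F_aim, rng,
            config.ancestral_range)
    G, labels = simulate_genotypes(pop_freqs, config.panel_sizes, rng,
                                   pop_names=config.pop_names,
                                   marker_prefix="aim", sample_prefix="ref")
    return G, labels, pop_freqs


@dataclass
class SimCohort:
    aim: GenotypeMatrix
    disease: GenotypeMatrix
    panel: GenotypeMatrix
    panel_labels: np.ndarray
    truth: SimTruth


def simulate_cohort(config: SimConfig, seed: int | None = None) -> SimCohort:
    """End-to-end draw of AIM panel, disease panel, reference panel,
    subgroup-linked subphenotypes and MCAR missingness.  Deterministic given
    the configuration and seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_pops = len(config.pop_sizes)

    p_aim, aim_freqs = draw_population_freqs(
        config.m_aim, n_pops, config.F_aim, rng, config.ancestral_range)

    F_dis = np.full(config.m_disease, config.F_disease)
    if config.n_differentiated_disease_snps:
        F_dis[:config.n_differentiated_disease_snps] = config.F_differentiated
    p_dis, dis_freqs = draw_population_freqs(
        config.m_disease, n_pops, F_dis, rng, config.ancestral_range)

    aim_G, pop_labels = simulate_genotypes(
        aim_freqs, config.pop_sizes, rng, pop_names=config.pop_names,
        marker_prefix="aim")

    per_sample, subgroup = inject_subgroup_effects(
        dis_freqs, config.pop_sizes, config, rng)
    dis_vals = rng.binomial(2, per_sample).astype(float)
    disease_G = GenotypeMatrix(aim_G.sample_ids,
                               [f"snp{j}" for j in range(config.m_disease)],
                               dis_vals)

    subpheno = simulate_subphenotypes(subgroup, config, rng,
                                      sample_ids=aim_G.sample_ids) \
        if config.subphenotypes else None

    aim_G, aim_rates = apply_missingness(aim_G, config.aim_call_rate_range, rng)
    disease_G, dis_rates = apply_missingness(
        disease_G, config.disease_call_rate_range, rng,
        n_low_call=config.n_low_call_snps, low_call_rate=config.low_call_rate)

    panel_G, panel_labels, _ = make_reference_panel(config, rng,
                                                    pop_freqs=aim_freqs)

    truth = SimTruth(
        population=pop_labels,
        subgroup=subgroup,
        ancestral_freqs={"aim": p_aim, "disease": p_dis},
        pop_freqs={"aim": aim_freqs, "disease": dis_freqs},
        call_rates={"aim": aim_rates, "disease": dis_rates},
        subphenotypes=subpheno,
    )
    return SimCohort(aim=aim_G, disease=disease_G, panel=panel_G,
                     panel_labels=panel_labels, truth=truth)
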