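"""Synthetic assay-data generators.

Every downstream analysis in this package consumes one of five inputs:
growth-curve titer series, adsorption titer series, phage x strain titer
matrices, per-tool gene-call sets, and amino-acid proteomes. This module
generates all five with the statistical structure the analyses assume, and
returns the planted ground truth alongside, so parameter recovery can be
tested without any external data.

Noise on counts is multiplicative lognormal: plaque titers span five or
more decades within one assay, so additive noise has no sensible scale.
The t=0 observation of each kinetic series is left noiseless — it defines
the assay's reference titer (P0 / the initial titer).

Generators are deterministic: the same :class:`SimulationConfig` seed and
parameters reproduce outputs bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import require
from .adsorption import DEFAULT_TIMES, AdsorptionSeries
from .aai import AMINO_ACIDS, ProteinRecord
from .consensus import GeneCall, PredictionSet
from .growth import GrowthCurve

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "simulate_growth_curve",
    "simulate_adsorption_series",
    "simulate_host_range",
    "simulate_predictions",
    "simulate_proteome_pair",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Reproducibility and noise settings shared by all generators.

    noise_sd is the standard deviation of the lognormal multiplicative
    noise on counts (0 disables noise); replicate_count is carried as
    metadata for assays run in replicate.
    """

    seed: int = 0
    noise_sd: float = 0.05
    replicate_count: int = 3

    def __post_init__(self) -> None:
        require(self.noise_sd >= 0, "noise_sd must be nonnegative")
        require(self.replicate_count >= 1, "replicate_count must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth recorded next to generated data.

    Downstream parameter-recovery tests read truth from here, never from
    the generated observations. Only the fields a given generator plants
    are populated.
    """

    true_K: float | None = None
    true_burst: float | None = None
    true_latent_min: float | None = None
    true_rise_min: float | None = None
    true_breadths: tuple[float, ...] | None = None
    susceptible_strains: dict | None = None
    true_eop: dict | None = None
    true_gene_set: tuple[tuple[int, int, str], ...] | None = None
    tool_memberships: dict | None = None
    spurious_calls: dict | None = None
    true_divergence: float | None = None
    pair_identity_pct: tuple[float, ...] | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            k: v
            for k, v in self.__dict__.items()
            if v is not None and (k != "extra" or v)
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def _multiplicative_noise(
    rng: np.random.Generator, values: np.ndarray, noise_sd: float, keep_first: bool = True
) -> np.ndarray:
    """Lognormal multiplicative noise; the first point stays exact."""
    if noise_sd == 0:
        return values.copy()
    noisy = values * np.exp(rng.normal(0.0, noise_sd, size=len(values)))
    if keep_first:
        noisy[0] = values[0]
    return noisy


def simulate_growth_curve(
    initial_titer: float,
    latent_min: float,
    rise_min: float,
    burst: float,
    t_max: float = 240.0,
    step: float = 10.0,
    config: SimulationConfig = SimulationConfig(),
) -> tuple[GrowthCurve, PlantedTruth]:
    """One-step growth curve: flat latent, exponential rise, plateau.

    The noiseless expectation is ``initial_titer`` for t < latent_min, an
    exponential ramp over ``rise_min`` minutes, and
    ``initial_titer * (1 + burst)`` thereafter (the plateau forced by the
    relative-burst definition). Sampling at 0, step, ..., t_max.
    """
    require(initial_titer > 0, "initial_titer must be positive")
    require(burst >= 0, "burst must be nonnegative")
    require(step > 0 and t_max > 0, "step and t_max must be positive")
    require(latent_min > 0 and rise_min > 0, "latent_min and rise_min must be positive")
    require(latent_min + rise_min < t_max, "latent + rise must end before t_max")

    times = np.arange(0.0, t_max + step / 2, step)
    final = initial_titer * (1.0 + burst)
    expected = np.empty_like(times)
    for i, t in enumerate(times):
        if t < latent_min:
            expected[i] = initial_titer
        elif t < latent_min + rise_min:
            expected[i] = initial_titer * (1.0 + burst) ** ((t - latent_min) / rise_min)
        else:
            expected[i] = final
    titers = _multiplicative_noise(config.rng(), expected, config.noise_sd)
    truth = PlantedTruth(
        true_burst=burst, true_latent_min=latent_min, true_rise_min=rise_min
    )
    return GrowthCurve(times, titers), truth


def simulate_adsorption_series(
    P0: float,
    B: float,
    K: float,
    times: Sequence[float] = DEFAULT_TIMES,
    config: SimulationConfig = SimulationConfig(),
) -> tuple[AdsorptionSeries, PlantedTruth]:
    """First-order adsorption decay ``Pt = P0 * exp(-K*B*t)`` with noise.

    ``Pt(0)`` equals P0 exactly; the noiseless series is strictly
    decreasing for K > 0.
    """
    require(P0 > 0 and B > 0, "P0 and B must be positive")
    require(K >= 0, "K must be nonnegative")
    t = np.asarray(times, dtype=float)
    require(t.ndim == 1 and len(t) >= 2, "need at least two times")
    require(t[0] == 0, "times must start at 0")
    require(bool(np.all(np.diff(t) > 0)), "times must be sorted strictly ascending")
    expected = P0 * np.exp(-K * B * t)
    counts = _multiplicative_noise(config.rng(), expected, config.noise_sd)
    return AdsorptionSeries(t, counts, B=B), PlantedTruth(true_K=K)


def simulate_host_range(
    n_phages: int,
    n_strains: int,
    planted_breadths: Sequence[float],
    reference_titer: float = 1e9,
    eop_log10_mean: float = -0.5,
    eop_log10_sd: float = 1.0,
    config: SimulationConfig = SimulationConfig(),
) -> tuple[pd.DataFrame, pd.Series, PlantedTruth]:
    """Phage x strain titer matrix with planted host-range breadths.

    Each phage infects exactly ``round(breadth * n_strains)`` randomly
    chosen strains; their EOP values are drawn log-normally (base-10 mean
    and sd set by the two eop parameters, spanning all four plating tiers
    at the defaults), the rest are 0. Test titers are EOP times the
    phage's reference titer, with multiplicative noise; zeros stay zero, so
    planted breadths are recovered exactly downstream.

    Returns the titer matrix (phage rows, strain columns), the per-phage
    reference titers, and the planted truth.
    """
    require(n_phages >= 1 and n_strains >= 1, "need at least one phage and strain")
    require(len(planted_breadths) == n_phages, "one breadth per phage")
    for b in planted_breadths:
        require(0 <= b <= 1, f"breadth {b} outside [0, 1]")
    require(reference_titer > 0, "reference_titer must be positive")

    rng = config.rng()
    phages = [f"phage_{i + 1}" for i in range(n_phages)]
    strains = [f"strain_{j + 1}" for j in range(n_strains)]
    eop = np.zeros((n_phages, n_strains))
    susceptible: dict[str, list[str]] = {}
    for i, b in enumerate(planted_breadths):
        n_sus = int(np.floor(b * n_strains + 0.5))
        chosen = rng.choice(n_strains, size=n_sus, replace=False)
        eop[i, chosen] = 10.0 ** rng.normal(eop_log10_mean, eop_log10_sd, size=n_sus)
        susceptible[phages[i]] = sorted(strains[j] for j in chosen)

    titers = eop * reference_titer
    if config.noise_sd > 0:
        titers = titers * np.exp(rng.normal(0.0, config.noise_sd, size=titers.shape))
    matrix = pd.DataFrame(titers, index=phages, columns=strains)
    refs = pd.Series(reference_titer, index=phages, name="reference_titer")
    truth = PlantedTruth(
        true_breadths=tuple(float(b) for b in planted_breadths),
        susceptible_strains=susceptible,
        true_eop={p: dict(zip(strains, row)) for p, row in zip(phages, eop)},
    )
    return matrix, refs, truth


def _place_true_genes(
    rng: np.random.Generator, genome_length: int, n_genes: int
) -> list[tuple[int, int, str]]:
    """Non-overlapping genes tiled left to right with random gaps."""
    lengths = 3 * rng.integers(60, 400, size=n_genes)  # 180..1197 bp, codon multiples
    require(
        int(lengths.sum()) + 20 * n_genes < genome_length,
        "n_genes x average gene length must fit within genome_length",
    )
    slack = genome_length - int(lengths.sum())
    # distribute the slack as random intergenic gaps (at least 10 bp each)
    gaps = rng.multinomial(slack - 10 * (n_genes + 1), np.full(n_genes + 1, 1 / (n_genes + 1)))
    gaps = gaps + 10
    genes = []
    pos = 1
    for L, gap in zip(lengths, gaps[:-1]):
        start = pos + int(gap)
        stop = start + int(L) - 1
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((start, stop, strand))
        pos = stop + 1
    return genes


def simulate_predictions(
    genome_length: int,
    n_genes: int,
    n_tools: int = 7,
    miss_rate: float = 0.1,
    spurious_rate: float = 3.0,
    start_jitter: int = 30,
    topology: str = "circular",
    genome_id: str = "synthetic_genome",
    config: SimulationConfig = SimulationConfig(),
) -> tuple[list[PredictionSet], PlantedTruth]:
    """Per-tool gene-call sets perturbed from a shared true gene set.

    Each tool independently drops true genes with probability ``miss_rate``,
    adds a Poisson(``spurious_rate``) number of spurious calls whose 3'
    keys occur nowhere else, and jitters the 5' (start-codon) end of
    retained genes by up to ``start_jitter`` bp in codon steps. The 3'
    anchor — the stop coordinate on the + strand, the start coordinate on
    the - strand — is never moved, so retained true genes keep identical
    match keys across tools (start-codon calls vary across real gene
    callers; stop codons are fixed by the reading frame).
    """
    require(0 <= miss_rate <= 1, "miss_rate must be in [0, 1]")
    require(spurious_rate >= 0, "spurious_rate must be nonnegative")
    require(start_jitter >= 0, "start_jitter must be nonnegative")
    require(n_tools >= 2, "need at least two tools")

    rng = config.rng()
    true_genes = _place_true_genes(rng, genome_length, n_genes)
    used_keys = {
        (strand, stop if strand == "+" else start) for start, stop, strand in true_genes
    }

    sets: list[PredictionSet] = []
    memberships: dict[str, list[int]] = {}
    spurious_record: dict[str, list[list]] = {}
    for t in range(n_tools):
        tool = f"tool_{t + 1}"
        calls: list[GeneCall] = []
        kept: list[int] = []
        for gi, (start, stop, strand) in enumerate(true_genes):
            if rng.random() < miss_rate:
                continue
            kept.append(gi)
            max_steps = start_jitter // 3
            shift = 3 * int(rng.integers(-max_steps, max_steps + 1)) if max_steps else 0
            if strand == "+":
                new_start = int(np.clip(start + shift, 1, stop - 29))
                calls.append(GeneCall(new_start, stop, strand, source_tool=tool))
            else:
                new_stop = int(np.clip(stop + shift, start + 29, genome_length))
                calls.append(GeneCall(start, new_stop, strand, source_tool=tool))
        n_spurious = int(rng.poisson(spurious_rate))
        spur: list[list] = []
        for _ in range(n_spurious):
            for _attempt in range(1000):
                strand = "+" if rng.random() < 0.5 else "-"
                length = 3 * int(rng.integers(30, 200))
                start = int(rng.integers(1, genome_length - length))
                stop = start + length - 1
                key = (strand, stop if strand == "+" else start)
                if key not in used_keys:
                    used_keys.add(key)
                    calls.append(GeneCall(start, stop, strand, source_tool=tool))
                    spur.append([start, stop, strand])
                    break
        memberships[tool] = kept
        spurious_record[tool] = spur
        sets.append(
            PredictionSet(
                tool=tool,
                genome_id=genome_id,
                genome_length=genome_length,
                topology=topology,
                calls=tuple(calls),
            )
        )
    truth = PlantedTruth(
        true_gene_set=tuple(true_genes),
        tool_memberships=memberships,
        spurious_calls=spurious_record,
    )
    return sets, truth


def simulate_proteome_pair(
    n_proteins: int = 50,
    length_range: tuple[int, int] = (200, 400),
    divergence: float = 0.05,
    indel_rate: float = 0.0,
    config: SimulationConfig = SimulationConfig(),
) -> tuple[list[ProteinRecord], list[ProteinRecord], PlantedTruth]:
    """Two proteomes at a controlled amino-acid divergence.

    Proteome A is random over the 20-letter alphabet; proteome B applies an
    i.i.d. substitution at each site with probability ``divergence``
    (always to a different residue), so the expected per-pair identity is
    ``(1 - divergence) * 100`` percent. Orthologs are positionally paired
    (``a_i`` with ``b_i``) and the realized identity of every pair is
    recorded in the planted truth. Indels are off by default (keeping the
    positional identity oracle exact); a nonzero ``indel_rate`` deletes
    sites of B i.i.d. at that rate.
    """
    require(0 <= divergence < 1, "divergence must be in [0, 1)")
    require(0 <= indel_rate < 1, "indel_rate must be in [0, 1)")
    require(n_proteins >= 1, "need at least one protein")
    lo, hi = length_range
    require(3 <= lo <= hi, "invalid length range")

    rng = config.rng()
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    prot_a: list[ProteinRecord] = []
    prot_b: list[ProteinRecord] = []
    identities: list[float] = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        idx = rng.integers(0, 20, size=length)
        seq_a = alphabet[idx]
        sub_mask = rng.random(length) < divergence
        # substitute to a uniformly chosen *different* residue
        offsets = rng.integers(1, 20, size=length)
        seq_b = np.where(sub_mask, alphabet[(idx + offsets) % 20], seq_a)
        identities.append(100.0 * float((~sub_mask).sum()) / length)
        if indel_rate > 0:
            keep = rng.random(length) >= indel_rate
            seq_b = seq_b[keep]
        prot_a.append(ProteinRecord(f"a_{i + 1}", seq_a.tobytes().decode()))
        prot_b.append(ProteinRecord(f"b_{i + 1}", seq_b.tobytes().decode()))
    truth = PlantedTruth(
        true_divergence=divergence, pair_identity_pct=tuple(identities)
    )
    return prot_a, prot_b, truth
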