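"""Synthetic herd generator: pedigree, CNV landscape, phenotypes, feed events.

The real study population (a closed experimental Nellore herd with
pedigree, SNP-array CNV calls and electronic feed-bunk records) is not
publicly deposited, so every downstream stage is exercised on synthetic
data carrying known ground truth:

* a multi-generation pedigree with discrete generations and random
  mating;
* a non-overlapping CNV region landscape with deletion/duplication/mixed
  types, configurable carrier frequencies and per-region additive effects;
* per-sample CNV call tables (optionally fragmented at the breakpoint
  base) plus array QC metrics drawn from pass/fail mixtures;
* phenotypes from the generative animal model
  y = fixed effects + sum_r code_r * beta_r + u + e with breeding values
  cascaded down the pedigree (founder u ~ N(0, sigma2_u); offspring
  u = (u_sire + u_dam)/2 + Mendelian sampling with variance
  sigma2_u * (1/2)(1 - (F_s + F_d)/2));
* feed-bunk tag-read streams with meal structure (reads every 1.0-6.3 s
  within a meal, > 300 s gaps between meals) and exact TF/FF truth.

Identical configuration and seed give byte-identical tables.  Carrier
status is assigned per animal independently at the region's carrier
frequency (not transmitted through the pedigree): the association model
treats the CNVR code as a fixed covariate, so transmission is not needed
and this keeps frequency control exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import ARS_UCD12_AUTOSOME_LENGTHS
from .io_qc import CnvCall, SampleQc
from .pedigree import UNKNOWN, a_matrix

__all__ = [
    "SimulationConfig",
    "simulate_pedigree",
    "simulate_cnv_landscape",
    "simulate_genotypes",
    "simulate_cnv_calls",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_feed_events",
    "simulate_study",
    "StudyData",
]

#: Mean inter-marker spacing (bp) of a 75K bovine SNP panel; used to give
#: simulated calls a realistic supporting-SNP count.
PANEL_SPACING_BP = 32_300


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: ~700 animals over 5 discrete generations
    (about 620 passing array QC at the default 10% failure rate), 500
    CNV regions with mean length 170 kb on the 29 cattle autosomes,
    carrier frequencies in [0.005, 0.10] and heritability
    sigma2_u / (sigma2_u + sigma2_e) = 1/3."""

    n_founders: int = 100
    n_generations: int = 4
    offspring_per_mating: int = 3
    n_matings: int | None = None  # dams mated per generation; default n_founders // 2
    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(ARS_UCD12_AUTOSOME_LENGTHS)
    )
    n_regions: int = 500
    region_mean_length: int = 170_000
    carrier_freq_range: tuple[float, float] = (0.005, 0.10)
    type_proportions: tuple[float, float, float] = (0.456, 0.437, 0.107)
    effect_sizes: Mapping[str, float] = field(default_factory=dict)
    sigma2_u: float = 1.0
    sigma2_e: float = 2.0
    n_groups: int = 5
    group_effect_sd: float = 1.0
    mu: float = 0.0
    qc_fail_fraction: float = 0.10
    fragmentation: float = 0.0
    false_call_rate: float = 0.0
    seed: int = 20_240_101

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.offspring_per_mating < 1:
            raise ValueError("offspring_per_mating must be >= 1")
        if self.sigma2_u < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be >= 0")
        lo, hi = self.carrier_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("carrier frequencies must lie in (0, 1)")
        if any(v <= 0 for v in self.chromosome_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if abs(sum(self.type_proportions) - 1.0) > 1e-9 or min(self.type_proportions) < 0:
            raise ValueError("type_proportions must be non-negative and sum to 1")
        if not (0 <= self.qc_fail_fraction < 1):
            raise ValueError("qc_fail_fraction must lie in [0, 1)")
        if not (0 <= self.fragmentation <= 1):
            raise ValueError("fragmentation must lie in [0, 1]")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_pedigree(cfg: SimulationConfig, rng=None) -> pd.DataFrame:
    """Discrete-generation pedigree with random mating.

    Founders (generation 0) have unknown parents; in each later
    generation up to ``n_matings`` dams of the previous generation are
    each mated once to a randomly drawn sire and produce
    ``offspring_per_mating`` offspring of random sex.  Parents always
    precede offspring in the table.
    """
    rng = _rng(cfg.seed if rng is None else rng)
    rows = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"A{counter:05d}"

    founders = [new_id() for _ in range(cfg.n_founders)]
    sex = {}
    for i, a in enumerate(founders):
        sex[a] = "M" if i < cfg.n_founders // 2 else "F"
        rows.append({"animal": a, "sire": UNKNOWN, "dam": UNKNOWN, "generation": 0, "sex": sex[a]})
    prev = founders
    for gen in range(1, cfg.n_generations + 1):
        males = [a for a in prev if sex[a] == "M"]
        females = [a for a in prev if sex[a] == "F"]
        if not males or not females:
            raise ValueError("a generation lacks one sex; increase n_founders")
        n_matings = cfg.n_matings if cfg.n_matings is not None else cfg.n_founders // 2
        if len(females) > n_matings:
            chosen = rng.choice(len(females), size=n_matings, replace=False)
            females = [females[k] for k in sorted(chosen)]
        current = []
        for dam in females:
            sire = males[rng.integers(len(males))]
            for _ in range(cfg.offspring_per_mating):
                a = new_id()
                sex[a] = "M" if rng.random() < 0.5 else "F"
                rows.append(
                    {"animal": a, "sire": sire, "dam": dam, "generation": gen, "sex": sex[a]}
                )
                current.append(a)
        prev = current
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "generation", "sex"])


def simulate_cnv_landscape(cfg: SimulationConfig, rng=None) -> pd.DataFrame:
    """Place non-overlapping CNV regions on the genome.

    Chromosomes are chosen with probability proportional to length;
    region lengths are exponential around ``region_mean_length``
    (truncated to [5 kb, 20x mean]); types follow ``type_proportions``;
    carrier frequencies are uniform on ``carrier_freq_range``.  Placed
    regions keep a >= 1 kb gap so distinct regions never merge.
    Raises when the requested regions cannot fit.
    """
    rng = _rng(cfg.seed + 1 if rng is None else rng)
    chroms = list(cfg.chromosome_lengths)
    lengths = np.array([cfg.chromosome_lengths[c] for c in chroms], dtype=float)
    if cfg.n_regions * (cfg.region_mean_length + 1000) > 0.5 * lengths.sum():
        raise ValueError("region count infeasible for genome size")
    probs = lengths / lengths.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    types = np.array(["deletion", "duplication", "mixed"])
    rows = []
    for i in range(cfg.n_regions):
        for _attempt in range(1000):
            c = chroms[rng.choice(len(chroms), p=probs)]
            clen = cfg.chromosome_lengths[c]
            L = int(np.clip(rng.exponential(cfg.region_mean_length),
                            5_000, 20 * cfg.region_mean_length))
            if L >= clen:
                continue
            start = int(rng.integers(1, clen - L + 1))
            end = start + L - 1
            # keep a >=1 kb buffer between true regions
            if all(end < s - 1000 or start > e + 1000 for s, e in placed[c]):
                placed[c].append((start, end))
                break
        else:
            raise ValueError("could not place region without overlap; genome too crowded")
        rtype = types[rng.choice(3, p=np.asarray(cfg.type_proportions))]
        freq = float(rng.uniform(*cfg.carrier_freq_range))
        rows.append(
            {
                "region_id": f"TR{i+1}",
                "chromosome": c,
                "start": start,
                "end": end,
                "type": rtype,
                "carrier_freq": freq,
                "effect": float(cfg.effect_sizes.get(f"TR{i+1}", 0.0)),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["chromosome", "start"],
                          key=lambda s: s.map(lambda v: (len(str(v)), str(v)))
                          if s.name == "chromosome" else s).reset_index(drop=True)


def simulate_genotypes(
    pedigree: pd.DataFrame, landscape: pd.DataFrame, rng
) -> pd.DataFrame:
    """True CNVR codes per animal: -1 deletion carrier, +1 duplication.

    Carriers are drawn independently per animal at the region's carrier
    frequency; in mixed regions carriers split evenly between the two
    carrier classes.
    """
    rng = _rng(rng)
    animals = list(pedigree["animal"])
    codes = np.zeros((len(animals), len(landscape)), dtype=np.int8)
    for j, reg in enumerate(landscape.itertuples(index=False)):
        carrier = rng.random(len(animals)) < reg.carrier_freq
        if reg.type == "deletion":
            codes[carrier, j] = -1
        elif reg.type == "duplication":
            codes[carrier, j] = 1
        else:
            sign = np.where(rng.random(len(animals)) < 0.5, -1, 1)
            codes[carrier, j] = sign[carrier]
    return pd.DataFrame(
        codes, index=pd.Index(animals, name="sample_id"), columns=list(landscape["region_id"])
    )


def _call_n_snps(length: int) -> int:
    return max(3, int(round(length / PANEL_SPACING_BP)) + 1)


def simulate_cnv_calls(
    pedigree: pd.DataFrame,
    landscape: pd.DataFrame,
    genotypes: pd.DataFrame,
    cfg: SimulationConfig,
    rng=None,
) -> tuple[list[CnvCall], list[SampleQc]]:
    """Emit per-sample CNV calls and array QC metrics.

    Every carrier emits one call spanning its true region; with
    probability ``cfg.fragmentation`` the call is split into two calls
    sharing the breakpoint base (so region merging re-derives the
    truth).  ``cfg.false_call_rate`` adds Poisson-distributed spurious
    calls per sample.  A fraction ``cfg.qc_fail_fraction`` of samples
    receives metrics violating the sample QC thresholds; the rest draw
    from well-behaved distributions.
    """
    if len(landscape) == 0:
        raise ValueError("landscape is empty")
    rng = _rng(cfg.seed + 2 if rng is None else rng)
    calls: list[CnvCall] = []
    animals = list(pedigree["animal"])
    chroms = list(cfg.chromosome_lengths)
    lengths = np.array([cfg.chromosome_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    for sample in animals:
        row = genotypes.loc[sample]
        for reg in landscape.itertuples(index=False):
            code = int(row[reg.region_id])
            if code == 0:
                continue
            cn = 1 if code < 0 else 3
            if rng.random() < cfg.fragmentation and reg.end > reg.start:
                m = int(rng.integers(reg.start, reg.end))  # breakpoint base, shared
                pieces = [(reg.start, m), (m, reg.end)]
            else:
                pieces = [(reg.start, reg.end)]
            for s, e in pieces:
                calls.append(
                    CnvCall(
                        sample_id=sample, chromosome=str(reg.chromosome),
                        start=s, end=e, copy_state=cn,
                        n_snps=_call_n_snps(e - s + 1),
                        confidence=float(np.round(rng.uniform(10, 100), 3)),
                    )
                )
        for _ in range(rng.poisson(cfg.false_call_rate)):
            c = chroms[rng.choice(len(chroms), p=probs)]
            L = int(np.clip(rng.exponential(cfg.region_mean_length), 5_000, 2_000_000))
            start = int(rng.integers(1, max(2, cfg.chromosome_lengths[c] - L)))
            calls.append(
                CnvCall(
                    sample_id=sample, chromosome=c, start=start, end=start + L - 1,
                    copy_state=int(rng.choice([1, 3])), n_snps=_call_n_snps(L),
                    confidence=float(np.round(rng.uniform(10, 100), 3)),
                )
            )

    n_calls_by_sample = pd.Series([c.sample_id for c in calls]).value_counts()
    qc: list[SampleQc] = []
    fail = rng.random(len(animals)) < cfg.qc_fail_fraction
    for sample, bad in zip(animals, fail):
        if bad:
            which = rng.integers(3)
            lrr = rng.uniform(0.31, 0.60) if which == 0 else abs(rng.normal(0.15, 0.03))
            drift = rng.uniform(0.011, 0.05) if which == 1 else abs(rng.normal(0.0, 0.002))
            gcwf = rng.choice([-1, 1]) * rng.uniform(0.051, 0.2) if which == 2 \
                else rng.normal(0.0, 0.01)
        else:
            lrr = abs(rng.normal(0.15, 0.03))
            drift = abs(rng.normal(0.0, 0.002))
            gcwf = rng.normal(0.0, 0.01)
        qc.append(
            SampleQc(
                sample_id=sample,
                lrr_sd=float(np.round(min(lrr, 0.30) if not bad and lrr > 0.30 else lrr, 4)),
                baf_drift=float(np.round(min(drift, 0.01) if not bad and drift > 0.01 else drift, 5)),
                gc_wave_factor=float(np.round(gcwf if bad else np.clip(gcwf, -0.05, 0.05), 4)),
                n_calls=int(n_calls_by_sample.get(sample, 0)),
            )
        )
    return calls, qc


def simulate_breeding_values(
    pedigree: pd.DataFrame,
    sigma2_u: float,
    rng,
    inbreeding: pd.Series | None = None,
) -> pd.Series:
    """Cascade additive breeding values down a (sorted) pedigree.

    Founder u ~ N(0, sigma2_u); an offspring receives the parent average
    plus a Mendelian-sampling deviation whose variance shrinks with
    parental inbreeding: sigma2_u * (1/2)(1 - (F_s + F_d)/2) when both
    parents are known, with the usual 3/4 and 1 factors when one or both
    parents are unknown.
    """
    rng = _rng(rng)
    if inbreeding is None:
        A, ids = a_matrix(pedigree)
        inbreeding = pd.Series(np.diag(A) - 1.0, index=ids)
    u: dict[str, float] = {}
    sd = np.sqrt(sigma2_u) if sigma2_u > 0 else 0.0
    for row in pedigree.itertuples(index=False):
        s = row.sire if row.sire != UNKNOWN else None
        d = row.dam if row.dam != UNKNOWN else None
        if s is None and d is None:
            u[row.animal] = float(rng.normal(0.0, sd))
            continue
        if s is not None and (s not in u):
            raise ValueError(f"sire {s!r} of {row.animal!r} has no breeding value yet")
        if d is not None and (d not in u):
            raise ValueError(f"dam {d!r} of {row.animal!r} has no breeding value yet")
        if s is not None and d is not None:
            mean = 0.5 * (u[s] + u[d])
            var = 0.5 * (1.0 - 0.5 * (inbreeding[s] + inbreeding[d]))
        else:
            p = s if s is not None else d
            mean = 0.5 * u[p]
            var = 0.75 - 0.25 * inbreeding[p]
        u[row.animal] = float(mean + rng.normal(0.0, np.sqrt(max(var, 0.0) * sigma2_u)))
    return pd.Series(u, name="u").loc[pedigree["animal"].tolist()]


def simulate_phenotypes(
    pedigree: pd.DataFrame,
    landscape: pd.DataFrame,
    genotypes: pd.DataFrame,
    cfg: SimulationConfig,
    rng=None,
    trait: str = "y",
) -> tuple[pd.DataFrame, dict]:
    """Generative animal model: y = mu + CG effect + sum_r code*beta_r + u + e.

    Animals are assigned to ``cfg.n_groups`` contemporary groups (CG)
    whose effects are drawn N(0, group_effect_sd^2) once per simulation.
    Returns the record table (animal_id, CG, trait value) and a truth
    dict with breeding values, residuals, group effects and the per-region
    effects actually applied.
    """
    rng = _rng(cfg.seed + 3 if rng is None else rng)
    animals = list(pedigree["animal"])
    u = simulate_breeding_values(pedigree, cfg.sigma2_u, rng)
    e = rng.normal(0.0, np.sqrt(cfg.sigma2_e), len(animals)) if cfg.sigma2_e > 0 \
        else np.zeros(len(animals))
    groups = rng.integers(cfg.n_groups, size=len(animals))
    group_effects = rng.normal(0.0, cfg.group_effect_sd, cfg.n_groups) \
        if cfg.group_effect_sd > 0 else np.zeros(cfg.n_groups)
    effects = landscape.set_index("region_id")["effect"]
    cnv_part = genotypes.loc[animals].to_numpy(dtype=float) @ effects.loc[genotypes.columns].to_numpy()
    y = cfg.mu + group_effects[groups] + cnv_part + u.to_numpy() + e
    records = pd.DataFrame(
        {
            "animal_id": animals,
            "CG": [f"G{g+1}" for g in groups],
            trait: y,
        }
    )
    truth = {
        "u": u,
        "e": pd.Series(e, index=animals, name="e"),
        "group_effects": {f"G{i+1}": float(v) for i, v in enumerate(group_effects)},
        "effects": effects.to_dict(),
        "sigma2_u": cfg.sigma2_u,
        "sigma2_e": cfg.sigma2_e,
    }
    return records, truth


def simulate_feed_events(
    animal_ids: Sequence[str],
    n_days: int,
    rng,
    *,
    meals_per_day: int = 3,
    cadence_s: tuple[float, float] = (1.0, 6.3),
    meal_duration_s: tuple[float, float] = (120.0, 1200.0),
    meal_intake_kg: tuple[float, float] = (1.0, 4.0),
    inter_meal_gap_s: tuple[float, float] = (400.0, 3600.0),
    shared_bunks: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tag-read streams with meal structure and exact TF/FF truth.

    Reads within a meal are spaced uniformly in ``cadence_s`` (the 1.0 to
    6.3 s scan interval of electronic trough systems); consecutive meals
    of one animal are separated by more than 300 s, so noise-free event
    derivation recovers the truth exactly.  With ``shared_bunks=False``
    each animal feeds at its own bunk and meal counts/durations are
    unperturbed by other animals.  TF truth uses last-read minus
    first-read times, matching the downstream duration definition.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if inter_meal_gap_s[0] <= 300.0:
        raise ValueError("inter-meal gaps must exceed the 300 s meal criterion")
    rng = _rng(rng)
    reads = []
    truth_rows = []
    for i, animal in enumerate(sorted(str(a) for a in animal_ids)):
        bunk = "B1" if shared_bunks else f"B{i+1}"
        t = float(rng.uniform(0, 3600))
        tf_s = 0.0
        n_meals = 0
        for _day in range(n_days):
            for _meal in range(meals_per_day):
                dur = float(rng.uniform(*meal_duration_s))
                intake = float(rng.uniform(*meal_intake_kg))
                times = [t]
                while times[-1] - t < dur:
                    step = float(rng.uniform(*cadence_s))
                    times.append(times[-1] + step)
                times = times[:-1] if len(times) > 1 and times[-1] - t > dur else times
                per_read = intake / len(times)
                for ts in times:
                    reads.append(
                        {"animal_id": animal, "bunk_id": bunk,
                         "timestamp_s": ts, "intake_kg": per_read}
                    )
                tf_s += times[-1] - times[0]
                n_meals += 1
                t = times[-1] + float(rng.uniform(*inter_meal_gap_s))
        truth_rows.append(
            {"animal_id": animal, "TF": tf_s / 60.0 / n_days, "FF": n_meals / n_days}
        )
    stream = pd.DataFrame(reads).sort_values("timestamp_s", kind="mergesort").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows, columns=["animal_id", "TF", "FF"])
    return stream, truth


@dataclass
class StudyData:
    """Everything one synthetic study run produces."""

    config: SimulationConfig
    pedigree: pd.DataFrame
    landscape: pd.DataFrame
    genotypes: pd.DataFrame
    calls: list[CnvCall]
    sample_qc: list[SampleQc]
    phenotypes: pd.DataFrame
    truth: dict


def simulate_study(cfg: SimulationConfig) -> StudyData:
    """Run the full generator with sub-streams derived from ``cfg.seed``."""
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(0, 2**31 - 1, size=5)
    pedigree = simulate_pedigree(cfg, np.random.default_rng(seeds[0]))
    landscape = simulate_cnv_landscape(cfg, np.random.default_rng(seeds[1]))
    genotypes = simulate_genotypes(pedigree, landscape, np.random.default_rng(seeds[2]))
    calls, qc = simulate_cnv_calls(
        pedigree, landscape, genotypes, cfg, np.random.default_rng(seeds[3])
    )
    phenos, truth = simulate_phenotypes(
        pedigree, landscape, genotypes, cfg, np.random.default_rng(seeds[4])
    )
    return StudyData(
        config=cfg, pedigree=pedigree, landscape=landscape, genotypes=genotypes,
        calls=calls, sample_qc=qc, phenotypes=phenos, truth=truth,
    )
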